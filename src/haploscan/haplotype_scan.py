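"""Carrier-haplotype definition, cohort scanning and fine length measurement.

The three-step procedure:

1. **define** — over a physical window centred on the focal position, find
   an assignment of one haplotype per known carrier such that all chosen
   haplotypes are identical over the in-window markers (missing calls are
   wildcards).  The merged allele string is the carrier haplotype; markers
   missing in every carrier stay unresolved.
2. **scan** — find every other individual with at least one haplotype
   identical to the consensus over the window.
3. **fine extend** — for a pair of haplotypes, grow the shared region one
   marker at a time in order of physical distance from the focal position;
   a mismatch freezes that side while the other keeps extending, giving a
   variant-resolution shared interval.

Coordinates: marker positions are 1-based bp; windows are half-open
``[pos - L/2, pos + L/2)``.  Window growth is symmetric about the focal
position (asymmetric growth can be had by calling ``define`` directly with
explicit bounds).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .datatypes import MISSING, FocalVariant, MarkerMap, PhasedCohort
from .errors import ValidationError, WindowError

__all__ = [
    "CarrierHaplotype",
    "ConsensusResult",
    "FineInterval",
    "ScanMatch",
    "SweepResult",
    "SweepRow",
    "define_carrier_haplotype",
    "scan_cohort",
    "coarse_sweep",
    "fine_extend",
    "haplotype_background_frequency",
]

_MAX_CARRIERS_EXHAUSTIVE = 16


@dataclass
class CarrierHaplotype:
    """Consensus allele string over a window around the focal variant."""

    chrom: str
    window_start_bp: int
    window_end_bp: int
    marker_indices: np.ndarray      # indices into the full MarkerMap
    alleles: np.ndarray             # int8; MISSING marks unresolved markers
    source_carrier_ids: list[str]
    chosen_haps: dict[str, int]     # carrier id -> haplotype index (0/1)

    @property
    def window_length_bp(self) -> int:
        return self.window_end_bp - self.window_start_bp

    @property
    def n_resolved(self) -> int:
        return int((self.alleles != MISSING).sum())


@dataclass
class ConsensusResult:
    """Outcome of carrier-haplotype definition.

    ``status`` is ``"ok"`` (one consensus string), ``"ambiguous"`` (several
    haplotype assignments give distinct strings — e.g. a single known
    carrier) or ``"no_consensus"``.  In the last case ``discordant_marker``
    names the first conflicting marker, in order of distance from the focal
    position, for the assignment that got furthest.
    """

    status: str
    candidates: list[CarrierHaplotype] = field(default_factory=list)
    discordant_marker: tuple[str, int] | None = None  # (marker id, pos)

    @property
    def ok(self) -> bool:
        return self.status in ("ok", "ambiguous")


@dataclass
class ScanMatch:
    individual_id: str
    hap_indices: list[int]


@dataclass
class SweepRow:
    window_length_bp: int
    n_markers: int
    consensus: ConsensusResult
    match_ids: list[str]


@dataclass
class SweepResult:
    rows: list[SweepRow]
    stop_reason: str

    def verify_nested(self) -> None:
        """Monotone specificity: growing the window never adds matches."""
        for a, b in zip(self.rows, self.rows[1:]):
            if not set(b.match_ids) <= set(a.match_ids):
                raise ValidationError(
                    f"nestedness violated between windows {a.window_length_bp} "
                    f"and {b.window_length_bp}"
                )

    def nominated(self) -> list[str]:
        """Match set of the longest window that still had matches."""
        for row in reversed(self.rows):
            if row.match_ids:
                return list(row.match_ids)
        return []


def _distance_order(positions: np.ndarray, focal_pos: int) -> np.ndarray:
    """Marker order by increasing distance from the focal position;
    ties break to the left (lower position)."""
    dist = np.abs(positions.astype(np.int64) - focal_pos)
    return np.lexsort((positions, dist))


def _matches(haps: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Row-wise wildcard equality of haplotypes against a consensus."""
    return ((haps == consensus) | (haps == MISSING) | (consensus == MISSING)).all(axis=-1)


def _check_phased(cohort: PhasedCohort, row: int, cols: np.ndarray) -> bool:
    if cohort.phased is None:
        return True
    return bool(cohort.phased[row][cols].all())


def define_carrier_haplotype(
    cohort: PhasedCohort,
    marker_map: MarkerMap,
    focal: FocalVariant,
    window_length_bp: int,
    window: tuple[int, int] | None = None,
) -> ConsensusResult:
    """Search haplotype assignments of the known carriers for a consensus.

    The search is exhaustive over the ``2^k`` assignments (k = number of
    known carriers), which is what makes the operation directly comparable
    with a brute-force oracle.
    """
    if not focal.known_carrier_ids:
        raise ValidationError("need at least one known carrier")
    if len(focal.known_carrier_ids) > _MAX_CARRIERS_EXHAUSTIVE:
        raise ValidationError("too many known carriers for exhaustive search")
    if window is None:
        if window_length_bp <= 0:
            raise ValidationError("window length must be positive")
        start = focal.position_bp - window_length_bp // 2
        window = (start, start + window_length_bp)
    idx = marker_map.window_indices(focal.chrom, window[0], window[1])
    if idx.size == 0:
        raise WindowError(
            f"no markers on chromosome {focal.chrom!r} in window "
            f"[{window[0]}, {window[1]})"
        )
    positions = marker_map.pos[idx]
    order = _distance_order(positions, focal.position_bp)

    rows = [cohort.index_of(c) for c in focal.known_carrier_ids]
    for c, r in zip(focal.known_carrier_ids, rows):
        if not _check_phased(cohort, r, idx):
            raise ValidationError(
                f"carrier {c!r} has phase-unknown calls inside the window"
            )
    hap_pairs = [cohort.alleles[r][idx] for r in rows]  # each (k, 2)

    candidates: list[CarrierHaplotype] = []
    seen: set[bytes] = set()
    best_progress = -1
    best_conflict: int | None = None
    for assignment in itertools.product((0, 1), repeat=len(rows)):
        consensus = np.full(idx.size, MISSING, dtype=np.int8)
        conflict_at = None
        for rank in order:
            for pair, hap in zip(hap_pairs, assignment):
                a = pair[rank, hap]
                if a == MISSING:
                    continue
                if consensus[rank] == MISSING:
                    consensus[rank] = a
                elif consensus[rank] != a:
                    conflict_at = rank
                    break
            if conflict_at is not None:
                break
        if conflict_at is None:
            key = consensus.tobytes()
            if key not in seen:
                seen.add(key)
                candidates.append(
                    CarrierHaplotype(
                        chrom=focal.chrom,
                        window_start_bp=window[0],
                        window_end_bp=window[1],
                        marker_indices=idx,
                        alleles=consensus,
                        source_carrier_ids=list(focal.known_carrier_ids),
                        chosen_haps=dict(zip(focal.known_carrier_ids, assignment)),
                    )
                )
        else:
            progress = int(np.where(order == conflict_at)[0][0])
            if progress > best_progress:
                best_progress = progress
                best_conflict = conflict_at

    if candidates:
        status = "ok" if len(candidates) == 1 else "ambiguous"
        return ConsensusResult(status, candidates)
    marker = (str(marker_map.ids[idx[best_conflict]]), int(positions[best_conflict]))
    return ConsensusResult("no_consensus", [], discordant_marker=marker)


def scan_cohort(
    cohort: PhasedCohort,
    marker_map: MarkerMap,
    consensus: ConsensusResult | CarrierHaplotype,
) -> list[ScanMatch]:
    """All individuals beyond the source carriers with >= 1 haplotype
    matching the consensus (any candidate, when ambiguous).

    Individuals with phase-unknown calls inside the window cannot be
    haplotype-matched and are skipped.
    """
    candidates = (
        consensus.candidates if isinstance(consensus, ConsensusResult) else [consensus]
    )
    if not candidates:
        raise ValidationError("no consensus to scan for")
    idx = candidates[0].marker_indices
    exclude = set(candidates[0].source_carrier_ids)

    haps = cohort.alleles[:, idx, :]  # (n, k, 2)
    match_any = np.zeros((cohort.n_individuals, 2), dtype=bool)
    for cand in candidates:
        for hap in (0, 1):
            match_any[:, hap] |= _matches(haps[:, :, hap], cand.alleles)

    out: list[ScanMatch] = []
    for i, ind in enumerate(cohort.ids):
        if ind in exclude:
            continue
        if not _check_phased(cohort, i, idx):
            continue
        hap_hits = [h for h in (0, 1) if match_any[i, h]]
        if hap_hits:
            out.append(ScanMatch(ind, hap_hits))
    return out


def coarse_sweep(
    cohort: PhasedCohort,
    marker_map: MarkerMap,
    focal: FocalVariant,
    increment_bp: int = 200_000,
    max_length_bp: int = 5_000_000,
) -> SweepResult:
    """Define + scan at window lengths ``increment, 2*increment, ...``.

    Stops when the match set beyond the known carriers becomes empty, when
    no consensus exists any more, or at ``max_length_bp``.
    """
    if increment_bp <= 0:
        raise ValidationError("increment must be positive")
    if max_length_bp < increment_bp:
        raise ValidationError("max window shorter than one increment")
    rows: list[SweepRow] = []
    reason = "max_length"
    length = increment_bp
    while length <= max_length_bp:
        try:
            consensus = define_carrier_haplotype(cohort, marker_map, focal, length)
        except WindowError:
            length += increment_bp
            continue  # window not yet wide enough to contain a marker
        if not consensus.ok:
            reason = "no_consensus"
            break
        matches = scan_cohort(cohort, marker_map, consensus)
        rows.append(
            SweepRow(
                window_length_bp=length,
                n_markers=int(consensus.candidates[0].marker_indices.size),
                consensus=consensus,
                match_ids=[m.individual_id for m in matches],
            )
        )
        if not matches:
            reason = "no_matches"
            break
        length += increment_bp
    result = SweepResult(rows, reason)
    result.verify_nested()
    return result


@dataclass
class FineInterval:
    """Variant-resolution shared interval between two haplotypes.

    ``start_bp``/``end_bp`` span the outermost *matching* markers (the
    conservative inner bound); ``outer_start_bp``/``outer_end_bp`` span the
    innermost mismatching flank markers (or the chromosome-end markers when
    no mismatch was reached), which upper-bounds any clean window.
    """

    empty: bool
    start_bp: int = 0
    end_bp: int = 0
    n_matching_markers: int = 0
    outer_start_bp: int = 0
    outer_end_bp: int = 0

    @property
    def length_bp(self) -> int:
        return 0 if self.empty else self.end_bp - self.start_bp

    @property
    def outer_length_bp(self) -> int:
        return 0 if self.empty else self.outer_end_bp - self.outer_start_bp


def fine_extend(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    marker_map: MarkerMap,
    chrom: str,
    focal_position_bp: int,
) -> FineInterval:
    """Stepwise single-variant extension of the shared haplotype.

    Markers are added in order of increasing physical distance from the
    focal position.  The four closest markers must match, else the interval
    is empty.  A mismatch freezes its side of the extension; the other side
    continues until it mismatches too or the chromosome ends.  Missing
    calls are wildcards.
    """
    idx = marker_map.chrom_indices(chrom)
    if idx.size == 0:
        raise ValidationError(f"no markers on chromosome {chrom!r}")
    positions = marker_map.pos[idx]
    if not (positions[0] <= focal_position_bp <= positions[-1]):
        raise ValidationError(
            f"focal position {focal_position_bp} outside mapped range "
            f"[{positions[0]}, {positions[-1]}] on chromosome {chrom!r}"
        )
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != (idx.size,) or b.shape != (idx.size,):
        raise ValidationError("haplotypes must cover the chromosome's markers")

    ok = (a == b) | (a == MISSING) | (b == MISSING)
    order = _distance_order(positions, focal_position_bp)

    closest = order[: min(4, order.size)]
    if not ok[closest].all():
        return FineInterval(empty=True)

    frozen = {"L": False, "R": False}
    matched_pos: list[int] = []
    outer = {"L": int(positions[0]), "R": int(positions[-1])}
    for rank in order:
        side = "L" if positions[rank] < focal_position_bp else "R"
        if frozen[side]:
            continue
        if ok[rank]:
            matched_pos.append(int(positions[rank]))
        else:
            frozen[side] = True
            outer[side] = int(positions[rank])
            if frozen["L"] and frozen["R"]:
                break

    return FineInterval(
        empty=False,
        start_bp=min(matched_pos),
        end_bp=max(matched_pos),
        n_matching_markers=len(matched_pos),
        outer_start_bp=outer["L"],
        outer_end_bp=outer["R"],
    )


def haplotype_background_frequency(
    cohort: PhasedCohort,
    consensus: ConsensusResult | CarrierHaplotype,
    carrier_ids: list[str] | None = None,
) -> float:
    """Fraction of non-carrier haplotypes matching the consensus.

    ``carrier_ids`` defaults to the consensus' source carriers; pass the
    full (truth) carrier set to measure the genuine background rate.  A
    consensus with zero resolved markers matches vacuously (frequency 1).
    """
    candidates = (
        consensus.candidates if isinstance(consensus, ConsensusResult) else [consensus]
    )
    if not candidates:
        raise ValidationError("no consensus defined")
    exclude = set(
        carrier_ids if carrier_ids is not None else candidates[0].source_carrier_ids
    )
    idx = candidates[0].marker_indices
    keep = [i for i, ind in enumerate(cohort.ids) if ind not in exclude]
    if not keep:
        return 0.0
    haps = cohort.alleles[keep][:, idx, :]
    match = np.zeros((len(keep), 2), dtype=bool)
    for cand in candidates:
        for hap in (0, 1):
            match[:, hap] |= _matches(haps[:, :, hap], cand.alleles)
    return float(match.sum()) / (2 * len(keep))
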