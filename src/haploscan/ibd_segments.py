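"""Pairwise IBD segment calling and sharing summaries.

The caller is a transparent stand-in for likelihood-based kinship tools:
candidate segments are maximal runs of markers without an opposite-
homozygote pair (tolerating a configurable number of them as errors), and
when per-marker allele frequencies are supplied each candidate is refined
to the sub-run maximizing the cumulative log-likelihood ratio of IBD1
versus IBD0 (a max-subarray pass), which pins the boundaries to within a
few markers of the truth.  Input is unphased dosage genotypes, as with
kinship tools; phase is not required for IBD calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import MISSING, MarkerMap
from .errors import ValidationError

__all__ = [
    "IBDParams",
    "IBDSegment",
    "SharingSummary",
    "CalibrationResult",
    "call_ibd_segments",
    "summarize_sharing",
    "relationship_calibration",
]

_LLR_CLIP = 3.0


@dataclass
class IBDParams:
    min_length_bp: float = 2_500_000
    min_markers: int = 100
    max_opposite_homozygotes: int = 1
    ibd2_ibs2_fraction: float = 0.99

    def validate(self) -> None:
        if self.min_length_bp < 0 or self.min_markers < 1:
            raise ValidationError("bad IBD caller thresholds")
        if self.max_opposite_homozygotes < 0:
            raise ValidationError("opposite-homozygote tolerance must be >= 0")


@dataclass
class IBDSegment:
    id_a: str
    id_b: str
    chrom: str
    start_bp: int
    end_bp: int
    state: str  # "IBD1" or "IBD2"
    n_markers: int = 0

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValidationError("segment start must precede end")
        if self.state not in ("IBD1", "IBD2"):
            raise ValidationError(f"bad IBD state {self.state!r}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


def _llr_ibd1_vs_ibd0(ga: np.ndarray, gb: np.ndarray, freq: np.ndarray) -> np.ndarray:
    """Per-marker log-likelihood ratio of the genotype pair under IBD1
    (one shared allele) versus IBD0, clipped to +-``_LLR_CLIP``."""
    f = np.clip(freq, 1e-6, 1 - 1e-6)
    hwe = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])  # (3, m)

    # P(g | one allele fixed to s), s = ref (0) or alt (1)
    cond = np.zeros((2, 3, len(f)))
    cond[0, 0], cond[0, 1] = 1 - f, f
    cond[1, 1], cond[1, 2] = 1 - f, f

    valid = (ga != MISSING) & (gb != MISSING)
    gA = np.where(valid, ga, 0)
    gB = np.where(valid, gb, 0)
    cols = np.arange(len(f))
    p0 = hwe[gA, cols] * hwe[gB, cols]
    p1 = (1 - f) * cond[0, gA, cols] * cond[0, gB, cols] + f * cond[1, gA, cols] * cond[1, gB, cols]
    with np.errstate(divide="ignore"):
        llr = np.log(p1) - np.log(p0)
    llr = np.clip(llr, -_LLR_CLIP, _LLR_CLIP)
    llr[~valid] = 0.0
    return llr


def _max_subarray(x: np.ndarray) -> tuple[float, int, int]:
    """Kadane's algorithm; returns (best sum, first index, last index)."""
    best, best_i, best_j = -np.inf, 0, -1
    cur, cur_i = 0.0, 0
    for j, v in enumerate(x):
        if cur <= 0:
            cur, cur_i = v, j
        else:
            cur += v
        if cur > best:
            best, best_i, best_j = cur, cur_i, j
    return best, best_i, best_j


def _candidate_runs(opp_idx: np.ndarray, n: int, max_opp: int) -> list[tuple[int, int, int]]:
    """Greedy left-to-right merge of opposite-homozygote-free runs into
    candidates with <= ``max_opp`` internal violations.  Returns
    (first marker, last marker, internal violation count) triples."""
    clean: list[tuple[int, int]] = []
    prev = -1
    for o in list(opp_idx) + [n]:
        if o - prev > 1:
            clean.append((prev + 1, o - 1))
        prev = o
    runs: list[tuple[int, int, int]] = []
    for lo, hi in clean:
        if runs and runs[-1][2] < max_opp and runs[-1][1] + 2 == lo:
            plo, _, pv = runs[-1]
            runs[-1] = (plo, hi, pv + 1)
        else:
            runs.append((lo, hi, 0))
    return runs


def call_ibd_segments(
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    marker_map: MarkerMap,
    params: IBDParams | None = None,
    allele_freq: np.ndarray | None = None,
    pair: tuple[str, str] = ("A", "B"),
) -> list[IBDSegment]:
    """Call IBD segments for one pair of individuals.

    ``allele_freq`` (cohort alt-allele frequencies per marker) enables the
    likelihood boundary refinement; without it, segment boundaries are the
    outermost run markers.  Deterministic; symmetric in the two inputs.
    """
    params = params or IBDParams()
    params.validate()
    ga = np.asarray(genotypes_a)
    gb = np.asarray(genotypes_b)
    if ga.shape != (len(marker_map),) or gb.shape != (len(marker_map),):
        raise ValidationError("genotype vectors must match the marker map")
    if allele_freq is not None and np.shape(allele_freq) != (len(marker_map),):
        raise ValidationError("allele frequencies must match the marker map")

    segments: list[IBDSegment] = []
    for chrom in marker_map.chromosomes:
        idx = marker_map.chrom_indices(chrom)
        pos = marker_map.pos[idx]
        a, b = ga[idx], gb[idx]
        valid = (a != MISSING) & (b != MISSING)
        opp = valid & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
        opp_idx = np.flatnonzero(opp)
        llr = (
            _llr_ibd1_vs_ibd0(a, b, np.asarray(allele_freq)[idx])
            if allele_freq is not None
            else None
        )
        for lo, hi, _ in _candidate_runs(opp_idx, idx.size, params.max_opposite_homozygotes):
            if llr is not None:
                score, j0, j1 = _max_subarray(llr[lo : hi + 1])
                if j1 < j0 or score <= 0:
                    continue
                lo, hi = lo + j0, lo + j1
            n_markers = hi - lo + 1
            start, end = int(pos[lo]), int(pos[hi])
            if n_markers < params.min_markers or end - start < params.min_length_bp:
                continue
            seg_valid = valid[lo : hi + 1]
            ibs2 = (a[lo : hi + 1] == b[lo : hi + 1]) & seg_valid
            informative = seg_valid.sum()
            state = (
                "IBD2"
                if informative > 0 and ibs2.sum() / informative >= params.ibd2_ibs2_fraction
                else "IBD1"
            )
            segments.append(
                IBDSegment(pair[0], pair[1], chrom, start, end, state, n_markers)
            )
    return segments


@dataclass
class SharingSummary:
    """Thresholded totals of a pair's IBD segments, in Mb."""

    total_mb_over_hi: float = 0.0
    n_segments_over_hi: int = 0
    longest_mb: float = 0.0
    total_mb_band: float = 0.0
    n_segments_band: int = 0
    hi_threshold_mb: float = 5.0
    lo_threshold_mb: float = 2.5
    focal_segment: IBDSegment | None = None
    genome_fraction: float | None = None

    def to_dict(self) -> dict:
        d = {
            "total_mb_over_hi": round(self.total_mb_over_hi, 1),
            "n_segments_over_hi": self.n_segments_over_hi,
            "longest_mb": round(self.longest_mb, 1),
            "total_mb_band": round(self.total_mb_band, 1),
            "n_segments_band": self.n_segments_band,
            "hi_threshold_mb": self.hi_threshold_mb,
            "lo_threshold_mb": self.lo_threshold_mb,
            "focal_segment": None,
        }
        if self.focal_segment is not None:
            s = self.focal_segment
            d["focal_segment"] = {
                "chrom": s.chrom,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "length_mb": round(s.length_mb, 2),
                "state": s.state,
            }
        return d


def summarize_sharing(
    segments: list[IBDSegment],
    thresholds_mb: tuple[float, float] = (5.0, 2.5),
    focal: tuple[str, int] | None = None,
) -> SharingSummary:
    """Totals and counts per threshold band, longest segment, and the
    segment containing the focal position (if any)."""
    hi, lo = thresholds_mb
    if lo > hi:
        raise ValidationError("band thresholds must satisfy lo <= hi")
    over = [s for s in segments if s.length_mb > hi]
    band = [s for s in segments if lo < s.length_mb <= hi]
    focal_segment = None
    if focal is not None:
        chrom, pos = focal
        for s in segments:
            if s.chrom == chrom and s.start_bp <= pos <= s.end_bp:
                focal_segment = s
                break
    return SharingSummary(
        total_mb_over_hi=sum(s.length_mb for s in over),
        n_segments_over_hi=len(over),
        longest_mb=max((s.length_mb for s in segments), default=0.0),
        total_mb_band=sum(s.length_mb for s in band),
        n_segments_band=len(band),
        hi_threshold_mb=hi,
        lo_threshold_mb=lo,
        focal_segment=focal_segment,
    )


@dataclass
class CalibrationResult:
    """Monte-Carlo sharing estimates for cousin pairs.

    ``mean_fraction`` is the genome fraction with >= 1 shared haplotype
    (expectation ``(1/2) ** (2d)`` for degree-d cousins); in truth mode
    ``mean_allele_fraction`` is the kinship-style sharing proportion that
    half-weights IBD1 (expectation ``2 * (1/2) ** (2d + 2)``, e.g. 1/128
    for third cousins).
    """

    degree: int
    mean_fraction: float
    se_fraction: float
    fractions: np.ndarray = field(repr=False, default=None)
    mean_allele_fraction: float | None = None
    se_allele_fraction: float | None = None


def _cousin_pair_pedigree(degree: int):
    """Pedigree whose last two members are cousins of the given degree
    (0 = full siblings); every non-apex mate is an unrelated founder."""
    from .cohort_sim.pedigree import FEMALE, MALE, Member, Pedigree

    members = [
        Member("A-001", None, None, MALE, "A"),
        Member("A-002", None, None, FEMALE, "A"),
    ]
    if degree == 0:
        members.append(Member("P1", "A-001", "A-002", MALE, "A"))
        members.append(Member("P2", "A-001", "A-002", FEMALE, "A"))
        return Pedigree(members)
    tips = []
    for side in ("L", "R"):
        father, mother = "A-001", "A-002"
        for gen in range(degree):
            child = Member(f"{side}{gen}", father, mother, MALE, "A")
            spouse = Member(f"{side}{gen}s", None, None, FEMALE, "A")
            members += [child, spouse]
            father, mother = child.id, spouse.id
        tips.append((father, mother))
    members.append(Member("P1", tips[0][0], tips[0][1], MALE, "A"))
    members.append(Member("P2", tips[1][0], tips[1][1], FEMALE, "A"))
    return Pedigree(members)


def relationship_calibration(
    degree: int,
    n_pairs: int,
    seed: int,
    genome: list[tuple[str, int]] | None = None,
    cm_per_mb: float = 1.0,
    marker_density_per_mb: float = 0.0,
    use_caller: bool = False,
    params: IBDParams | None = None,
) -> CalibrationResult:
    """Monte-Carlo expectation of the genome fraction shared IBD (>= 1
    haplotype) by cousin pairs of a given degree.

    With ``use_caller=False`` the truth segments are measured directly
    (the analytic expectation for degree d is ``2 * (1/2) ** (2d + 2)``);
    with ``use_caller=True`` the opposite-homozygote caller runs on the
    simulated genotypes, which requires a positive marker density.
    """
    from .cohort_sim.config import SimConfig
    from .cohort_sim.founders import FounderHaplotypes, simulate_founders
    from .cohort_sim.genedrop import gene_drop
    from .datatypes import MarkerMap as _MM

    if degree < 0:
        raise ValidationError("cousin degree must be >= 0 (0 = siblings)")
    if n_pairs < 1:
        raise ValidationError("need at least one pair")
    if use_caller and marker_density_per_mb <= 0:
        raise ValidationError("caller mode needs a positive marker density")

    from .cohort_sim.config import DEFAULT_GENOME

    genome = list(genome) if genome is not None else list(DEFAULT_GENOME)
    pedigree = _cousin_pair_pedigree(degree)
    n_founders = len(pedigree.founders)
    config = SimConfig(
        genome=genome,
        cm_per_mb=cm_per_mb,
        marker_density_per_mb=max(marker_density_per_mb, 1e-9),
        founder_maf_min=0.2,
        founder_maf_max=0.5,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    apex_labels = {0, 1, 2, 3}  # the shared couple is the first two founders
    fractions = np.empty(n_pairs)
    allele_fractions = np.empty(n_pairs) if not use_caller else None
    for k in range(n_pairs):
        if marker_density_per_mb > 0:
            founders = simulate_founders(config, n_founders, rng)
        else:
            empty = _MM(np.empty(0, object), np.empty(0, np.int64), np.empty(0, object))
            founders = FounderHaplotypes(
                np.empty((2 * n_founders, 0), np.int8), np.empty(0), empty
            )
        cohort, truth = gene_drop(pedigree, founders, config, rng)
        if use_caller:
            g = cohort.genotypes()
            ia, ib = cohort.index_of("P1"), cohort.index_of("P2")
            segs = call_ibd_segments(
                g[ia], g[ib], founders.marker_map, params,
                allele_freq=founders.frequencies, pair=("P1", "P2"),
            )
            shared = sum(s.length_bp for s in segs)
            fractions[k] = shared / sum(length for _, length in genome)
        else:
            fractions[k] = truth.shared_fraction("P1", "P2", labels=apex_labels)
            allele_fractions[k] = truth.allele_sharing_fraction(
                "P1", "P2", labels=apex_labels
            )
    se = fractions.std(ddof=1) / np.sqrt(n_pairs) if n_pairs > 1 else float("nan")
    result = CalibrationResult(degree, float(fractions.mean()), float(se), fractions)
    if allele_fractions is not None:
        result.mean_allele_fraction = float(allele_fractions.mean())
        result.se_allele_fraction = (
            float(allele_fractions.std(ddof=1) / np.sqrt(n_pairs))
            if n_pairs > 1
            else float("nan")
        )
    return result
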