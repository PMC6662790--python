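"""Gene dropping: transmit recombined founder haplotypes down a pedigree.

Recombination follows the Haldane (no interference) model: per meiosis and
chromosome the crossover count is Poisson with mean equal to the genetic
length in Morgans (``bp / 1e6 * cm_per_mb / 100``) and crossover positions
are uniform.  Truth IBD records the founder-haplotype origin of every
transmitted segment in 0-based half-open bp coordinates ``[0, length)``;
a marker at 1-based position ``p`` lives at coordinate ``p - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..datatypes import MISSING, PhasedCohort
from ..errors import ValidationError
from .config import SimConfig
from .founders import FounderHaplotypes
from .pedigree import Pedigree

Segment = tuple[int, int, int]  # (start, end, founder_hap_label)

__all__ = ["TruthIBD", "gene_drop"]


def _slice_segments(segments: list[Segment], a: int, b: int) -> list[Segment]:
    out = []
    for s, e, lab in segments:
        lo, hi = max(s, a), min(e, b)
        if lo < hi:
            out.append((lo, hi, lab))
    return out


def _merge_adjacent(segments: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in segments:
        if out and out[-1][2] == seg[2] and out[-1][1] == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


@dataclass
class TruthIBD:
    """Founder origin of every haplotype segment of every individual."""

    segments: dict[str, dict[str, tuple[list[Segment], list[Segment]]]]
    genome: list[tuple[str, int]]

    @property
    def ids(self) -> list[str]:
        return list(self.segments)

    def of(self, individual_id: str, chrom: str, hap: int) -> list[Segment]:
        return self.segments[individual_id][chrom][hap]

    def label_at(self, individual_id: str, chrom: str, hap: int, coord: int) -> int:
        """Founder-haplotype label at 0-based coordinate ``coord``."""
        for s, e, lab in self.of(individual_id, chrom, hap):
            if s <= coord < e:
                return lab
        raise ValidationError(
            f"coordinate {coord} outside chromosome {chrom!r} for {individual_id!r}"
        )

    def segment_at(
        self, individual_id: str, chrom: str, hap: int, coord: int
    ) -> Segment:
        for seg in self.of(individual_id, chrom, hap):
            if seg[0] <= coord < seg[1]:
                return seg
        raise ValidationError(f"coordinate {coord} outside chromosome {chrom!r}")

    def validate_tiling(self) -> None:
        """Check that segments tile each chromosome exactly: contiguous,
        non-overlapping, covering ``[0, length)``."""
        lengths = dict(self.genome)
        for ind, per_chrom in self.segments.items():
            for chrom, pair in per_chrom.items():
                for hap, segs in enumerate(pair):
                    if not segs or segs[0][0] != 0 or segs[-1][1] != lengths[chrom]:
                        raise ValidationError(
                            f"{ind} chr{chrom} hap{hap}: segments do not span chromosome"
                        )
                    for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
                        if e0 != s1:
                            raise ValidationError(
                                f"{ind} chr{chrom} hap{hap}: gap/overlap at {e0}->{s1}"
                            )

    def shared_intervals(
        self,
        id_a: str,
        id_b: str,
        chrom: str,
        labels: set[int] | None = None,
    ) -> list[tuple[int, int]]:
        """Intervals where the pair shares >= 1 founder-haplotype label
        (truth IBD1-or-more), optionally restricted to a label set."""
        pieces: list[tuple[int, int]] = []
        for hap_a in (0, 1):
            segs_a = self.of(id_a, chrom, hap_a)
            by_label_a: dict[int, list[tuple[int, int]]] = {}
            for s, e, lab in segs_a:
                if labels is None or lab in labels:
                    by_label_a.setdefault(lab, []).append((s, e))
            for hap_b in (0, 1):
                for s, e, lab in self.of(id_b, chrom, hap_b):
                    if lab in by_label_a:
                        pieces += _intersect(by_label_a[lab], [(s, e)])
        return _union(pieces)

    def shared_fraction(
        self, id_a: str, id_b: str, labels: set[int] | None = None
    ) -> float:
        """Genome fraction where the pair is truth-IBD (>= 1 shared label)."""
        total = sum(length for _, length in self.genome)
        shared = 0
        for chrom, _ in self.genome:
            shared += sum(e - s for s, e in self.shared_intervals(id_a, id_b, chrom, labels))
        return shared / total

    def _pairing_intervals(
        self, id_a: str, id_b: str, chrom: str, hap_a: int, hap_b: int,
        labels: set[int] | None,
    ) -> list[tuple[int, int]]:
        pieces: list[tuple[int, int]] = []
        by_label: dict[int, list[tuple[int, int]]] = {}
        for s, e, lab in self.of(id_a, chrom, hap_a):
            if labels is None or lab in labels:
                by_label.setdefault(lab, []).append((s, e))
        for s, e, lab in self.of(id_b, chrom, hap_b):
            if lab in by_label:
                pieces += _intersect(by_label[lab], [(s, e)])
        return _union(pieces)

    def allele_sharing_fraction(
        self, id_a: str, id_b: str, labels: set[int] | None = None
    ) -> float:
        """Expected fraction of shared alleles: IBD1 regions count 1/2,
        IBD2 regions count 1 (the kinship-style sharing proportion)."""
        total = sum(length for _, length in self.genome)
        weighted = 0.0
        for chrom, _ in self.genome:
            k1 = self.shared_intervals(id_a, id_b, chrom, labels)
            p00 = self._pairing_intervals(id_a, id_b, chrom, 0, 0, labels)
            p11 = self._pairing_intervals(id_a, id_b, chrom, 1, 1, labels)
            p01 = self._pairing_intervals(id_a, id_b, chrom, 0, 1, labels)
            p10 = self._pairing_intervals(id_a, id_b, chrom, 1, 0, labels)
            k2 = _union(_intersect(p00, p11) + _intersect(p01, p10))
            weighted += 0.5 * sum(e - s for s, e in k1)
            weighted += 0.5 * sum(e - s for s, e in k2)
        return weighted / total


def _meiosis(
    parent_pair: tuple[list[Segment], list[Segment]],
    parent_alleles: np.ndarray,  # (m_c, 2)
    chrom_len: int,
    morgans: float,
    marker_coords: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[Segment]]:
    """One meiosis on one chromosome: returns the transmitted allele vector
    and its truth segments."""
    n_x = int(rng.poisson(morgans))
    breaks = np.sort(rng.integers(1, chrom_len, size=n_x)) if n_x else np.empty(0, np.int64)
    start = int(rng.integers(0, 2))

    source = (np.searchsorted(breaks, marker_coords, side="right") + start) % 2
    alleles = np.where(source == 0, parent_alleles[:, 0], parent_alleles[:, 1])

    bounds = [0, *[int(b) for b in breaks], chrom_len]
    segs: list[Segment] = []
    current = start
    for a, b in zip(bounds, bounds[1:]):
        if a < b:
            segs += _slice_segments(parent_pair[current], a, b)
        current ^= 1
    return alleles.astype(np.int8), _merge_adjacent(segs)


def gene_drop(
    pedigree: Pedigree,
    founders: FounderHaplotypes,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhasedCohort, TruthIBD]:
    """Drop founder haplotypes through the pedigree.

    Founders are assigned haplotype rows ``2i, 2i + 1`` in pedigree order.
    Members are processed in pedigree (topological) order; per non-founder
    the paternal meiosis precedes the maternal one, chromosomes in genome
    order.  Haplotype 0 of every non-founder is paternal.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    founder_members = pedigree.founders
    if founders.n_founders < len(founder_members):
        raise ValidationError(
            f"{len(founder_members)} pedigree founders but only "
            f"{founders.n_founders} simulated founders"
        )

    marker_map = founders.marker_map
    chrom_idx = {c: marker_map.chrom_indices(c) for c, _ in config.genome}
    chrom_coords = {c: marker_map.pos[chrom_idx[c]] - 1 for c, _ in config.genome}

    founder_row = {m.id: 2 * i for i, m in enumerate(founder_members)}
    alleles: dict[str, np.ndarray] = {}
    truth: dict[str, dict[str, tuple[list[Segment], list[Segment]]]] = {}

    for member in pedigree.members:
        cube = np.empty((len(marker_map), 2), dtype=np.int8)
        per_chrom: dict[str, tuple[list[Segment], list[Segment]]] = {}
        if member.is_founder:
            row = founder_row[member.id]
            cube[:, 0] = founders.haplotypes[row]
            cube[:, 1] = founders.haplotypes[row + 1]
            for chrom, length in config.genome:
                per_chrom[chrom] = ([(0, length, row)], [(0, length, row + 1)])
        else:
            for hap, parent_id in ((0, member.father), (1, member.mother)):
                if parent_id not in alleles:
                    raise ValidationError(
                        f"parent {parent_id!r} of {member.id!r} has no haplotypes"
                    )
                parent_cube = alleles[parent_id]
                for chrom, length in config.genome:
                    idx = chrom_idx[chrom]
                    morgans = length / 1e6 * config.cm_per_mb / 100.0
                    transmitted, segs = _meiosis(
                        truth[parent_id][chrom],
                        parent_cube[idx],
                        length,
                        morgans,
                        chrom_coords[chrom],
                        rng,
                    )
                    cube[idx, hap] = transmitted
                    if chrom in per_chrom:
                        per_chrom[chrom] = (per_chrom[chrom][0], segs)
                    else:
                        per_chrom[chrom] = (segs, [])
        alleles[member.id] = cube
        truth[member.id] = per_chrom

    ids = pedigree.ids
    cube_all = np.stack([alleles[i] for i in ids]) if ids else np.empty((0, 0, 2), np.int8)
    cohort = PhasedCohort(ids, cube_all)
    assert not (cube_all == MISSING).any()
    return cohort, TruthIBD(truth, list(config.genome))
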