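"""Core containers shared across modules.

Conventions
-----------
* Marker positions are 1-based base pairs (VCF convention).  Windows and
  internal interval arithmetic are half-open ``[start, end)``.
* Alleles are coded ``0`` (reference), ``1`` (alternative); ``MISSING``
  (``-1``) marks a missing call.
* A diploid individual carries two haplotypes; axis 2 of the allele cube
  indexes them (0 = paternal for simulated data, arbitrary for real data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

MISSING: int = -1

__all__ = ["MISSING", "MarkerMap", "PhasedCohort", "FocalVariant"]


@dataclass
class MarkerMap:
    """Physical map of biallelic markers: chromosome, position, identifier.

    Positions must be strictly increasing within each chromosome and
    chromosomes must be stored in contiguous blocks.
    """

    chrom: np.ndarray  # dtype str/object, shape (m,)
    pos: np.ndarray    # dtype int64, shape (m,), 1-based bp
    ids: np.ndarray    # dtype str/object, shape (m,)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        if not (len(self.chrom) == len(self.pos) == len(self.ids)):
            raise ValidationError("marker map columns have unequal lengths")
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != prev_chrom:
                if c in seen:
                    raise ValidationError(
                        f"chromosome {c!r} appears in non-contiguous blocks"
                    )
                seen.add(c)
                prev_chrom = c
                prev_pos = -1
            if p <= prev_pos:
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {c!r}: "
                    f"{prev_pos} then {p}"
                )
            prev_pos = p

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Indices of all markers on ``chrom`` (in map order)."""
        return np.flatnonzero(self.chrom == chrom)

    def window_indices(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Indices of markers on ``chrom`` with ``start_bp <= pos < end_bp``."""
        mask = (self.chrom == chrom) & (self.pos >= start_bp) & (self.pos < end_bp)
        return np.flatnonzero(mask)

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.chrom[indices], self.pos[indices], self.ids[indices])


@dataclass
class PhasedCohort:
    """Individuals x markers x 2 allele cube with 0/1/``MISSING`` coding.

    ``phased`` flags, per diploid call, whether the two alleles are in known
    phase.  Simulated data is fully phased; VCF input may mix ``|`` and ``/``
    separators.
    """

    ids: list[str]
    alleles: np.ndarray          # (n, m, 2) int8
    phased: np.ndarray | None = None  # (n, m) bool; None means all phased

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValidationError("allele cube must have shape (n, m, 2)")
        if self.alleles.shape[0] != len(self.ids):
            raise ValidationError("id list does not match allele cube")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate individual ids")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValidationError("allele codes outside {0, 1, missing}")
        if self.phased is not None:
            self.phased = np.asarray(self.phased, dtype=bool)
            if self.phased.shape != self.alleles.shape[:2]:
                raise ValidationError("phased flags do not match allele cube")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def index_of(self, individual_id: str) -> int:
        try:
            return self.ids.index(individual_id)
        except ValueError:
            raise ValidationError(f"unknown individual id {individual_id!r}") from None

    def haplotype(self, individual_id: str, hap: int) -> np.ndarray:
        """One haplotype (length-m allele vector) of one individual."""
        if hap not in (0, 1):
            raise ValidationError("haplotype index must be 0 or 1")
        return self.alleles[self.index_of(individual_id), :, hap]

    def genotypes(self) -> np.ndarray:
        """Diploid dosage matrix (n, m): 0/1/2 with ``MISSING`` where any
        allele is missing."""
        a = self.alleles
        g = a[:, :, 0].astype(np.int8) + a[:, :, 1].astype(np.int8)
        g[(a[:, :, 0] == MISSING) | (a[:, :, 1] == MISSING)] = MISSING
        return g

    def subset_individuals(self, keep_ids: list[str]) -> "PhasedCohort":
        idx = [self.index_of(i) for i in keep_ids]
        phased = None if self.phased is None else self.phased[idx]
        return PhasedCohort(list(keep_ids), self.alleles[idx], phased)

    def subset_markers(self, indices: np.ndarray) -> "PhasedCohort":
        phased = None if self.phased is None else self.phased[:, indices]
        return PhasedCohort(list(self.ids), self.alleles[:, indices], phased)

    def allele_frequencies(self) -> np.ndarray:
        """Alternative-allele frequency per marker, over non-missing calls."""
        a = self.alleles
        called = a != MISSING
        num = np.where(called, a, 0).sum(axis=(0, 2))
        den = called.sum(axis=(0, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.maximum(den, 1), np.nan)

    def copy(self) -> "PhasedCohort":
        phased = None if self.phased is None else self.phased.copy()
        return PhasedCohort(list(self.ids), self.alleles.copy(), phased)


@dataclass
class FocalVariant:
    """A variant of interest that is absent from the marker set.

    ``position_bp`` need not coincide with any mapped marker.  The known
    carriers are the individuals whose carrier status has been established
    externally (sequencing in the study design; truth lookup in simulation).
    """

    chrom: str
    position_bp: int
    known_carrier_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValidationError("focal position must be a positive 1-based bp")
        if len(set(self.known_carrier_ids)) != len(self.known_carrier_ids):
            raise ValidationError("duplicate known carrier ids")
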