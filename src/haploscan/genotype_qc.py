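"""Genotype quality control.

Filters are applied in a fixed order: individual call rate, marker call
rate (recomputed on retained individuals), Hardy-Weinberg exact test,
Mendelian-error masking, then ancestry outliers on the first two principal
components.  Genotypes are diploid dosages 0/1/2 with ``MISSING`` (-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .datatypes import MISSING
from .errors import ValidationError

__all__ = [
    "QCReport",
    "QCThresholds",
    "call_rate_filter",
    "hwe_exact_test",
    "mendel_error_scan",
    "apply_mendel_mask",
    "ancestry_outliers",
    "run_qc",
]


@dataclass
class QCThresholds:
    individual_call_rate: float = 0.98
    marker_call_rate: float = 0.98
    hwe_p: float = 1e-6
    pc_sd: float = 6.0
    n_pcs: int = 2

    def validate(self) -> None:
        for name, v in (
            ("individual_call_rate", self.individual_call_rate),
            ("marker_call_rate", self.marker_call_rate),
        ):
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1]")
        if not (0.0 < self.hwe_p <= 1.0):
            raise ValidationError("hwe_p must be in (0, 1]")
        if self.pc_sd <= 0:
            raise ValidationError("pc_sd must be positive")


@dataclass
class QCReport:
    """Every removed entity carries exactly one primary reason."""

    removed_individuals: list[tuple[str, str]] = field(default_factory=list)
    removed_markers: list[tuple[str, str]] = field(default_factory=list)
    mendel_masked: list[tuple[str, str]] = field(default_factory=list)
    ancestry_outliers: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        by_reason: dict[str, int] = {}
        for _, reason in self.removed_individuals:
            by_reason[f"individuals_{reason}"] = by_reason.get(f"individuals_{reason}", 0) + 1
        for _, reason in self.removed_markers:
            by_reason[f"markers_{reason}"] = by_reason.get(f"markers_{reason}", 0) + 1
        by_reason["mendel_masked_calls"] = len(self.mendel_masked)
        by_reason["ancestry_outliers"] = len(self.ancestry_outliers)
        return by_reason

    def to_dict(self) -> dict:
        return {
            "removed_individuals": [list(t) for t in self.removed_individuals],
            "removed_markers": [list(t) for t in self.removed_markers],
            "mendel_masked": [list(t) for t in self.mendel_masked],
            "ancestry_outliers": list(self.ancestry_outliers),
            "counts": self.counts,
        }


def call_rate_filter(
    genotypes: np.ndarray,
    ids: list[str],
    axis: str,
    threshold: float,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Retained indices along ``axis`` ("individuals" rows or "markers"
    columns) with call rate >= ``threshold``, plus removal entries."""
    if genotypes.size == 0:
        raise ValidationError("empty genotype matrix")
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("call-rate threshold must be in (0, 1]")
    if axis == "individuals":
        called = (genotypes != MISSING).mean(axis=1)
        reason = "call_rate_individual"
    elif axis == "markers":
        called = (genotypes != MISSING).mean(axis=0)
        reason = "call_rate_marker"
    else:
        raise ValidationError(f"bad axis {axis!r}")
    if len(ids) != len(called):
        raise ValidationError("id list does not match matrix axis")
    keep = called >= threshold
    removed = [(ids[i], reason) for i in np.flatnonzero(~keep)]
    return np.flatnonzero(keep), removed


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    P-value is the sum of probabilities of all heterozygote counts that are
    no more probable than the observed one, conditional on the allele
    counts (two-sided exact test; the standard formulation for array QC).
    """
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v < 0 or int(v) != v:
            raise ValidationError("genotype counts must be non-negative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValidationError("no genotypes")
    n_alt = n_het + 2 * n_hom_alt
    n_ref = n_het + 2 * n_hom_ref
    rare = min(n_alt, n_ref)

    # P(het = h | n, allele counts) ∝ n! / (nAA! nAB! nBB!) * 2^h
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# Trio rules: a child genotype is inconsistent when it cannot be formed from
# one allele of each parent.  Missing genotypes contribute no constraint.
def _trio_inconsistent(gf: int, gm: int, gc: int) -> bool:
    if gc == MISSING:
        return False
    possible = {
        (f_al, m_al)
        for f_al in _alleles(gf)
        for m_al in _alleles(gm)
    }
    return gc not in {f + m for f, m in possible}


def _alleles(g: int) -> tuple[int, ...]:
    if g == MISSING:
        return (0, 1)  # unconstrained
    return {0: (0,), 1: (0, 1), 2: (1,)}[g]


def mendel_error_scan(
    pedigree,
    genotypes: np.ndarray,
    ids: list[str],
    marker_ids: list[str] | np.ndarray,
) -> list[tuple[str, str]]:
    """Flag (child_id, marker_id) pairs with a biallelic Mendelian
    inconsistency, using whichever parents are present in the matrix."""
    index = {i: k for k, i in enumerate(ids)}
    errors: list[tuple[str, str]] = []
    for member in pedigree.members:
        if member.id not in index:
            continue
        fa = index.get(member.father) if member.father else None
        mo = index.get(member.mother) if member.mother else None
        if fa is None and mo is None:
            continue
        gc = genotypes[index[member.id]]
        gf = genotypes[fa] if fa is not None else np.full_like(gc, MISSING)
        gm = genotypes[mo] if mo is not None else np.full_like(gc, MISSING)

        # Vectorized duo rules (parent hom x child opposite hom), plus the
        # trio-only rules when both parents are typed.
        bad = ((gf == 0) & (gc == 2)) | ((gf == 2) & (gc == 0))
        bad |= ((gm == 0) & (gc == 2)) | ((gm == 2) & (gc == 0))
        both = (gf != MISSING) & (gm != MISSING) & (gc != MISSING)
        bad |= both & (gf == 0) & (gm == 0) & (gc != 0)
        bad |= both & (gf == 2) & (gm == 2) & (gc != 2)
        bad |= both & (((gf == 0) & (gm == 2)) | ((gf == 2) & (gm == 0))) & (gc != 1)
        for j in np.flatnonzero(bad):
            errors.append((member.id, str(marker_ids[j])))
    return errors


def apply_mendel_mask(
    pedigree,
    genotypes: np.ndarray,
    ids: list[str],
    marker_ids: list[str] | np.ndarray,
    errors: list[tuple[str, str]] | None = None,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Mask flagged calls to missing for the full trio at that marker.

    The error's source is unidentifiable, so the child and both typed
    parents are blanked.  Masking only ever removes calls.
    """
    if errors is None:
        errors = mendel_error_scan(pedigree, genotypes, ids, marker_ids)
    index = {i: k for k, i in enumerate(ids)}
    col = {str(m): j for j, m in enumerate(marker_ids)}
    out = genotypes.copy()
    for child_id, marker_id in errors:
        j = col[marker_id]
        member = pedigree.get(child_id)
        for target in (child_id, member.father, member.mother):
            if target is not None and target in index:
                out[index[target], j] = MISSING
    return out, errors


def ancestry_outliers(
    genotypes: np.ndarray,
    ids: list[str],
    n_pcs: int = 2,
    sd_threshold: float = 6.0,
) -> list[str]:
    """Ids scoring > ``sd_threshold`` standard deviations from the mean on
    any of the first ``n_pcs`` principal components.

    Markers are standardized (missing imputed at the marker mean,
    zero-variance markers dropped); the PCA is computed on the cohort
    itself, with no external reference.
    """
    n = genotypes.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 individuals for ancestry PCA")
    if n <= n_pcs:
        raise ValidationError("fewer individuals than requested PCs")
    g = genotypes.astype(float)
    g[genotypes == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    # Columns with no calls at all carry no information.
    mean = np.where(np.isnan(mean), 0.0, mean)
    g = np.where(np.isnan(g), mean, g) - mean
    sd = g.std(axis=0)
    keep = sd > 0
    g = g[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(g, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    flagged: set[int] = set()
    for k in range(min(n_pcs, scores.shape[1])):
        col = scores[:, k]
        spread = col.std()
        if spread == 0:
            continue
        z = np.abs(col - col.mean()) / spread
        flagged |= set(np.flatnonzero(z > sd_threshold))
    return [ids[i] for i in sorted(flagged)]


def run_qc(
    genotypes: np.ndarray,
    ids: list[str],
    marker_ids: list[str] | np.ndarray,
    pedigree=None,
    thresholds: QCThresholds | None = None,
) -> tuple[np.ndarray, list[str], list[str], QCReport]:
    """Full QC pass; returns (masked genotype matrix, retained individual
    ids, retained marker ids, report)."""
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    report = QCReport()
    marker_ids = [str(m) for m in marker_ids]

    rows, removed = call_rate_filter(genotypes, ids, "individuals",
                                     thresholds.individual_call_rate)
    report.removed_individuals += removed
    g = genotypes[rows]
    kept_ids = [ids[i] for i in rows]

    cols, removed = call_rate_filter(g, marker_ids, "markers",
                                     thresholds.marker_call_rate)
    report.removed_markers += removed
    g = g[:, cols]
    kept_markers = [marker_ids[j] for j in cols]

    hwe_keep = []
    for j in range(g.shape[1]):
        col = g[:, j]
        counts = [(col == k).sum() for k in (0, 1, 2)]
        if sum(counts) == 0:
            p = 1.0
        else:
            p = hwe_exact_test(*counts)
        if p < thresholds.hwe_p:
            report.removed_markers.append((kept_markers[j], "hwe"))
        else:
            hwe_keep.append(j)
    g = g[:, hwe_keep]
    kept_markers = [kept_markers[j] for j in hwe_keep]

    if pedigree is not None:
        g, errors = apply_mendel_mask(pedigree, g, kept_ids, kept_markers)
        report.mendel_masked += errors

    outliers = ancestry_outliers(g, kept_ids, thresholds.n_pcs, thresholds.pc_sd)
    report.ancestry_outliers += outliers
    if outliers:
        out_set = set(outliers)
        keep_rows = [i for i, x in enumerate(kept_ids) if x not in out_set]
        report.removed_individuals += [(x, "ancestry") for x in outliers]
        g = g[keep_rows]
        kept_ids = [kept_ids[i] for i in keep_rows]

    return g, kept_ids, kept_markers, report
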