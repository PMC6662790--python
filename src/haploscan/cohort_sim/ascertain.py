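"""Array ascertainment and error injection.

Turns the true phased cohort into something array-like: markers below the
array MAF threshold are dropped, then genotype errors, missingness and
phase switch errors are injected.  Draw order (for reproducibility):
genotype-error mask + affected-allele choice, then missingness mask, then
switch-error mask.

Per-call semantics: a genotype error flips one randomly chosen allele of a
diploid call; a missing event blanks both alleles of a call; a switch error
at marker j swaps the maternal/paternal assignment of an individual from j
onward within the chromosome.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import MISSING, MarkerMap, PhasedCohort
from ..errors import ValidationError
from .config import SimConfig

__all__ = ["ascertain_and_corrupt"]


def ascertain_and_corrupt(
    cohort: PhasedCohort,
    marker_map: MarkerMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhasedCohort, MarkerMap, np.ndarray]:
    """Returns the corrupted array cohort, its marker map, and the indices
    of retained markers (into the input map)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    freqs = cohort.allele_frequencies()
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) >= config.array_maf_min)
    if keep.size == 0:
        raise ValidationError(
            f"array MAF threshold {config.array_maf_min} removed every marker"
        )

    out = cohort.subset_markers(keep)
    out_map = marker_map.subset(keep)
    n, m = out.n_individuals, out.n_markers
    alleles = out.alleles.copy()

    if config.genotype_error_rate > 0:
        err = rng.random((n, m)) < config.genotype_error_rate
        which = rng.integers(0, 2, size=(n, m))
        for hap in (0, 1):
            sel = err & (which == hap) & (alleles[:, :, hap] != MISSING)
            alleles[:, :, hap][sel] = 1 - alleles[:, :, hap][sel]

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        alleles[miss] = MISSING

    if config.switch_error_rate > 0:
        flips = rng.random((n, m)) < config.switch_error_rate
        for chrom, _ in config.genome:
            idx = out_map.chrom_indices(chrom)
            if idx.size == 0:
                continue
            parity = np.cumsum(flips[:, idx], axis=1) % 2 == 1
            block = alleles[:, idx, :]
            swapped = block[:, :, ::-1]
            alleles[:, idx, :] = np.where(parity[:, :, None], swapped, block)

    return PhasedCohort(list(out.ids), alleles), out_map, keep
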