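"""Founder haplotype simulation.

Founder haplotypes are drawn i.i.d. per marker from per-marker allele
frequencies; there is deliberately no background LD, which keeps haplotype
uniqueness analytically computable for the matching tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..datatypes import MarkerMap
from ..errors import ValidationError
from .config import SimConfig

__all__ = ["FounderHaplotypes", "simulate_founders"]


@dataclass
class FounderHaplotypes:
    """2 x n_founders haplotypes over the simulated marker map.

    Row ``2*f`` and ``2*f + 1`` are the two haplotypes of founder ``f``; the
    row index doubles as the founder-haplotype label used in truth IBD
    records.
    """

    haplotypes: np.ndarray   # (2 * n_founders, m) int8
    frequencies: np.ndarray  # (m,) alt-allele frequency each marker was drawn at
    marker_map: MarkerMap

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def labels(self) -> np.ndarray:
        return np.arange(self.haplotypes.shape[0])


def simulate_markers(config: SimConfig, rng: np.random.Generator) -> tuple[MarkerMap, np.ndarray]:
    """Draw marker positions and per-marker alt-allele frequencies."""
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for chrom, length in config.genome:
        if length <= 0:
            raise ValidationError(f"chromosome {chrom!r} has non-positive length")
        n = int(round(config.marker_density_per_mb * length / 1e6))
        n = min(n, length)
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        chroms += [chrom] * n
        positions.append(pos.astype(np.int64))
    pos_all = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    ids = np.array(
        [f"m{c}_{p}" for c, p in zip(chroms, pos_all)], dtype=object
    )
    marker_map = MarkerMap(np.array(chroms, dtype=object), pos_all, ids)
    freqs = rng.uniform(config.founder_maf_min, config.founder_maf_max, len(marker_map))
    return marker_map, freqs


def simulate_founders(
    config: SimConfig,
    n_founders: int,
    rng: np.random.Generator | None = None,
) -> FounderHaplotypes:
    """Simulate ``2 * n_founders`` i.i.d. haplotypes and their marker map."""
    config.validate()
    if n_founders < 1:
        raise ValidationError("need at least one founder")
    if config.marker_density_per_mb <= 0:
        raise ValidationError("marker density must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    marker_map, freqs = simulate_markers(config, rng)
    haps = (rng.random((2 * n_founders, len(marker_map))) < freqs).astype(np.int8)
    return FounderHaplotypes(haps, freqs, marker_map)
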