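import numpy as np
import pytest

from haploscan.cohort_sim import KindredSpec, PedigreeSpec, SimConfig
from haploscan.datatypes import MISSING, MarkerMap, PhasedCohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """One 20 Mb chromosome, light marker density: fast everywhere."""
    return SimConfig(
        genome=[("1", 20_000_000)],
        marker_density_per_mb=30.0,
        pedigree_spec=PedigreeSpec([KindredSpec(generations=3, mean_sibship=2.5)]),
        seed=11,
    )


def make_random_cohort(n_individuals, n_markers, rng, missing_rate=0.0,
                       chrom="1", spacing=10_000):
    """Unstructured random phased cohort + map (no pedigree structure)."""
    alleles = rng.integers(0, 2, size=(n_individuals, n_markers, 2)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n_individuals, n_markers, 2)) < missing_rate
        alleles[mask] = MISSING
    ids = [f"I{i:03d}" for i in range(n_individuals)]
    pos = (np.arange(n_markers) + 1) * spacing
    marker_map = MarkerMap(
        np.array([chrom] * n_markers, dtype=object),
        pos.astype(np.int64),
        np.array([f"m{j}" for j in range(n_markers)], dtype=object),
    )
    return PhasedCohort(ids, alleles), marker_map


def make_cohort_from_haps(hap_rows, chrom="1", spacing=10_000):
    """Cohort from an explicit list of (hap0, hap1) per individual."""
    alleles = np.array(hap_rows, dtype=np.int8).transpose(0, 2, 1)
    n, m, _ = alleles.shape
    ids = [f"I{i:03d}" for i in range(n)]
    pos = (np.arange(m) + 1) * spacing
    marker_map = MarkerMap(
        np.array([chrom] * m, dtype=object),
        pos.astype(np.int64),
        np.array([f"m{j}" for j in range(m)], dtype=object),
    )
    return PhasedCohort(ids, alleles), marker_map
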