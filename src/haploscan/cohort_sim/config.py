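"""Simulation configuration objects.

Everything the simulator does is a pure function of a :class:`SimConfig`;
the same config (including seed) reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import PedigreeError, ValidationError

DEFAULT_GENOME: list[tuple[str, int]] = [
    ("1", 50_000_000),
    ("2", 50_000_000),
    ("3", 50_000_000),
    ("4", 50_000_000),
]


def _check_rate(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must be in [0, 1], got {value}")


@dataclass
class KindredSpec:
    """One recorded kindred: a set of founder couples and their descendants.

    ``generations`` counts generations including the founders, so
    ``generations=1`` yields founders only (no matings).  Sibship sizes are
    Poisson with mean ``mean_sibship``; every child in a non-terminal
    generation marries a fresh, unrelated founder spouse.
    """

    generations: int
    mean_sibship: float = 2.5
    n_founder_couples: int = 1

    def validate(self) -> None:
        if self.generations < 1:
            raise PedigreeError("kindred must have at least 1 generation")
        if self.n_founder_couples < 1:
            raise PedigreeError("kindred needs at least one founder couple")
        if self.mean_sibship < 0:
            raise PedigreeError("mean sibship must be non-negative")
        if self.generations > 1 and self.mean_sibship == 0:
            raise PedigreeError(
                "impossible kindred: zero sibship with more than one generation"
            )


@dataclass
class PedigreeSpec:
    """Recorded kindreds plus unrecorded cross-kindred ancestry.

    ``n_unrecorded_links`` hidden ancestral couples connect kindred founders
    through chains of ``link_meioses_per_side`` unrecorded meioses on each
    side.  With the default of 4 meioses per side the two connected founders
    are third cousins (they share one great-great-grandparental couple and
    no closer ancestor).  With ``shared_ancestor=True`` a single hidden
    couple is the apex of every link, so one unrecorded lineage feeds many
    kindreds — the scenario a drifted founder variant needs.
    """

    kindreds: list[KindredSpec]
    n_unrecorded_links: int = 0
    link_meioses_per_side: int = 4
    shared_ancestor: bool = False

    def validate(self) -> None:
        if not self.kindreds:
            raise PedigreeError("pedigree spec needs at least one kindred")
        for k in self.kindreds:
            k.validate()
        if self.n_unrecorded_links < 0:
            raise PedigreeError("negative link count")
        if self.n_unrecorded_links > 0:
            if self.link_meioses_per_side < 1:
                raise PedigreeError("link depth must be >= 1 meiosis per side")
            if len(self.kindreds) < 2:
                raise PedigreeError("links require at least two kindreds")


@dataclass
class QtcModel:
    """Gaussian QTc phenotype model with incomplete penetrance."""

    carrier_mean_ms: float = 456.0
    noncarrier_mean_ms: float = 413.0
    sd_ms: float = 15.0
    penetrance: float = 0.8

    def validate(self) -> None:
        if self.sd_ms < 0:
            raise ValidationError("QTc sd must be >= 0")
        _check_rate("penetrance", self.penetrance)


@dataclass
class SimConfig:
    """Full recipe for one synthetic isolate cohort."""

    genome: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_GENOME))
    cm_per_mb: float = 1.0
    n_founders: int | None = None  # derived from the pedigree when None
    founder_maf_min: float = 0.05
    founder_maf_max: float = 0.5
    marker_density_per_mb: float = 30.0
    array_maf_min: float = 0.0
    pedigree_spec: PedigreeSpec = field(
        default_factory=lambda: PedigreeSpec([KindredSpec(generations=3)])
    )
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    switch_error_rate: float = 0.0
    qtc_model: QtcModel = field(default_factory=QtcModel)
    seed: int = 0

    def validate(self) -> None:
        if not self.genome:
            raise ValidationError("genome must list at least one chromosome")
        for chrom, length in self.genome:
            if length <= 0:
                raise ValidationError(f"chromosome {chrom!r} has non-positive length")
        if self.cm_per_mb < 0:
            raise ValidationError("cm_per_mb must be >= 0")
        if self.marker_density_per_mb < 0:
            raise ValidationError("marker density must be >= 0")
        if not (0.0 <= self.founder_maf_min <= self.founder_maf_max <= 0.5):
            raise ValidationError(
                "founder MAF spectrum must satisfy 0 <= min <= max <= 0.5"
            )
        _check_rate("array_maf_min", self.array_maf_min)
        _check_rate("genotype_error_rate", self.genotype_error_rate)
        _check_rate("missing_rate", self.missing_rate)
        _check_rate("switch_error_rate", self.switch_error_rate)
        self.pedigree_spec.validate()
        self.qtc_model.validate()


# Named RNG substreams: every stochastic stage draws from its own generator
# derived from (seed, stream index), so adding draws to one stage never
# perturbs another.
_STREAMS = {
    "pedigree": 0,
    "founders": 1,
    "genedrop": 2,
    "ascertain": 3,
    "qtc": 4,
    "misc": 5,
}


def substream(seed: int, name: str, attempt: int = 0) -> np.random.Generator:
    """Deterministic per-stage random generator."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(attempt), _STREAMS[name]])
    )
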