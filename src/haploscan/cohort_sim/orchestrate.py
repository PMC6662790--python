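"""End-to-end cohort simulation.

``simulate_cohort`` wires the pieces together: pedigree, founder haplotypes,
gene drop, variant planting, array ascertainment/corruption and phenotypes.
It can optionally *condition* the draw on the planted variant reaching a
minimum number of kindreds and on every carrier's truth segment extending a
minimum flank on both sides of the locus — i.e. it rejects and redraws
until the simulated history matches the ascertained scenario the analysis
targets (a drifted founder variant segregating in several kindreds).
Rejection is over complete replicates, so accepted cohorts remain exact
draws from the conditional distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datatypes import MarkerMap, PhasedCohort
from ..errors import ValidationError
from .ascertain import ascertain_and_corrupt
from .config import SimConfig, substream
from .founders import FounderHaplotypes, simulate_founders
from .genedrop import TruthIBD, gene_drop
from .pedigree import Pedigree, build_pedigree
from .qtc import simulate_qtc
from .variant import PlantedVariant, plant_variant

__all__ = ["SimResult", "simulate_cohort"]


@dataclass
class SimResult:
    config: SimConfig
    pedigree: Pedigree
    founders: FounderHaplotypes
    truth: TruthIBD
    cohort_true: PhasedCohort   # recorded members, error-free, all markers
    full_map: MarkerMap
    cohort: PhasedCohort        # recorded members, array markers, corrupted
    marker_map: MarkerMap
    variant: PlantedVariant
    ecg: pd.DataFrame
    attempt: int

    @property
    def recorded_carrier_ids(self) -> list[str]:
        recorded = {m.id for m in self.pedigree.recorded_members}
        return [c for c in self.variant.carrier_ids if c in recorded]

    def carriers_by_kindred(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for c in self.recorded_carrier_ids:
            out.setdefault(self.pedigree.get(c).fid, []).append(c)
        return out


def _candidate_labels(
    pedigree: Pedigree, founder_hap_label: int | str | None
) -> list[int] | None:
    """Resolve the requested planting label(s) to founder-haplotype rows.

    ``"link"`` means "any haplotype of a hidden link apex founder"; an int is
    taken literally; ``None`` falls back to the first founder's haplotypes.
    """
    founder_ids = [m.id for m in pedigree.founders]
    if isinstance(founder_hap_label, (int, np.integer)):
        return [int(founder_hap_label)]
    if founder_hap_label == "link":
        rows = []
        for i, m in enumerate(pedigree.founders):
            if not m.recorded and m.fid.startswith("H"):
                rows += [2 * i, 2 * i + 1]
        if not rows:
            raise ValidationError("no hidden link founders to plant on")
        return rows[:4]  # the apex couple's four haplotypes
    if founder_hap_label is None:
        if not founder_ids:
            raise ValidationError("pedigree has no founders")
        return [0, 1]
    raise ValidationError(f"bad founder_hap_label {founder_hap_label!r}")


def _conditions_met(
    pedigree: Pedigree,
    truth: TruthIBD,
    variant: PlantedVariant,
    require_carrier_kindreds: int,
    require_known_kindred_carriers: int,
    min_flank_bp: float,
) -> bool:
    recorded = {m.id for m in pedigree.recorded_members}
    carriers = [c for c in variant.carrier_ids if c in recorded]
    if not carriers:
        return False
    by_kindred: dict[str, int] = {}
    for c in carriers:
        fid = pedigree.get(c).fid
        by_kindred[fid] = by_kindred.get(fid, 0) + 1
    if len(by_kindred) < require_carrier_kindreds:
        return False
    if max(by_kindred.values()) < require_known_kindred_carriers:
        return False
    if min_flank_bp > 0:
        coord = variant.position_bp - 1
        chrom_len = dict(truth.genome)[variant.chrom]
        for c in carriers:
            ok = False
            for hap in variant.carrier_haps[c]:
                s, e, _ = truth.segment_at(c, variant.chrom, hap, coord)
                left_ok = (coord - s) >= min_flank_bp or s == 0
                right_ok = (e - coord) >= min_flank_bp or e == chrom_len
                if left_ok and right_ok:
                    ok = True
                    break
            if not ok:
                return False
    return True


def simulate_cohort(
    config: SimConfig,
    focal_chrom: str | None = None,
    focal_position_bp: int | None = None,
    founder_hap_label: int | str | None = None,
    require_carrier_kindreds: int = 0,
    require_known_kindred_carriers: int = 0,
    min_flank_mb: float = 0.0,
    max_attempts: int = 500,
) -> SimResult:
    """Simulate one cohort, redrawing until the conditioning holds."""
    config.validate()
    if focal_chrom is None:
        focal_chrom = config.genome[0][0]
    lengths = dict(config.genome)
    if focal_chrom not in lengths:
        raise ValidationError(f"unknown focal chromosome {focal_chrom!r}")
    if focal_position_bp is None:
        focal_position_bp = lengths[focal_chrom] // 2

    for attempt in range(max_attempts):
        ped_seed = int(
            np.random.SeedSequence([config.seed, attempt, 97]).generate_state(1)[0]
        )
        pedigree = build_pedigree(config.pedigree_spec, ped_seed)
        founders = simulate_founders(
            config, len(pedigree.founders), substream(config.seed, "founders", attempt)
        )
        cohort_full, truth = gene_drop(
            pedigree, founders, config, substream(config.seed, "genedrop", attempt)
        )
        variant = None
        for label in _candidate_labels(pedigree, founder_hap_label):
            cand = plant_variant(
                truth, label, focal_chrom, focal_position_bp, founders.n_founders
            )
            if _conditions_met(
                pedigree,
                truth,
                cand,
                require_carrier_kindreds,
                require_known_kindred_carriers,
                min_flank_mb * 1e6,
            ):
                variant = cand
                break
        if variant is None:
            continue

        recorded_ids = [m.id for m in pedigree.recorded_members]
        cohort_true = cohort_full.subset_individuals(recorded_ids)
        cohort, marker_map, _ = ascertain_and_corrupt(
            cohort_true,
            founders.marker_map,
            config,
            substream(config.seed, "ascertain", attempt),
        )
        carrier_set = set(variant.carrier_ids)
        flags = np.array([i in carrier_set for i in recorded_ids])
        ecg = simulate_qtc(
            recorded_ids, flags, config.qtc_model, substream(config.seed, "qtc", attempt)
        )
        return SimResult(
            config=config,
            pedigree=pedigree,
            founders=founders,
            truth=truth,
            cohort_true=cohort_true,
            full_map=founders.marker_map,
            cohort=cohort,
            marker_map=marker_map,
            variant=variant,
            ecg=ecg,
            attempt=attempt,
        )
    raise ValidationError(
        f"conditioning not met within {max_attempts} attempts; "
        "relax the requirements or change the pedigree spec"
    )
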