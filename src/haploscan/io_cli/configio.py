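"""YAML configuration parsing for the simulator and the full pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..cohort_sim.config import (
    DEFAULT_GENOME,
    KindredSpec,
    PedigreeSpec,
    QtcModel,
    SimConfig,
)
from ..errors import ValidationError

__all__ = [
    "PipelineConfig",
    "sim_config_from_dict",
    "default_pipeline_config",
    "load_pipeline_config",
]


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d or {})
    ped = d.pop("pedigree", None)
    qtc = d.pop("qtc", None)
    genome = d.pop("genome", None)
    kwargs: dict = {}
    allowed = {
        "cm_per_mb",
        "n_founders",
        "founder_maf_min",
        "founder_maf_max",
        "marker_density_per_mb",
        "array_maf_min",
        "genotype_error_rate",
        "missing_rate",
        "switch_error_rate",
        "seed",
    }
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"unknown simulate keys: {sorted(unknown)}")
    kwargs.update(d)
    if genome is not None:
        kwargs["genome"] = [(str(c), int(length)) for c, length in genome]
    if ped is not None:
        kindreds = [
            KindredSpec(
                generations=int(k.get("generations", 3)),
                mean_sibship=float(k.get("mean_sibship", 2.5)),
                n_founder_couples=int(k.get("n_founder_couples", 1)),
            )
            for k in ped.get("kindreds", [{}])
        ]
        kwargs["pedigree_spec"] = PedigreeSpec(
            kindreds=kindreds,
            n_unrecorded_links=int(ped.get("n_unrecorded_links", 0)),
            link_meioses_per_side=int(ped.get("link_meioses_per_side", 4)),
            shared_ancestor=bool(ped.get("shared_ancestor", False)),
        )
    if qtc is not None:
        kwargs["qtc_model"] = QtcModel(
            carrier_mean_ms=float(qtc.get("carrier_mean_ms", 456.0)),
            noncarrier_mean_ms=float(qtc.get("noncarrier_mean_ms", 413.0)),
            sd_ms=float(qtc.get("sd_ms", 15.0)),
            penetrance=float(qtc.get("penetrance", 0.8)),
        )
    config = SimConfig(**kwargs)
    config.validate()
    return config


@dataclass
class PipelineConfig:
    """Everything one ``run`` needs; built from YAML or defaults."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    # conditioning of the simulated scenario
    require_carrier_kindreds: int = 3
    require_known_kindred_carriers: int = 3
    min_flank_mb: float = 1.5
    # focal variant
    focal_chrom: str | None = None
    focal_position_bp: int | None = None
    founder_hap_label: int | str | None = "link"
    n_known_carriers: int = 3
    # module parameters
    scan_increment_bp: int = 200_000
    scan_max_length_bp: int = 5_000_000
    qc_mind: float = 0.98
    qc_geno: float = 0.98
    qc_hwe: float = 1e-6
    qc_pc_sd: float = 6.0
    ibd_min_mb: float = 2.5
    ibd_min_markers: int = 100
    reference_frequency: float = 8.1e-6
    # file-input mode (bypasses the simulator when vcf is set)
    vcf: str | None = None
    fam: str | None = None
    ecg: str | None = None
    known_carrier_ids: list[str] = field(default_factory=list)


def default_pipeline_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Desk-scale demonstration scenario: six 3-generation kindreds whose
    founders are cryptically connected through one unrecorded couple, a
    variant planted on an apex haplotype, array-like markers."""
    sim = SimConfig(
        genome=list(DEFAULT_GENOME),
        cm_per_mb=0.5,
        founder_maf_min=0.3,
        founder_maf_max=0.5,
        marker_density_per_mb=30.0,
        array_maf_min=0.05,
        pedigree_spec=PedigreeSpec(
            kindreds=[KindredSpec(generations=3, mean_sibship=3.0) for _ in range(6)],
            n_unrecorded_links=6,
            link_meioses_per_side=1,
            shared_ancestor=True,
        ),
        seed=seed,
    )
    cfg = PipelineConfig(seed=seed, sim=sim)
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValidationError(f"unknown pipeline option {key!r}")
        setattr(cfg, key, value)
    return cfg


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    cfg = default_pipeline_config(seed=seed)
    if "simulate" in raw:
        sim_d = dict(raw["simulate"])
        sim_d.setdefault("seed", seed)
        cfg.sim = sim_config_from_dict(sim_d)
    if "conditioning" in raw:
        c = raw["conditioning"]
        cfg.require_carrier_kindreds = int(c.get("carrier_kindreds", cfg.require_carrier_kindreds))
        cfg.require_known_kindred_carriers = int(
            c.get("known_kindred_carriers", cfg.require_known_kindred_carriers)
        )
        cfg.min_flank_mb = float(c.get("min_flank_mb", cfg.min_flank_mb))
    if "focal" in raw:
        f = raw["focal"]
        cfg.focal_chrom = str(f["chrom"]) if "chrom" in f else None
        cfg.focal_position_bp = int(f["position_bp"]) if "position_bp" in f else None
        if "label" in f:
            lab = f["label"]
            cfg.founder_hap_label = lab if lab == "link" else int(lab)
        cfg.n_known_carriers = int(f.get("n_known_carriers", cfg.n_known_carriers))
        cfg.known_carrier_ids = [str(x) for x in f.get("known_carriers", [])]
    if "scan" in raw:
        s = raw["scan"]
        cfg.scan_increment_bp = int(s.get("increment_bp", cfg.scan_increment_bp))
        cfg.scan_max_length_bp = int(s.get("max_length_bp", cfg.scan_max_length_bp))
    if "qc" in raw:
        q = raw["qc"]
        # mind/geno follow the PLINK convention: maximum missing fraction.
        if "mind" in q:
            cfg.qc_mind = 1.0 - float(q["mind"])
        if "geno" in q:
            cfg.qc_geno = 1.0 - float(q["geno"])
        cfg.qc_hwe = float(q.get("hwe", cfg.qc_hwe))
        cfg.qc_pc_sd = float(q.get("pc_sd", cfg.qc_pc_sd))
    if "ibd" in raw:
        b = raw["ibd"]
        cfg.ibd_min_mb = float(b.get("min_mb", cfg.ibd_min_mb))
        cfg.ibd_min_markers = int(b.get("min_markers", cfg.ibd_min_markers))
    if "report" in raw:
        cfg.reference_frequency = float(
            raw["report"].get("reference_frequency", cfg.reference_frequency)
        )
    for key in ("vcf", "fam", "ecg"):
        if key in raw:
            setattr(cfg, key, str(raw[key]))
    return cfg
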