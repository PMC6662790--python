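"""Top-level pipeline: simulate/load -> QC -> sweep -> confirm -> fine
extend -> IBD summaries -> report, with a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..cohort_sim import simulate_cohort
from ..datatypes import MISSING, FocalVariant, MarkerMap, PhasedCohort
from ..errors import HaploscanError, StageError, ValidationError
from ..genotype_qc import QCThresholds, run_qc
from ..haplotype_scan import (
    SweepResult,
    coarse_sweep,
    fine_extend,
    scan_cohort,
)
from ..ibd_segments import IBDParams, call_ibd_segments, summarize_sharing
from ..pheno_stats import carrier_stats
from .configio import PipelineConfig
from .io import (
    read_ecg,
    read_fam,
    read_phased_vcf,
    write_ecg,
    write_fam,
    write_json,
    write_map,
    write_phased_vcf,
    write_truth_ibd,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    known_carrier_ids: list[str]
    nominated: list[str]
    confirmed: list[str]
    sweep: SweepResult
    report: dict
    qc_cohort: PhasedCohort | None = None
    qc_map: MarkerMap | None = None
    sim = None  # SimResult when the input was simulated


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _apply_mask_to_cohort(cohort: PhasedCohort, pedigree, masked: list, marker_ids: list[str]) -> None:
    col = {m: j for j, m in enumerate(marker_ids)}
    idx = {i: k for k, i in enumerate(cohort.ids)}
    for child_id, marker_id in masked:
        j = col[marker_id]
        member = pedigree.get(child_id)
        for target in (child_id, member.father, member.mother):
            if target is not None and target in idx:
                cohort.alleles[idx[target], j, :] = MISSING


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    files: dict[str, str] = {}

    # ---- stage 1: simulate or load -------------------------------------
    sim = None
    truth_carriers: set[str] | None = None
    try:
        if cfg.vcf is not None:
            cohort, marker_map, _ = read_phased_vcf(cfg.vcf)
            pedigree = read_fam(cfg.fam) if cfg.fam else None
            ecg = read_ecg(cfg.ecg) if cfg.ecg else None
            known = list(cfg.known_carrier_ids)
            if not known:
                raise ValidationError("file-input mode needs focal.known_carriers")
            if cfg.focal_chrom is None or cfg.focal_position_bp is None:
                raise ValidationError("file-input mode needs an explicit focal variant")
            focal_chrom, focal_pos = cfg.focal_chrom, cfg.focal_position_bp
            contigs = None
            stages.append("load")
        else:
            sim = simulate_cohort(
                cfg.sim,
                focal_chrom=cfg.focal_chrom,
                focal_position_bp=cfg.focal_position_bp,
                founder_hap_label=cfg.founder_hap_label,
                require_carrier_kindreds=cfg.require_carrier_kindreds,
                require_known_kindred_carriers=cfg.require_known_kindred_carriers,
                min_flank_mb=cfg.min_flank_mb,
            )
            cohort, marker_map, pedigree, ecg = (
                sim.cohort, sim.marker_map, sim.pedigree, sim.ecg,
            )
            focal_chrom, focal_pos = sim.variant.chrom, sim.variant.position_bp
            truth_carriers = set(sim.recorded_carrier_ids)
            by_kindred = sim.carriers_by_kindred()
            best = max(by_kindred, key=lambda k: (len(by_kindred[k]), k))
            known = sorted(by_kindred[best])[: cfg.n_known_carriers]
            contigs = dict(cfg.sim.genome)

            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            write_phased_vcf(inputs / "cohort.vcf", cohort, marker_map, contigs)
            write_map(inputs / "markers.map", marker_map)
            write_fam(inputs / "cohort.fam", pedigree)
            write_ecg(inputs / "ecg.csv", ecg)
            write_truth_ibd(inputs / "truth_ibd.tsv", sim.truth)
            for f in inputs.iterdir():
                files[f"inputs/{f.name}"] = _sha256(f)
            stages.append("simulate")
    except HaploscanError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("simulate", str(exc)) from exc

    # ---- stage 2: QC ----------------------------------------------------
    try:
        genos = cohort.genotypes()
        thresholds = QCThresholds(
            individual_call_rate=cfg.qc_mind,
            marker_call_rate=cfg.qc_geno,
            hwe_p=cfg.qc_hwe,
            pc_sd=cfg.qc_pc_sd,
        )
        marker_ids = [str(m) for m in marker_map.ids]
        _, kept_ids, kept_markers, qc_report = run_qc(
            genos, list(cohort.ids), marker_ids, pedigree, thresholds
        )
        keep_cols = np.array(
            [j for j, m in enumerate(marker_ids) if m in set(kept_markers)]
        )
        qc_cohort = cohort.subset_individuals(kept_ids).subset_markers(keep_cols)
        qc_map = marker_map.subset(keep_cols)
        if pedigree is not None and qc_report.mendel_masked:
            _apply_mask_to_cohort(qc_cohort, pedigree, qc_report.mendel_masked, kept_markers)
        write_json(out / "qc_report.json", qc_report.to_dict())
        files["qc_report.json"] = _sha256(out / "qc_report.json")
        stages.append("qc")
    except HaploscanError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("qc", str(exc)) from exc

    # ---- stage 3: coarse sweep + scan ----------------------------------
    try:
        known = [k for k in known if k in set(kept_ids)]
        if not known:
            raise ValidationError("all known carriers were removed by QC")
        focal = FocalVariant(focal_chrom, focal_pos, known)
        sweep = coarse_sweep(
            qc_cohort, qc_map, focal,
            increment_bp=cfg.scan_increment_bp,
            max_length_bp=cfg.scan_max_length_bp,
        )
        with (out / "sweep.tsv").open("w") as fh:
            fh.write("window_bp\tn_markers\tn_matches\tmatch_ids\n")
            for row in sweep.rows:
                fh.write(
                    f"{row.window_length_bp}\t{row.n_markers}\t"
                    f"{len(row.match_ids)}\t{','.join(row.match_ids)}\n"
                )
        files["sweep.tsv"] = _sha256(out / "sweep.tsv")
        nominated = sweep.nominated()
        stages.append("sweep")
    except HaploscanError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("sweep", str(exc)) from exc

    # ---- stage 4: confirmation (truth lookup in simulation) ------------
    if truth_carriers is not None:
        confirmed = [i for i in nominated if i in truth_carriers]
    else:
        confirmed = list(nominated)
    stages.append("confirm")

    # ---- stage 5: fine extension ---------------------------------------
    try:
        fine_rows = []
        last_row = next((r for r in reversed(sweep.rows) if r.match_ids), None)
        if last_row is not None and confirmed:
            consensus = last_row.consensus
            anchor = consensus.candidates[0]
            anchor_id = anchor.source_carrier_ids[0]
            anchor_hap = qc_cohort.alleles[
                qc_cohort.index_of(anchor_id), :, anchor.chosen_haps[anchor_id]
            ]
            chrom_idx = qc_map.chrom_indices(focal_chrom)
            matches = {
                m.individual_id: m for m in scan_cohort(qc_cohort, qc_map, consensus)
            }
            for ind in confirmed:
                if ind not in matches:
                    continue
                hap_b = qc_cohort.alleles[
                    qc_cohort.index_of(ind), :, matches[ind].hap_indices[0]
                ]
                interval = fine_extend(
                    anchor_hap[chrom_idx], hap_b[chrom_idx], qc_map,
                    focal_chrom, focal_pos,
                )
                fine_rows.append((anchor_id, ind, interval))
        with (out / "fine_intervals.tsv").open("w") as fh:
            fh.write("id_a\tid_b\tstart_bp\tend_bp\tlength_mb\tn_markers\n")
            for id_a, id_b, iv in fine_rows:
                fh.write(
                    f"{id_a}\t{id_b}\t{iv.start_bp}\t{iv.end_bp}\t"
                    f"{iv.length_bp / 1e6:.2f}\t{iv.n_matching_markers}\n"
                )
        files["fine_intervals.tsv"] = _sha256(out / "fine_intervals.tsv")
        stages.append("extend")
    except HaploscanError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("extend", str(exc)) from exc

    # ---- stage 6: IBD sharing ------------------------------------------
    try:
        params = IBDParams(
            min_length_bp=cfg.ibd_min_mb * 1e6, min_markers=cfg.ibd_min_markers
        )
        freqs = qc_cohort.allele_frequencies()
        genos_qc = qc_cohort.genotypes()
        summaries = []
        if known and confirmed:
            ia = qc_cohort.index_of(known[0])
            for ind in confirmed:
                ib = qc_cohort.index_of(ind)
                segs = call_ibd_segments(
                    genos_qc[ia], genos_qc[ib], qc_map, params,
                    allele_freq=freqs, pair=(known[0], ind),
                )
                summary = summarize_sharing(segs, focal=(focal_chrom, focal_pos))
                summaries.append((known[0], ind, segs, summary))
        with (out / "ibd_segments.tsv").open("w") as fh:
            fh.write("id_a\tid_b\tchrom\tstart_bp\tend_bp\tstate\tlength_mb\n")
            for _, _, segs, _ in summaries:
                for s in segs:
                    fh.write(
                        f"{s.id_a}\t{s.id_b}\t{s.chrom}\t{s.start_bp}\t"
                        f"{s.end_bp}\t{s.state}\t{s.length_mb:.1f}\n"
                    )
        write_json(
            out / "ibd_sharing.json",
            {f"{a}|{b}": summary.to_dict() for a, b, _, summary in summaries},
        )
        files["ibd_segments.tsv"] = _sha256(out / "ibd_segments.tsv")
        files["ibd_sharing.json"] = _sha256(out / "ibd_sharing.json")
        stages.append("ibd")
    except HaploscanError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("ibd", str(exc)) from exc

    # ---- stage 7: report ------------------------------------------------
    try:
        all_carriers = sorted(set(known) | set(confirmed))
        labels = None
        ecg_kept = None
        if ecg is not None:
            ecg_kept = ecg[ecg["id"].isin(kept_ids)].reset_index(drop=True)
            carrier_set = set(all_carriers)
            labels = {str(i): str(i) in carrier_set for i in ecg_kept["id"]}
        stats = carrier_stats(
            n_carriers=len(all_carriers),
            n_individuals=len(kept_ids),
            reference_frequency=cfg.reference_frequency,
            ecg=ecg_kept,
            carrier_labels=labels,
        )
        report = {
            "known_carriers": known,
            "nominated": nominated,
            "confirmed": confirmed,
            "carriers_total": all_carriers,
            "stats": stats.to_dict(),
        }
        write_json(out / "report.json", report)
        files["report.json"] = _sha256(out / "report.json")
        stages.append("report")
    except HaploscanError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("report", str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": stages,
        "parameters": {
            "scan_increment_bp": cfg.scan_increment_bp,
            "scan_max_length_bp": cfg.scan_max_length_bp,
            "qc": {
                "individual_call_rate": cfg.qc_mind,
                "marker_call_rate": cfg.qc_geno,
                "hwe_p": cfg.qc_hwe,
                "pc_sd": cfg.qc_pc_sd,
            },
            "ibd": {"min_mb": cfg.ibd_min_mb, "min_markers": cfg.ibd_min_markers},
            "reference_frequency": cfg.reference_frequency,
        },
        "files": files,
    }
    write_json(out / "manifest.json", manifest)

    result = PipelineResult(
        out_dir=out,
        manifest=manifest,
        known_carrier_ids=known,
        nominated=nominated,
        confirmed=confirmed,
        sweep=sweep,
        report=report,
        qc_cohort=qc_cohort,
        qc_map=qc_map,
    )
    result.sim = sim
    return result
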