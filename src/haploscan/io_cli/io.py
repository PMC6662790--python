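"""Readers and writers for the interchange formats.

Phased VCF is the haplotype interchange format (``|``-separated GT);
``/``-separated calls are loaded but flagged phase-unknown, which the
haplotype scan refuses to match.  All coordinates on disk are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ..cohort_sim.genedrop import TruthIBD
from ..cohort_sim.pedigree import Member, Pedigree
from ..datatypes import MISSING, MarkerMap, PhasedCohort
from ..errors import PedigreeError, ValidationError

__all__ = [
    "write_phased_vcf",
    "read_phased_vcf",
    "write_fam",
    "read_fam",
    "write_map",
    "read_map",
    "write_ecg",
    "read_ecg",
    "write_truth_ibd",
    "read_truth_ibd",
]


def write_phased_vcf(
    path: str | Path,
    cohort: PhasedCohort,
    marker_map: MarkerMap,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Biallelic phased VCF (REF=A, ALT=G placeholders; GT only)."""
    path = Path(path)
    lengths = contig_lengths or {}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haploscan\n")
        for chrom in marker_map.chromosomes:
            if chrom in lengths:
                fh.write(f"##contig=<ID={chrom},length={lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.ids)
            + "\n"
        )
        alleles = cohort.alleles
        phased = cohort.phased
        for j in range(len(marker_map)):
            calls = []
            for i in range(cohort.n_individuals):
                a0, a1 = alleles[i, j]
                sep = "|" if phased is None or phased[i, j] else "/"
                s0 = "." if a0 == MISSING else str(int(a0))
                s1 = "." if a1 == MISSING else str(int(a1))
                calls.append(f"{s0}{sep}{s1}")
            fh.write(
                f"{marker_map.chrom[j]}\t{marker_map.pos[j]}\t{marker_map.ids[j]}"
                f"\tA\tG\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def _prevalidate_vcf(path: Path) -> None:
    """Cheap structural pass so malformed lines are reported by number."""
    n_fields = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < 10:
                    raise ValidationError(
                        f"{path}:{lineno}: VCF header has no sample columns"
                    )
                n_fields = len(fields)
                continue
            if n_fields is None:
                raise ValidationError(f"{path}:{lineno}: data before #CHROM header")
            if len(fields) != n_fields:
                raise ValidationError(
                    f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
                )


def read_phased_vcf(path: str | Path) -> tuple[PhasedCohort, MarkerMap, dict]:
    """Load a biallelic VCF into a cohort + marker map.

    Multiallelic records are skipped (counted in the info dict); ``.``
    alleles become missing; ``/``-separated calls are flagged unphased.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    _prevalidate_vcf(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    phased_rows: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        g = np.array(var.genotypes, dtype=np.int64)  # (n, 3): a0, a1, phased
        chroms.append(var.CHROM)
        positions.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        allele_rows.append(g[:, :2].astype(np.int8))
        phased_rows.append(g[:, 2].astype(bool))
    vcf.close()
    if not allele_rows:
        raise ValidationError(f"{path}: no usable biallelic records")
    alleles = np.stack(allele_rows, axis=1)  # (n, m, 2)
    phased = np.stack(phased_rows, axis=1)
    # Homozygous-missing comes back as -1 already; clamp anything negative.
    alleles[alleles < 0] = MISSING
    marker_map = MarkerMap(
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(ids, dtype=object),
    )
    cohort = PhasedCohort(samples, alleles, phased)
    n_missing = int((alleles == MISSING).any(axis=2).sum())
    return cohort, marker_map, {"skipped_multiallelic": skipped, "n_missing_calls": n_missing}


def write_fam(path: str | Path, pedigree: Pedigree, phenotype: dict[str, str] | None = None) -> None:
    """PLINK .fam (FID IID PAT MAT SEX PHENO); recorded members only, with
    links to unrecorded parents written as founders."""
    phenotype = phenotype or {}
    recorded = {m.id for m in pedigree.recorded_members}
    with Path(path).open("w") as fh:
        for m in pedigree.recorded_members:
            pat = m.father if m.father in recorded else "0"
            mat = m.mother if m.mother in recorded else "0"
            pheno = phenotype.get(m.id, "-9")
            fh.write(f"{m.fid} {m.id} {pat or '0'} {mat or '0'} {m.sex} {pheno}\n")


def read_fam(path: str | Path) -> Pedigree:
    """Parse a .fam file; members are re-ordered parents-first.  Parents
    absent from the file are treated as unknown (founder link)."""
    path = Path(path)
    rows: list[tuple[str, str, str, str, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValidationError(f"{path}:{lineno}: expected 6 columns")
            fid, iid, pat, mat, sex = fields[0], fields[1], fields[2], fields[3], fields[4]
            try:
                sex_i = int(sex)
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: bad sex code {sex!r}") from None
            rows.append((fid, iid, pat, mat, sex_i))
    ids = [r[1] for r in rows]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate IID(s): {dup[:5]}")
    present = set(ids)
    members: dict[str, Member] = {}
    for fid, iid, pat, mat, sex_i in rows:
        father = pat if pat != "0" and pat in present else None
        mother = mat if mat != "0" and mat in present else None
        if (father is None) != (mother is None):
            father = mother = None  # single known parent: degrade to founder link
        members[iid] = Member(iid, father, mother, sex_i, fid)

    ordered: list[Member] = []
    placed: set[str] = set()
    pending = list(members.values())
    while pending:
        progress = False
        rest = []
        for m in pending:
            deps = [p for p in (m.father, m.mother) if p is not None]
            if all(d in placed for d in deps):
                ordered.append(m)
                placed.add(m.id)
                progress = True
            else:
                rest.append(m)
        if not progress:
            raise PedigreeError(f"{path}: pedigree contains a cycle")
        pending = rest
    return Pedigree(ordered)


def write_map(path: str | Path, marker_map: MarkerMap) -> None:
    with Path(path).open("w") as fh:
        for c, p, i in zip(marker_map.chrom, marker_map.pos, marker_map.ids):
            fh.write(f"{c}\t{p}\t{i}\n")


def read_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(
        Path(path), sep="\t", header=None, names=["chrom", "pos", "id"],
        dtype={"chrom": str, "id": str},
    )
    return MarkerMap(
        df["chrom"].to_numpy(object),
        df["pos"].to_numpy(np.int64),
        df["id"].to_numpy(object),
    )


def write_ecg(path: str | Path, ecg: pd.DataFrame) -> None:
    ecg[["id", "qt_ms", "rr_s"]].to_csv(Path(path), index=False)


def read_ecg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), dtype={"id": str})
    required = {"id", "qt_ms", "rr_s"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: ECG table needs columns {sorted(required)}")
    if (df["qt_ms"] <= 0).any() or (df["rr_s"] <= 0).any():
        raise ValidationError(f"{path}: QT and RR must be positive")
    return df


def write_truth_ibd(path: str | Path, truth: TruthIBD) -> None:
    with Path(path).open("w") as fh:
        for chrom, length in truth.genome:
            fh.write(f"##genome\t{chrom}\t{length}\n")
        fh.write("#id\tchrom\thap\tstart\tend\tlabel\n")
        for ind in truth.ids:
            for chrom, _ in truth.genome:
                for hap in (0, 1):
                    for s, e, lab in truth.of(ind, chrom, hap):
                        fh.write(f"{ind}\t{chrom}\t{hap}\t{s}\t{e}\t{lab}\n")


def read_truth_ibd(path: str | Path) -> TruthIBD:
    genome: list[tuple[str, int]] = []
    segments: dict = {}
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("##genome"):
                _, chrom, length = line.split()
                genome.append((chrom, int(length)))
                continue
            if line.startswith("#") or not line.strip():
                continue
            ind, chrom, hap, s, e, lab = line.split()
            per = segments.setdefault(ind, {})
            if chrom not in per:
                per[chrom] = ([], [])
            per[chrom][int(hap)].append((int(s), int(e), int(lab)))
    return TruthIBD(segments, genome)


def write_json(path: str | Path, obj) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
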