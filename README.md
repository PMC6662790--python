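# haploscan

Founder-haplotype carrier discovery for isolate cohorts: given phased SNP
array genotypes and a handful of sequencing-confirmed carriers of an
ultra-rare variant that is *absent from the array*, define the shared
carrier haplotype around the locus, scan the whole cohort for it, measure
its extent at single-variant resolution, and summarize identity-by-descent
sharing between the carriers — together with the genotype-QC filters and
the frequency/QTc statistics such a study reports.

Because real cohorts of this kind are not public, the package ships a
first-class synthetic-cohort simulator (`haploscan.cohort_sim`): kindreds
with recorded and *unrecorded* relationships, gene dropping with a Haldane
crossover model and full truth IBD labels, a rare variant planted on one
founder haplotype, array-style marker ascertainment with configurable
genotype/missing/phase-switch errors, and QTc phenotypes with incomplete
penetrance.

## Modules

| module | contents |
| --- | --- |
| `haploscan.cohort_sim` | pedigree builder, founder haplotypes, gene drop + truth IBD, variant planting, array corruption, QTc simulation, conditioned cohort orchestration |
| `haploscan.genotype_qc` | call-rate filters, exact Hardy-Weinberg test, Mendelian-error scan/mask, ancestry-PC outliers, `run_qc` |
| `haploscan.haplotype_scan` | consensus carrier-haplotype definition, cohort scan, coarse incremental-window sweep, variant-resolution fine extension, background haplotype frequency |
| `haploscan.ibd_segments` | opposite-homozygote IBD caller with likelihood boundary refinement, sharing summaries, cousin-pair calibration |
| `haploscan.pheno_stats` | Bazett QTc, carrier allele frequency, fold enrichment, per-group QTc summaries and penetrance |
| `haploscan.io_cli` | phased VCF / .fam / map / ECG / truth readers and writers, YAML config, CLI, full pipeline with run manifest |

## CLI

```sh
haploscan simulate --out simdir --seed 1            # synthetic cohort + truth
haploscan qc      --vcf simdir/cohort.vcf --fam simdir/cohort.fam --out qcdir
haploscan scan    --vcf simdir/cohort.vcf --focal 1:25000000 \
                  --carriers ID1,ID2,ID3 --increment 200000 --max 5000000 --out scandir
haploscan extend  --vcf simdir/cohort.vcf --focal 1:25000000 --pair ID1:1,ID9:2 --out extdir
haploscan ibd     --vcf simdir/cohort.vcf --pairs ID1,ID9 --min-mb 2.5 --out ibddir
haploscan report  --ecg simdir/ecg.csv --carriers carriers.txt --cohort-n 2011 --out repdir
haploscan run     --out rundir --seed 1             # full pipeline (simulate → report)
```

`run` and `simulate` accept `--config <yaml>`; see
`haploscan.io_cli.configio.load_pipeline_config` for the schema.  Exit
codes: 0 success, 2 validation error, 3 stage failure.

The full pipeline mirrors the study design: simulate (or load) → QC →
coarse sweep for the carrier haplotype → nomination and (in simulation)
truth-lookup confirmation → fine extension of the shared haplotype → IBD
sharing summaries → statistical report, writing a machine-readable
`manifest.json` with parameters and file digests; identical seeds give
identical digests.

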