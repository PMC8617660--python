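# bsaqtl

Bulked-segregant QTL mapping toolkit for backcross (BC1) populations:

* **`bsaqtl.synthetic_cross`** — simulates a BC1 population segregating a
  dominant, quantitatively penetrant restorer locus (fertility grades 0–4),
  draws phenotypic extreme bulks (default 30 + 30 plants), simulates pooled
  read counts, and emits a 4-sample VCF (two parents + two bulks) with a
  ground-truth sidecar.
* **`bsaqtl.variant_screen`** — reads the multi-sample VCF, applies GATK-style
  site hard filters (QUAL < 30, QD < 13, FS > 20, MQ < 20, rank sums < −3) and
  four genotype screening rules (homozygous parents, differing parents,
  sterile bulk matching the recurrent parent, bulk depth within [10, 100]),
  and writes a polarized donor/other allele-depth table.
* **`bsaqtl.bsa_statistics`** — the three genome scans: delta SNP-index with
  Monte-Carlo confidence bands per read depth, the G statistic tricube-smoothed
  to G′ with a Hampel-trimmed log-normal null and Benjamini–Hochberg FDR
  (default q ≤ 0.01, 1 Mb window), and ED⁵ with per-chromosome loess fitting
  thresholded at median + 3 SD.
* **`bsaqtl.qtl_call`** — interval calling (runs of consecutive significant
  SNPs), cross-method consensus, and gene-annotation intersection (GFF3/BED)
  with boolean attribute filters and per-gene variant counts.
* **`bsaqtl.cli` / `bsaqtl.pipeline`** — a `bsaqtl` command with `simulate`,
  `filter`, `scan`, `call`, and `run` subcommands, YAML config, and a
  reproducibility manifest.

## CLI usage

```sh
# full pipeline on a simulated dataset
bsaqtl init-config --out config.yaml   # optional: edit defaults
bsaqtl run --config config.yaml --seed 7 --out results/run1

# or stage by stage
bsaqtl simulate --seed 7 --out work/
bsaqtl filter --vcf work/simulated.vcf --donor P596 --recurrent P1318 \
    --fbulk F_bulk --sbulk S_bulk --out-snps work/snps.tsv
bsaqtl scan --snps work/snps.tsv --window 1000000 --fdr 0.01 \
    --ed-exponent 5 --seed 7 --out-track work/track.tsv \
    --out-thresholds work/thresholds.json
bsaqtl call --track work/track.tsv --thresholds work/thresholds.json \
    --gff annotation.gff3 --min-methods 2 --min-run 10 --out-dir work/called
```

All artifacts are plain TSV/JSON/VCF text.  Exit codes: 0 ok, 2 config
error, 3 data error.

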