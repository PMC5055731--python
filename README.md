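# metharray

Evaluation toolkit for Infinium-style DNA methylation arrays. It
re-implements, as a reusable Python package, the probe-level quality
screens and platform-evaluation analyses used to assess methylation
BeadChips against whole-genome bisulphite sequencing (WGBS):

- **`metharray.synthetic`** — generates every input with known ground
  truth: a genome with CpG islands, CpG-sparse regulatory regions and
  planted near-identical duplications; an array manifest; a VCF of
  variants; two-group intensity matrices; WGBS count tables.
- **`metharray.manifest`** — probe data model (Type I/II chemistry, 50-bp
  footprints, single-base-extension positions, 48/49-bp probe bodies),
  manifest CSV I/O, platform comparison with odds-ratio enrichment tests.
- **`metharray.crossreact`** — four in-silico bisulfite-converted genomes
  (plus/minus × unmethylated/CpG-methylated) and a seed-and-extend scanner
  that flags probes with ≥47 matched bases at off-target windows.
  Detection is provably complete down to 46/50 with the default seeds.
- **`metharray.variants`** — MAF-filtered variant overlap classification
  into target-CpG / SBE / probe-body categories.
- **`metharray.annotation`** — promoter/gene-body/intergenic and
  island/shore/open-sea context assignment, ≥1/≥2/≥3 coverage
  stratification of regulatory catalogs, specific/common DHS split.
- **`metharray.methstats`** — β-values (`M/(M+U+100)` after
  negative-control background correction), detection p-values, M-values,
  moderated-t differential methylation calling with empirical-Bayes
  variance shrinkage, cross-platform DMP agreement.
- **`metharray.dhs`** — region-level methylation at distal regulatory
  elements (pooled-ratio for WGBS, probe-mean for arrays),
  methylation-vs-open-chromatin log-odds, cross-platform concordance and
  disagreement typing (probe positioning vs technical artifact).

Coordinates are 0-based half-open internally; 1-based manifest positions
(`MAPINFO`) are converted at the I/O boundary. All generators are
deterministic: one RNG stream per generator, derived from the master seed
by a stable label.

## CLI

```bash
metharray simulate --seed 1 --outdir data/           # synthetic dataset + ground truth
metharray manifest-stats data/manifest.csv --compare other_manifest.csv
metharray crossreact --genome data/genome.fa --manifest data/manifest.csv --threshold 47
metharray variants --manifest data/manifest.csv --vcf data/variants.vcf --maf 0.05
metharray coverage --manifest data/manifest.csv --annot annot.yaml
metharray beta --meth data/intensities_meth.csv --unmeth data/intensities_unmeth.csv \
    --control-meth data/controls_meth.csv --control-unmeth data/controls_unmeth.csv --out beta.tsv
metharray dmp --beta beta.tsv --groups groups.csv --out dmps.tsv
metharray dmp-agree --a dmps_a.tsv --b dmps_b.tsv
metharray dhs-concordance --regions data/dhs_distal.bed --wgbs data/wgbs_counts.tsv \
    --beta beta.tsv --manifest data/manifest.csv
```

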