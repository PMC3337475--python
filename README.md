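# crmkit

Toolkit for regulatory-motif analysis in compact promoters: position weight
matrix (PWM) scanning with exact score-distribution cutoffs, ALLR-based
consolidation of redundant motif matrices, prediction of cis-regulatory
modules (CRMs) from binding-site density Z-score peaks, motif–phenotype
association statistics (occupancy, correlation screening, expression
coherence, hypergeometric/Fisher enrichment), overlap-based evaluation of
predicted modules with a random-placement null, ortholog/promoter
preparation utilities, and seeded synthetic-data generators so every
pipeline runs end to end without external downloads.

## Modules

| module | contents |
| --- | --- |
| `crmkit.pwm_core` | `CountMatrix`, `Background`, `PWM`, `SiteHit`; log-odds conversion, single-site scoring, both-strand scanning, exact-DP default cutoffs |
| `crmkit.motif_compare` | per-column ALLR, optimal ungapped matrix alignment over offsets/orientations, redundancy test (ALLR > 6.57, OLAP > 68.1 %), greedy consolidation |
| `crmkit.cermod_detect` | per-position site coverage, per-sequence Z profiles, peak calling at Z ≥ 3.09, gap-bounded (< 30 bp) peak extension, `predict_modules` |
| `crmkit.association` | occupancy = Σ e^score over both strands, Pearson/t screening, expression coherence with Monte-Carlo p, hypergeometric enrichment with child-term propagation, Fisher exact tests, Bonferroni correction |
| `crmkit.evaluation` | sensitivity/PPV against experimental modules, size-range filtering (27–580 bp), random-placement significance simulation |
| `crmkit.genome_prep` | reciprocal-best-hit ortholog calling (E < 1e-10, coverage ≥ 60 % of at least one protein), promoter extraction (≤ 2 kb, truncated at neighbor genes), operon-first filtering |
| `crmkit.synth` | seeded generators: promoters with chosen GC, planted motif sites, planted coherent expression clusters, assay vectors with target correlation |
| `crmkit.io_cli` | FASTA/BED6/bedGraph/TSV/matrix-text/TRANSFAC readers and writers (all coordinates 0-based half-open internally) and the `crmkit` CLI |

## CLI

`crmkit` exposes subcommands `scan`, `consolidate`, `cermod`, `occupancy`,
`coherence`, `enrich`, `eval`, `simulate`, and `synth`.  A self-contained
demo:

```sh
crmkit synth --out-dir fixture --seed 1
crmkit cermod --fasta fixture/promoters.fasta --matrices fixture/matrices.txt \
    --out-bed modules.bed --out-tsv modules.tsv --gc 0.36 --site-p 1e-5
crmkit eval --pred modules.bed --exp fixture/experimental_modules.bed --out eval.json
crmkit simulate --pred modules.bed --exp fixture/experimental_modules.bed \
    --promoter-lens fixture/promoter_lengths.tsv --out sim.json --seed 1
```

Seeds are always explicit flags and are logged to stderr.

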