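# pleioscan

Cross-trait pleiotropy scanning from GWAS summary statistics.

`pleioscan` asks whether two correlated phenotypes — the motivating case is a
schizophrenia-like binary diagnosis and nicotine-dependence-like quantitative
traits (FTND score, plasma cotinine, time-to-first-cigarette) — share genetic
liability, and if so, which variants, genes and pathways carry it.  It
implements:

- **Reciprocal polygenic risk scores.**  One trait's per-variant effect sizes
  weight allele dosages in the other trait's cohort,
  `score_i = Σ_j dosage_ij · w_j / (2 M_i)`, at the inclusion-threshold ladder
  P ≤ 5×10⁻⁵ … 5×10⁻¹; prediction is tested by linear or logistic regression
  with sex, age and study covariates, reporting incremental R² or Nagelkerke
  R².
- **A weakest-link joint ("overlap") test.**  For m traits with
  background-adjusted per-variant P-values P₁…P_m (genomic control,
  λ = median(z²)/median(χ²₁), never deflating), the overlap statistic is
  r = max_j P_j and, under independent nulls, P(R ≤ r) = rᵐ.  The construction
  requires *every* trait to support a variant: at genome-wide α = 5×10⁻⁸ with
  m = 2, both traits must beat α^(1/2) ≈ 2.2×10⁻⁴, which is also the
  worst-case per-variant false-positive rate when one trait carries an extreme
  signal.  Overlap P-values get Benjamini–Hochberg q-values; variants at
  q ≤ 0.05 are chained into loci, and a q ≤ 0.16 tier (the upper-tail χ²₁
  probability of a factor-2 AIC penalty) feeds the pathway stage.
- **Gene and pathway analysis.**  Candidate markers map to the containing
  gene, else the nearest gene within 50 kb; per-trait gene lists merge by a
  2-of-k rule; the seven strongly linked HLA genes are removed; pathway
  over-representation uses the hypergeometric upper tail with the ≥3
  list-genes / ≤300 reference-genes filters and BH adjustment; crosstalk
  between enriched pathways counts PPI edges joining their gene sets against
  a size-matched permutation null (pairs kept at permutation P < 0.05).
- **A synthetic-data generator.**  Hardy–Weinberg genotypes, a liability-
  threshold binary trait, correlated shared effect sizes, per-variant
  OLS/logistic scans, and matching gene/GMT/PPI annotations, so the whole
  analysis runs end to end with no external data.

## Worked example

The bundled demo simulates one binary-trait GWAS cohort and three
quantitative-trait cohorts (n = 2,000 each; 3,000 variants; 120 causal per
trait, 50 shared with effect correlation 0.8) and runs every stage:

```bash
pleioscan run --config examples/demo.cfg
```

```
INFO pleioscan: joint scan: 3000 variants, lambdas=['1.023', '1.029'], 11 loci at q<=0.05, 13 candidates at q<=0.16
INFO pleioscan: joint smoke1: 3000 shared variants (0 dropped), 11 loci, 13 candidates
...
INFO pleioscan: pathways: 13 merged genes (>=2 traits), 13 after HLA filter
INFO pleioscan: pipeline complete: 22 files in demo_out
```

The genomic-control λ near 1 says the scans are well calibrated; 11 loci pass
q ≤ 0.05 in the first trait pair — each a chain of shared-association
variants with its lead variant and nearest gene listed in
`loci_smoke1.tsv`:

```
LEAD_SNP  CHR  START    END      N_MARKERS  GENE
rs12      1    120000   120000   1          G2
rs1856    1    18560000 18560000 1          G243
```

`prs_nd_to_scz.tsv` shows the quantitative trait's risk scores predicting
the binary diagnosis (Wald statistic and Nagelkerke R² per threshold):

```
threshold  beta       se         stat       p            r2           n_markers
5e-05      19.975387  2.5782009  7.7478008  9.3497673e-15  0.043978268  17
0.0005     22.869334  3.036604   7.5312206  5.026816e-14   0.041571955  21
0.005      37.844399  5.8367384  6.4838264  8.942513e-11   0.030567252  51
```

Strong prediction already at the strictest thresholds reflects the simulated
architecture, where the shared causal variants carry detectable per-variant
signal.  Every output table, with a SHA-256 checksum per file, is listed in
`demo_out/manifest.json`; identical config + seed reproduces identical
checksums.

Each stage is also exposed standalone (`pleioscan simulate / prs / joint /
pathways`) and as library functions (`pleioscan.run_joint_scan`,
`pleioscan.compute_risk_scores`, ...).

## Layout

```
src/pleioscan/
  sumstats_io.py     summary-statistics / BED / GMT / PPI I-O, harmonization
  synthetic_data.py  cohort, scan and annotation simulation
  prs.py             risk scores and reciprocal prediction
  joint_test.py      weakest-link overlap test, FDR, locus merging
  gene_pathway.py    gene mapping, enrichment, crosstalk network
  pipeline.py        orchestration, config, manifest
  cli.py             command-line interface
docs/methods.md      model, assumptions, parameter choices, limitations
```
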