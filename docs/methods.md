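# Methods

## The overlap test

For each variant and each of m traits, the inputs are association Z-scores
from that trait's GWAS.  Each trait's statistics are first background-adjusted
by genomic control: λ = median(z²) / median(χ²₁), with the exact χ²₁ median
(0.4549…), adjusted χ² = z²/max(λ, 1), and adjusted P from the χ²₁ upper
tail.  λ < 1 is reported but not applied — deflation would anti-conservatively
sharpen every test.  With fewer than 100 variants the median is too unstable
to estimate inflation and the adjustment is skipped with a warning.

The overlap statistic is the weakest link r = max_j P_j.  Its null
distribution under independent trait tests is P(R ≤ r) = rᵐ, evaluated in
log space; P-values are floored at 10⁻³⁰⁰ throughout so that squaring cannot
underflow to zero.  An empirical-null option replaces each uniform marginal
with the trait's own genome-wide ECDF of adjusted P-values (floored at
1/(n+1)); it is appropriate when a trait's P distribution is visibly
non-uniform after adjustment, and reduces to rᵐ for uniform inputs.  An
alternative min-based statistic exists behind an option but is excluded from
all default analyses: it is dominated by single-trait signal, the opposite
of what a pleiotropy screen wants.

Two consequences of the max construction are worth stating.  At an overall
level α every trait must individually beat α^(1/m) (≈ 2.2×10⁻⁴ for
α = 5×10⁻⁸, m = 2); and when m−1 traits carry arbitrarily extreme signal,
the per-variant false-positive rate is bounded by that same α^(1/m), the
worst case of the method.  A variant that is genome-wide significant in one
trait but indifferent in the other (say P = 10⁻¹⁵ and 0.2) gets r = 0.2 and
overlap P = 0.04 — far from survival under multiplicity — so one-trait hits
are excluded implicitly, with no explicit pre-filter needed (one is available
behind a flag, default off).

Overlap P-values receive Benjamini–Hochberg step-up q-values (statsmodels).
Variants at q ≤ 0.05 are chained into loci: consecutive significant variants
on a chromosome join one locus while gaps stay within the merge window
(default 250 kb — no standard exists, and with independent simulated
variants any window that spans adjacent planted signals works; it is
configurable for real, LD-structured data).  The locus lead is the smallest
overlap P, ties broken to the smaller position.  A looser q ≤ 0.16 tier
supplies candidate markers for the pathway stage; 0.16 is the upper-tail χ²₁
probability at 2, i.e. the significance level at which a 1-df likelihood-
ratio test just offsets a factor-2 AIC penalty.

Trait tests are assumed independent, as in any analysis of GWAS from
non-overlapping cohorts; no sample-overlap correction is implemented.  This
is a documented limitation, not a default to rely on when cohorts share
controls.

## Risk scores

Scores use the average-per-allele convention: the sum of dosage × weight over
markers passing the source-trait P threshold, divided by 2·M_i where M_i is
the individual's count of non-missing scored markers.  Any affine rescaling
of the score leaves the regression statistic, P-value and variance explained
unchanged, so the choice among scoring conventions is inferentially neutral;
this one keeps scores comparable across individuals with missing genotypes.
Missing dosages drop out of both numerator and M_i (no mean imputation).
Thresholds passed by zero markers yield flagged, undefined scores and the
regression skips them.

Prediction regresses the target phenotype on the score with sex, age and
study-indicator covariates.  Variance explained is the incremental R² over
the covariates-only model (linear) or Nagelkerke's R²,
(1 − (L₀/L₁)^(2/n)) / (1 − L₀^(2/n)), with L₀ the covariates-only likelihood
(logistic).  Whether published threshold tables report incremental or
score-only R² is generally ambiguous; the incremental convention is used and
flagged here.  Complete separation in a logistic fit is caught and reported
as r² = 1 with an unreliable (NaN) P and a `separation` flag.

No LD clumping or pruning precedes scoring and no best-threshold selection is
performed; all five thresholds are reported.

## Synthetic data

The generator draws independent variants (no LD) on one linear
pseudo-chromosome, spaced 10 kb apart, with MAF uniform on [0.05, 0.5] and
Hardy–Weinberg binomial genotypes.  The quantitative trait is
Σ dosage·effect + covariate terms + N(0,1).  The binary trait thresholds a
latent liability (genetic + covariate + N(0,1)) at the (1−prevalence)
quantile of its model-implied distribution, so the realized case fraction
matches the prevalence up to binomial noise.  Shared causal variants draw
effect pairs from a bivariate normal with the configured correlation;
trait-specific causal variants draw independently.  Covariates are
sex ~ Bernoulli(0.5), age ~ uniform integers 18–70, study ~ 3-level
categorical, entering both traits.  Scans are exact per-variant OLS
(Frisch–Waugh residualization) or maximum-likelihood logistic regression
(vectorized Newton–Raphson; both verified against statsmodels to machine
precision on fixtures).  The binary scan runs on the population sample
rather than a case-control ascertainment, because downstream calibration
tests need honest nulls more than realistic enrichment.

Default cohort conditions, chosen once as a realistically powered desk-scale
architecture: n = 2,000 individuals, 3,000 variants, 120 causal per trait of
which 50 shared with effect correlation 0.8, effect SD 0.12 per allele copy
(liability heritability ≈ 0.3), prevalence 0.30.  Under these conditions
individual shared variants are detectable and the joint scan recovers
locus-level sharing.

The reciprocal risk-score arm uses a separate, deliberately diffuse
architecture (`PRS_STUDY_CONFIG`): 1,200 variants, 80 causal per trait, 50
shared, effect SD 0.06, GWAS cohorts of 2,000 and held-out target cohorts of
8,000, no individual reused across cohorts.  This emulates the regime the
method faces in practice — per-variant statistics mostly indistinguishable
from noise, aggregate shared signal well above the ~1/n incremental-R² noise
floor.  One real-data pattern is *not* reproduced at this scale: a strictly
monotone rise of r² across all five thresholds requires millions of markers
and 10⁴–10⁵ samples so that signal accrues faster than null-marker dilution
at every step; desk-scale profiles are hump-shaped and seed-noisy.  The
simulation checks therefore target what is identifiable here: detection of
sharing in both directions, monotone growth of mean r² in the shared-effect
correlation, and null calibration at zero sharing.

Annotations are generated on the same chromosome: non-overlapping gene
intervals with random lengths (5–30 kb) and gaps (0–120 kb, so variants fall
inside genes, within the 50-kb flank, or beyond); pathways as sampled gene
subsets, with the first `n_enriched_pathways` over-sampling causal-variant-
containing genes by a configurable factor; a PPI graph that is Erdős–Rényi
over genes plus optional extra within-pathway edges.  Passing one cohort's
`truth` table into further cohorts reuses the causal architecture with fresh
individuals, which is how multiple GWAS of the same traits are emulated.

What passing tests on these data do **not** show: robustness to LD (locus
merging and gene assignment on real data inherit LD structure), to
population stratification beyond genomic control, to allele-frequency
mismatch between cohorts, or to sample overlap between trait GWAS.

## Gene and pathway stage

A marker inside a gene belongs to that gene; otherwise it is assigned to the
nearest gene boundary within 50 kb on either side, else unmapped.
Containment beats proximity when genes overlap, and exact distance ties
break toward the smaller gene start — an arbitrary but deterministic rule.
Genes count once per trait list no matter how many markers hit them.  Lists
merge by presence in ≥ 2 trait lists (configurable), and the seven
classical HLA genes (HLA-B, -C, -DOA, -DQA1, -DQB1, -DRB1, -G) are removed
by exact match before testing, since their strong mutual LD makes their
joint appearance uninformative.

Enrichment is the one-sided hypergeometric upper tail P(X ≥ k) with N the
size of the supplied reference universe — all genes of the annotation in
use, never a hardcoded genome count — K the pathway's reference genes, n the
query list, k the overlap.  Pathways with k < 3 or K > 300 are excluded
before BH adjustment; significance is adjusted P < 0.05.

Pathway crosstalk scores an unordered pair of enriched pathways by the
number of PPI edges with one endpoint in each pathway's observed gene set
(a gene in both sets contributes through its incident edges; self-loops are
dropped on input).  The null redraws two uniform random gene sets of the
same sizes from the PPI node universe n_perm times (default 1,000);
perm P = (1 + #{null ≥ observed}) / (n_perm + 1), so the smallest reportable
value is 1/(n_perm+1) and an observed score of 0 always yields P = 1.  Pairs
with perm P < 0.05 are retained.  This between-set edge count with a
size-matched permutation null is this package's own crosstalk definition —
a deliberately simple, fully specified score occupying the usual
crosstalk-network interface (node weight = enrichment adjusted P, edge
weight = permutation P).

## Numerical choices and degenerate inputs

- Z ↔ P conversion through the two-sided normal tail in log space; P floored
  at 10⁻³⁰⁰; the conversion is an involution to 10⁻⁶ relative for |z| ≤ 37.
- Coordinates 1-based inclusive everywhere; BED converted on read;
  chromosome labels stripped of `chr`, X stored as 23 for numeric sorting.
- Harmonization negates effects for swapped alleles, reconciles strand
  flips via base complements, drops strand-ambiguous A/T and C/G variants
  (no allele frequencies are available to resolve them) and drops
  irreconcilable allele pairs with a logged reason rather than failing.
- Monomorphic variants scan to z = 0, P = 1 with a flag; they cannot carry
  association and excluding them silently would change marker counts.
- Logistic scan Newton steps are clipped to ±4 to survive
  quasi-separation; standard errors come from the observed information at
  the optimum.
- BH q-values, hypergeometric tails and χ² quantiles come from statsmodels
  and scipy; the package's own tests check them against hand-computed
  step-up and exhaustive-enumeration oracles.

## Known limitations

- No LD modelling anywhere: locus counts on real data will differ
  qualitatively from independent-variant simulations.
- Independence of trait tests is assumed; overlapping GWAS samples inflate
  the overlap test.
- Genomic control is a single-factor adjustment; confounding that varies
  along the genome is not addressed.
- The q-value tier uses plain BH; a π₀-estimating variant would be less
  conservative when signal is abundant.
- The crosstalk score ignores edge weights and network topology beyond
  direct between-set edges.
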