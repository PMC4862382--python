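# Demo pipeline run: simulated schizophrenia-like binary trait plus three
# nicotine-dependence-like quantitative GWAS cohorts sharing 50 causal
# variants, analysed end to end (risk scores, joint scans, pathways).
# Completes in well under a minute on one CPU.

simulate = true
prs = true
joint = true
pathways = true

n_individuals = 2000
n_variants = 3000
n_causal = 120
n_shared_causal = 50
shared_effect_corr = 0.8
prevalence = 0.30
n_smoking_traits = 3

q_loci = 0.05
q_candidates = 0.16
flank = 50000
merge_window = 250000
min_traits = 2
n_perm = 1000

seed = 7
out_dir = demo_out
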