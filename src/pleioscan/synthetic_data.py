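"""Synthetic cohorts with pleiotropic trait architecture, plus annotations.

The generator emulates the statistical structure the cross-trait analysis
assumes: two polygenic traits — one quantitative (nicotine-dependence-like)
and one binary (schizophrenia-like, via a liability-threshold model) —
sharing a configurable subset of causal variants whose effect sizes are
drawn with a configurable correlation.  Per-variant association scans turn
a cohort into GWAS summary statistics in the package's canonical dialect,
and a matching gene/pathway/PPI annotation is generated on the same
simulated chromosome so every downstream stage runs with no external data.

Variants are independent (no linkage disequilibrium) on a single linear
pseudo-chromosome; genotypes are Hardy–Weinberg binomial draws at MAFs
uniform in ``maf_range``.  Sex, age and study covariates enter both traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import SUMSTATS_COLUMNS, zscore_to_pvalue

__all__ = [
    "SimConfig",
    "Cohort",
    "simulate_cohort",
    "scan_summary_stats",
    "simulate_annotation",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort and its annotation.

    Trait A is the quantitative trait; trait B is the binary trait (case
    status from a liability threshold at the ``prevalence`` quantile).
    Defaults describe a desk-scale polygenic architecture: 2,000
    individuals, 3,000 independent common variants, 120 causal variants per
    trait of which 50 are shared with effect-size correlation 0.8.
    """

    n_individuals: int = 2000
    n_variants: int = 3000
    maf_range: tuple = (0.05, 0.5)
    n_causal_a: int = 120
    n_causal_b: int = 120
    n_shared_causal: int = 50
    effect_sd_a: float = 0.12
    effect_sd_b: float = 0.12
    shared_effect_corr: float = 0.8
    prevalence: float = 0.30
    covariate_effects: tuple = (0.2, 0.005, 0.1)  # sex, per-year age, per-study
    variant_spacing: int = 10_000  # bp between adjacent variants
    cluster_causal: bool = False  # place shared causal variants adjacently
    # annotation sizes
    n_genes: int = 300
    n_pathways: int = 20
    pathway_size_range: tuple = (10, 40)
    pathway_causal_enrichment: float = 1.0
    n_enriched_pathways: int = 1  # how many leading pathways get the enrichment
    gene_length_range: tuple = (5_000, 30_000)
    gene_gap_range: tuple = (0, 120_000)
    ppi_edge_prob: float = 0.01
    ppi_within_pathway_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_variants", "n_genes", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_causal_a", "n_causal_b", "n_shared_causal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_shared_causal > min(self.n_causal_a, self.n_causal_b):
            raise ValueError("n_shared_causal exceeds a trait's causal count")
        if self.n_causal_a > self.n_variants or self.n_causal_b > self.n_variants:
            raise ValueError("more causal variants than variants")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if not (-1 <= self.shared_effect_corr <= 1):
            raise ValueError("shared_effect_corr must be in [-1, 1]")
        if self.effect_sd_a <= 0 or self.effect_sd_b <= 0:
            raise ValueError("effect SDs must be > 0")

    @property
    def chrom_length(self) -> int:
        return (self.n_variants + 1) * self.variant_spacing


@dataclass
class Cohort:
    """One simulated sample with genotypes, phenotypes and ground truth."""

    config: SimConfig
    iids: list
    variants: pd.DataFrame  # SNP, CHR, BP, MAF
    dosages: np.ndarray  # n_individuals x n_variants, values {0,1,2}
    covariates: pd.DataFrame  # sex, age, study
    phenotype_quant: np.ndarray
    phenotype_binary: np.ndarray
    truth: pd.DataFrame  # per-variant causal flags and true effects
    genetic_quant: np.ndarray  # genetic component of the quantitative trait
    genetic_liability: np.ndarray  # genetic component of the latent liability

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=pd.Index(self.iids, name="iid"),
            columns=self.variants["SNP"],
        )

    def phenotype_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "iid": self.iids,
                "pheno_quant": self.phenotype_quant,
                "pheno_bin": self.phenotype_binary,
            }
        )
        return pd.concat([out, self.covariates.reset_index(drop=True)], axis=1)


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Causal variant positions and true effect sizes for both traits."""
    n = config.n_variants
    maf = rng.uniform(*config.maf_range, size=n)
    n_shared = config.n_shared_causal
    n_total = config.n_causal_a + config.n_causal_b - n_shared
    if config.cluster_causal:
        start = rng.integers(0, n - n_total + 1)
        picked = np.arange(start, start + n_total)
    else:
        picked = rng.choice(n, size=n_total, replace=False)
    shared = picked[:n_shared]
    only_a = picked[n_shared : config.n_causal_a]
    only_b = picked[config.n_causal_a :]

    eff_a = np.zeros(n)
    eff_b = np.zeros(n)
    eff_a[only_a] = rng.normal(0.0, config.effect_sd_a, size=only_a.size)
    eff_b[only_b] = rng.normal(0.0, config.effect_sd_b, size=only_b.size)
    rho = config.shared_effect_corr
    base = rng.normal(0.0, 1.0, size=n_shared)
    noise = rng.normal(0.0, 1.0, size=n_shared)
    eff_a[shared] = config.effect_sd_a * base
    eff_b[shared] = config.effect_sd_b * (rho * base + np.sqrt(1 - rho**2) * noise)

    causal_a = np.zeros(n, dtype=bool)
    causal_b = np.zeros(n, dtype=bool)
    causal_a[np.concatenate([shared, only_a])] = True
    causal_b[np.concatenate([shared, only_b])] = True
    return pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n)],
            "CHR": "1",
            "BP": (np.arange(n) + 1) * config.variant_spacing,
            "MAF": maf,
            "causal_a": causal_a,
            "causal_b": causal_b,
            "effect_a": eff_a,
            "effect_b": eff_b,
        }
    )


def simulate_cohort(config: SimConfig, truth: pd.DataFrame | None = None) -> Cohort:
    """Draw one cohort under ``config``.

    Passing the ``truth`` table of a previous cohort reuses its causal
    architecture (MAFs, causal flags, true effects) while sampling fresh
    individuals, which is how multiple GWAS samples of the same underlying
    traits are emulated without reusing subjects across cohorts.
    """
    rng = np.random.default_rng(config.seed)
    truth_rng, geno_rng, cov_rng, pheno_rng = rng.spawn(4)
    if truth is None:
        truth = _draw_truth(config, truth_rng)
    elif len(truth) != config.n_variants:
        raise ValueError("supplied truth table does not match n_variants")

    n, m = config.n_individuals, config.n_variants
    maf = truth["MAF"].to_numpy()
    dosages = geno_rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)

    sex = cov_rng.integers(0, 2, size=n)
    age = cov_rng.integers(18, 71, size=n)
    study = cov_rng.integers(0, 3, size=n)
    covariates = pd.DataFrame({"sex": sex, "age": age, "study": study})
    es, ea, et = config.covariate_effects
    cov_term = es * sex + ea * age + et * study

    g_a = dosages @ truth["effect_a"].to_numpy()
    g_b = dosages @ truth["effect_b"].to_numpy()
    y_quant = g_a + cov_term + pheno_rng.normal(0.0, 1.0, size=n)
    liability = g_b + cov_term + pheno_rng.normal(0.0, 1.0, size=n)

    # theoretical liability threshold at the (1 - prevalence) quantile:
    # mean/variance of the liability under the generating model
    eff_b = truth["effect_b"].to_numpy()
    mean_liab = float(2 * maf @ eff_b) + es * 0.5 + ea * 44.0 + et * 1.0
    var_gen = float((2 * maf * (1 - maf)) @ (eff_b**2))
    var_age = (71 - 18) ** 2 / 12.0  # continuous approximation of the uniform ints
    var_cov = es**2 * 0.25 + ea**2 * var_age + et**2 * (2.0 / 3.0)
    threshold = mean_liab + stats.norm.isf(config.prevalence) * np.sqrt(
        var_gen + var_cov + 1.0
    )
    y_bin = (liability > threshold).astype(np.int8)

    return Cohort(
        config=config,
        iids=[f"id{i + 1}" for i in range(n)],
        variants=truth[["SNP", "CHR", "BP", "MAF"]].copy(),
        dosages=dosages,
        covariates=covariates,
        phenotype_quant=y_quant,
        phenotype_binary=y_bin,
        truth=truth,
        genetic_quant=g_a,
        genetic_liability=g_b,
    )


# ---------------------------------------------------------------------------
# per-variant association scans


def _covariate_matrix(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Intercept + sex + age + study indicator columns."""
    if covariates is None:
        return np.ones((n, 1))
    study = pd.get_dummies(covariates["study"], drop_first=True, dtype=float)
    return np.column_stack(
        [np.ones(n), covariates["sex"], covariates["age"], study.to_numpy()]
    ).astype(float)


def _ols_scan(y: np.ndarray, dosages: np.ndarray, C: np.ndarray):
    """Per-variant OLS slope of y on dosage adjusting for C (Frisch–Waugh)."""
    n, k = C.shape
    proj = np.linalg.lstsq(C, np.column_stack([y, dosages]), rcond=None)[0]
    resid = np.column_stack([y, dosages]) - C @ proj
    ry, rd = resid[:, 0], resid[:, 1:]
    dd = np.einsum("ij,ij->j", rd, rd)
    mono = dd <= 1e-12
    dd_safe = np.where(mono, 1.0, dd)
    beta = (rd.T @ ry) / dd_safe
    rss = ry @ ry - beta**2 * dd_safe
    dof = n - k - 1
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / dd_safe)
    return beta, se, mono


def _logistic_scan(y: np.ndarray, dosages: np.ndarray, C: np.ndarray,
                   max_iter: int = 25, tol: float = 1e-8):
    """Per-variant ML logistic regression of y on dosage adjusting for C.

    Newton–Raphson vectorized across variants; the design for variant j is
    ``[C, dosage_j]``.  Returns (beta, se, monomorphic_mask) with beta the
    dosage log-odds-ratio.
    """
    n, k = C.shape
    m = dosages.shape[1]
    D = dosages.astype(float)
    dd = D.var(axis=0)
    mono = dd <= 1e-12

    # warm start from the covariates-only fit (shared by all variants)
    theta0 = np.zeros(k)
    for _ in range(50):
        mu = 1.0 / (1.0 + np.exp(-(C @ theta0)))
        W = mu * (1 - mu)
        H = C.T @ (C * W[:, None])
        g = C.T @ (y - mu)
        step = np.linalg.solve(H, g)
        theta0 = theta0 + step
        if np.abs(step).max() < tol:
            break

    p = k + 1
    theta = np.zeros((m, p))
    theta[:, :k] = theta0
    active = ~mono
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        th = theta[idx]
        eta = C @ th[:, :k].T + D[:, idx] * th[:, k]  # (n, v)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        r = y[:, None] - mu
        grad = np.empty((idx.size, p))
        grad[:, :k] = r.T @ C
        grad[:, k] = np.einsum("nv,nv->v", D[:, idx], r)
        H = np.empty((idx.size, p, p))
        H[:, :k, :k] = np.einsum("nk,nv,nl->vkl", C, W, C)
        cross = np.einsum("nk,nv->vk", C, W * D[:, idx])
        H[:, :k, k] = cross
        H[:, k, :k] = cross
        H[:, k, k] = np.einsum("nv,nv->v", D[:, idx] ** 2, W)
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        np.clip(step, -4.0, 4.0, out=step)  # damp early separation blow-ups
        theta[idx] += step
        done = np.abs(step).max(axis=1) < tol
        active[idx[done]] = False

    # standard errors from the observed information at the optimum
    beta = theta[:, k].copy()
    se = np.full(m, np.inf)
    idx = np.flatnonzero(~mono)
    if idx.size:
        th = theta[idx]
        eta = C @ th[:, :k].T + D[:, idx] * th[:, k]
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = np.empty((idx.size, p, p))
        H[:, :k, :k] = np.einsum("nk,nv,nl->vkl", C, W, C)
        cross = np.einsum("nk,nv->vk", C, W * D[:, idx])
        H[:, :k, k] = cross
        H[:, k, :k] = cross
        H[:, k, k] = np.einsum("nv,nv->v", D[:, idx] ** 2, W)
        cov = np.linalg.inv(H)
        se[idx] = np.sqrt(np.maximum(cov[:, k, k], 1e-300))
    beta[mono] = 0.0
    return beta, se, mono


def scan_summary_stats(
    cohort: Cohort, trait: str, include_covariates: bool = True
) -> pd.DataFrame:
    """Per-variant association scan producing canonical summary statistics.

    ``trait`` is ``"quant"`` (ordinary least squares) or ``"binary"``
    (maximum-likelihood logistic regression; BETA is the log odds ratio).
    Monomorphic variants are emitted with Z=0, P=1 and flagged in the
    in-memory ``MONOMORPHIC`` column.
    """
    if trait not in ("quant", "binary"):
        raise ValueError("trait must be 'quant' or 'binary'")
    n = cohort.config.n_individuals
    C = _covariate_matrix(cohort.covariates if include_covariates else None, n)
    if trait == "quant":
        y = np.asarray(cohort.phenotype_quant, dtype=float)
        beta, se, mono = _ols_scan(y, cohort.dosages, C)
    else:
        y = np.asarray(cohort.phenotype_binary, dtype=float)
        beta, se, mono = _logistic_scan(y, cohort.dosages, C)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(mono | ~np.isfinite(se), 0.0, beta / se)
    p = zscore_to_pvalue(z)
    p[z == 0] = 1.0
    beta = np.where(mono, 0.0, beta)

    # effect allele = the alternate allele whose dosage is counted; a fixed
    # A/G coding keeps harmonization trivial for simulated data
    out = cohort.variants[["SNP", "CHR", "BP"]].copy()
    out["A1"] = "A"
    out["A2"] = "G"
    out["BETA"] = beta
    out["SE"] = se
    out["Z"] = z
    out["P"] = p
    out["N"] = n
    out["MONOMORPHIC"] = mono
    return out[SUMSTATS_COLUMNS + ["MONOMORPHIC"]]


# ---------------------------------------------------------------------------
# annotation: genes, pathways, PPI


def simulate_annotation(config: SimConfig, truth: pd.DataFrame | None = None):
    """Gene intervals, pathway gene sets and a PPI edge list on the
    simulated chromosome.

    Genes are non-overlapping intervals tiled with random inter-gene gaps,
    so variants fall inside genes, within flanking distance, or beyond.
    Pathways are sampled gene subsets; genes containing a causal variant
    (for either trait) can be over-sampled by ``pathway_causal_enrichment``.
    The PPI graph is Erdős–Rényi over all genes with an optional extra
    within-pathway edge probability.

    Returns ``(genes, pathways, ppi_edges)`` where ``genes`` is a DataFrame
    (gene_id, chrom, start, end; 1-based inclusive), ``pathways`` maps
    pathway_id to (description, [gene ids]) and ``ppi_edges`` is a list of
    undirected gene-id pairs.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    if truth is None:
        truth = _draw_truth(config, np.random.default_rng(config.seed).spawn(4)[0])

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=config.n_genes
    )
    gaps = rng.integers(
        config.gene_gap_range[0], config.gene_gap_range[1] + 1, size=config.n_genes
    )
    starts = np.cumsum(gaps + np.concatenate([[0], lengths[:-1]])) + 1
    ends = starts + lengths - 1
    if ends[-1] > config.chrom_length:
        raise ValueError(
            f"{config.n_genes} genes (span {ends[-1]} bp) do not fit on the "
            f"{config.chrom_length} bp simulated chromosome"
        )
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i + 1}" for i in range(config.n_genes)],
            "chrom": "1",
            "start": starts,
            "end": ends,
        }
    )

    # genes that contain a causal variant, for pathway enrichment weighting
    causal_pos = truth.loc[truth["causal_a"] | truth["causal_b"], "BP"].to_numpy()
    contains_causal = np.array(
        [((causal_pos >= s) & (causal_pos <= e)).any() for s, e in zip(starts, ends)]
    )

    enriched_w = np.where(contains_causal, config.pathway_causal_enrichment, 1.0)
    enriched_w = enriched_w / enriched_w.sum()
    uniform_w = np.full(config.n_genes, 1.0 / config.n_genes)
    lo, hi = config.pathway_size_range
    pathways = {}
    gene_ids = genes["gene_id"].to_numpy()
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, min(hi, config.n_genes) + 1))
        w = enriched_w if i < config.n_enriched_pathways else uniform_w
        members = rng.choice(gene_ids, size=size, replace=False, p=w)
        pathways[f"PW{i + 1}"] = (f"simulated pathway {i + 1}", sorted(members))

    edges = set()
    if config.ppi_edge_prob > 0:
        iu, ju = np.triu_indices(config.n_genes, k=1)
        pick = rng.random(iu.size) < config.ppi_edge_prob
        edges.update(zip(gene_ids[iu[pick]], gene_ids[ju[pick]]))
    if config.ppi_within_pathway_prob > 0:
        for _, members in pathways.values():
            arr = np.array(members)
            iu, ju = np.triu_indices(arr.size, k=1)
            pick = rng.random(iu.size) < config.ppi_within_pathway_prob
            edges.update(zip(arr[iu[pick]], arr[ju[pick]]))
    return genes, pathways, sorted(edges)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed (convenience for replicates)."""
    return replace(config, seed=seed)


def simulate_paired_zscores(
    n_variants: int,
    frac_shared: float = 0.0,
    shared_z: float = 6.0,
    seed: int = 0,
    spacing: int = 100_000,
):
    """Summary-level scan pair: two traits' Z-scores with planted sharing.

    Null variants draw independent standard-normal Z in each trait; a
    ``frac_shared`` fraction carries a shared signal of magnitude
    ``shared_z`` (one random sign per variant, common to both traits) plus
    unit noise per trait.  Variants are spaced ``spacing`` bp apart so each
    planted signal forms its own locus.  Returns ``(frame_a, frame_b,
    shared_mask)`` with frames in the canonical summary-statistics dialect.
    """
    rng = np.random.default_rng(seed)
    n_shared = int(round(frac_shared * n_variants))
    shared = np.zeros(n_variants, dtype=bool)
    if n_shared:
        shared[rng.choice(n_variants, size=n_shared, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=n_variants)
    mean = np.where(shared, signs * shared_z, 0.0)
    frames = []
    for _ in range(2):
        z = mean + rng.normal(size=n_variants)
        df = pd.DataFrame(
            {
                "SNP": [f"rs{i + 1}" for i in range(n_variants)],
                "CHR": "1",
                "BP": (np.arange(n_variants) + 1) * spacing,
                "A1": "A",
                "A2": "G",
                "BETA": z,
                "SE": 1.0,
                "Z": z,
                "P": zscore_to_pvalue(z),
                "N": 10_000,
            }
        )
        frames.append(df[SUMSTATS_COLUMNS])
    return frames[0], frames[1], shared


#: conditions for the reciprocal risk-score arm: a diffuse polygenic
#: architecture (per-variant statistics mostly below genome-wide noticeability,
#: aggregate shared signal well above the 1/n incremental-R^2 noise floor)
#: scored in large held-out target cohorts
PRS_STUDY_CONFIG = SimConfig(
    n_individuals=2000,
    n_variants=1200,
    n_causal_a=80,
    n_causal_b=80,
    n_shared_causal=50,
    effect_sd_a=0.06,
    effect_sd_b=0.06,
    shared_effect_corr=0.8,
)

#: held-out target-cohort size for the reciprocal risk-score arm
PRS_TARGET_N = 8000


def reciprocal_study(config: SimConfig, n_target: int = PRS_TARGET_N) -> dict:
    """Simulate the four cohorts of one reciprocal risk-score experiment.

    One binary-trait GWAS cohort and one quantitative-trait GWAS cohort
    provide summary statistics; two held-out target cohorts (fresh
    individuals, same causal architecture) are scored and predicted.  No
    individual appears in more than one cohort.

    Returns a dict with ``ss_binary``, ``ss_quant`` (summary statistics)
    and ``target_quant``, ``target_binary`` (cohorts to be predicted).
    """
    seeds = [
        int(c.generate_state(1)[0] % 2**31)
        for c in np.random.SeedSequence(config.seed).spawn(4)
    ]
    gwas_binary = simulate_cohort(with_seed(config, seeds[0]))
    truth = gwas_binary.truth
    gwas_quant = simulate_cohort(with_seed(config, seeds[1]), truth=truth)
    target_cfg = replace(config, n_individuals=n_target)
    target_quant = simulate_cohort(with_seed(target_cfg, seeds[2]), truth=truth)
    target_binary = simulate_cohort(with_seed(target_cfg, seeds[3]), truth=truth)
    return {
        "ss_binary": scan_summary_stats(gwas_binary, "binary"),
        "ss_quant": scan_summary_stats(gwas_quant, "quant"),
        "target_quant": target_quant,
        "target_binary": target_binary,
        "truth": truth,
    }
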