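"""Weakest-link joint ("overlap") testing of shared association across traits.

For m traits with per-variant association P-values P_1..P_m (each first
background-adjusted by genomic control on its chi-square statistics), the
overlap statistic at a variant is the weakest link r = max_j P_j — small
only when *every* trait shows association.  Under independent null trait
tests the overlap P-value is P(R <= r) = r^m; an empirical-null option
replaces each uniform marginal with that trait's genome-wide adjusted
P-value ECDF.  Overlap P-values are converted to Benjamini–Hochberg
q-values; variants passing a q cutoff are chained into loci by physical
proximity, and a looser q tier supplies candidate markers for pathway work.

The construction caps the worst-case per-variant false-positive rate: at a
genome-wide level alpha with m traits, even an infinitely strong signal in
m-1 traits cannot push a null trait past alpha^(1/m) (2.2e-4 for
alpha = 5e-8, m = 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sumstats_io import P_FLOOR

logger = logging.getLogger("pleioscan")

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


# ---------------------------------------------------------------------------
# background (genomic-control) adjustment


def background_adjust(z: np.ndarray, min_variants: int = 100):
    """Genomic-control adjustment of one trait's association statistics.

    lambda = median(z^2) / median(chi^2_1); adjusted chi-square is
    z^2 / max(lambda, 1) (deflation below 1 is never applied) and adjusted
    P-values come from the chi^2_1 upper tail.  With fewer than
    ``min_variants`` statistics the adjustment is skipped (lambda = 1).

    Returns ``(adjusted_p, lambda)``.
    """
    z = np.asarray(z, dtype=float)
    chi2 = z**2
    if z.size < min_variants:
        logger.warning(
            "background_adjust: only %d variants (<%d); adjustment skipped",
            z.size, min_variants,
        )
        lam = 1.0
    else:
        lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    adj = chi2 / max(lam, 1.0)
    p = np.maximum(stats.chi2.sf(adj, 1), P_FLOOR)
    return p, lam


# ---------------------------------------------------------------------------
# overlap statistic and its P-value


def overlap_statistic(p_values, alternative: str = "max") -> np.ndarray:
    """Weakest-link overlap statistic per variant.

    ``p_values`` is an array-like of shape (n_variants, m) (or a length-m
    vector for one variant).  The default statistic is the largest of the
    per-trait P-values; ``alternative="min"`` exposes the strongest-link
    variant, which is not used by the main pipeline.
    """
    p = np.atleast_2d(np.asarray(p_values, dtype=float))
    if p.shape[1] < 2:
        raise ValueError("overlap statistic needs at least 2 traits")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P-values must lie in (0, 1]")
    r = p.min(axis=1) if alternative == "min" else p.max(axis=1)
    return r if r.size > 1 else float(r[0])


def overlap_pvalue(r, m: int, null: str = "uniform", per_trait_ps=None):
    """P(R <= r) for the weakest-link statistic.

    Under the independent-uniform null this is ``r ** m`` (evaluated in log
    space and floored at 1e-300).  ``null="empirical"`` instead multiplies
    each trait's empirical CDF at r, built from that trait's genome-wide
    adjusted P-values supplied in ``per_trait_ps`` (list of m arrays); the
    ECDF is floored at 1/(n_j + 1) so it never returns exactly 0.
    """
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any((r_arr <= 0) | (r_arr > 1)):
        raise ValueError("overlap statistic must lie in (0, 1]")
    if m < 2:
        raise ValueError("m must be >= 2")
    if null == "uniform":
        out = np.exp(m * np.log(r_arr))
    elif null == "empirical":
        if per_trait_ps is None or len(per_trait_ps) != m:
            raise ValueError("empirical null requires m per-trait P-value arrays")
        out = np.ones_like(r_arr)
        for pj in per_trait_ps:
            pj = np.sort(np.asarray(pj, dtype=float))
            ecdf = np.searchsorted(pj, r_arr, side="right") / (pj.size + 1)
            out *= np.maximum(ecdf, 1.0 / (pj.size + 1))
    else:
        raise ValueError(f"unknown null {null!r}")
    out = np.maximum(out, P_FLOOR)
    return out if out.size > 1 else float(out[0])


def per_trait_threshold(alpha: float, m: int) -> float:
    """Per-trait P-value every trait must beat for overlap significance.

    The weakest-link test rejects at overall level alpha only when each of
    the m traits has P below alpha^(1/m) — e.g. 2.2e-4 for the genome-wide
    alpha = 5e-8 with two traits.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha ** (1.0 / m)


def worst_case_fpr(alpha: float, m: int) -> float:
    """Per-variant false-positive rate when m-1 traits carry extreme signal.

    With P -> 0 in all but one trait, the overlap statistic reduces to the
    remaining null-uniform P-value, so the rejection probability at level
    alpha is alpha^(1/m) — the worst case of the construction.
    """
    return per_trait_threshold(alpha, m)


# ---------------------------------------------------------------------------
# multiplicity


def fdr_qvalues(joint_ps) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(joint_ps, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def aic_qvalue_rationale(penalty: float = 2.0) -> float:
    """q cutoff implied by an AIC penalty in a 1-df likelihood-ratio test.

    The upper-tail chi^2_1 probability at the penalty: a factor-of-2 AIC
    penalty corresponds to 0.157, reported as the 0.16 candidate tier.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    return float(stats.chi2.sf(penalty, 1))


# ---------------------------------------------------------------------------
# locus aggregation


@dataclass(frozen=True)
class Locus:
    """A chain of q-significant variants merged by physical proximity."""

    lead_variant: str
    chrom: str
    start: int
    end: int
    n_markers: int
    joint_p: float
    q: float
    annotated_gene: str = ""


def select_loci(
    results: pd.DataFrame,
    q_cutoff: float = 0.05,
    merge_window: int = 250_000,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge q-significant variants into loci.

    Consecutive significant variants on one chromosome are chained while
    each gap is at most ``merge_window`` bp.  The locus lead is the member
    with the smallest joint P (ties to the smaller position); ``N_MARKERS``
    counts members.  If ``genes`` is given the lead variant is annotated
    with its nearest gene (50-kb flank semantics of the gene mapper).

    ``results`` must be sorted by (CHR, BP) and carry columns
    SNP, CHR, BP, JOINT_P, Q.
    """
    sig = results.loc[results["Q"] <= q_cutoff]
    rows = []
    for chrom, grp in sig.groupby("CHR", sort=False):
        bp = grp["BP"].to_numpy()
        breaks = np.flatnonzero(np.diff(bp) > merge_window)
        bounds = np.concatenate([[0], breaks + 1, [len(grp)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            members = grp.iloc[lo:hi]
            lead = members.sort_values(["JOINT_P", "BP"]).iloc[0]
            rows.append(
                {
                    "LEAD_SNP": lead["SNP"],
                    "CHR": chrom,
                    "START": int(members["BP"].min()),
                    "END": int(members["BP"].max()),
                    "N_MARKERS": len(members),
                    "JOINT_P": float(lead["JOINT_P"]),
                    "Q": float(lead["Q"]),
                }
            )
    loci = pd.DataFrame(
        rows, columns=["LEAD_SNP", "CHR", "START", "END", "N_MARKERS", "JOINT_P", "Q"]
    )
    if not loci.empty:
        loci = loci.sort_values("JOINT_P", kind="stable").reset_index(drop=True)
    if genes is not None and not loci.empty:
        from .gene_pathway import map_snps_to_genes

        lead = results.set_index("SNP").loc[loci["LEAD_SNP"], ["CHR", "BP"]]
        loci["GENE"] = map_snps_to_genes(
            lead.reset_index().rename(columns={"SNP": "SNP"}), genes
        )["gene_id"].fillna("").to_numpy()
    else:
        loci["GENE"] = ""
    return loci


# ---------------------------------------------------------------------------
# full scan


def run_joint_scan(
    trait_frames: list,
    gc_adjust: bool = True,
    null: str = "uniform",
    q_loci: float = 0.05,
    q_candidates: float = 0.16,
    merge_window: int = 250_000,
    genes: pd.DataFrame | None = None,
    alternative: str = "max",
    exclude_gws_single: float | None = None,
):
    """Joint scan over >= 2 traits' harmonized summary statistics.

    ``trait_frames`` is a list of canonical summary-statistics DataFrames
    on a shared variant set (an inner join on SNP is applied, so pass the
    output of pairwise harmonization or any frames with consistent ids).

    Pipeline: per-trait genomic-control adjustment -> weakest-link overlap
    statistic -> overlap P-value -> BH q-values -> locus selection at
    ``q_loci`` plus the looser ``q_candidates`` marker tier for pathway
    analyses.  ``exclude_gws_single`` optionally drops variants already
    genome-wide significant in a single trait before testing (off by
    default; the max statistic already suppresses one-trait signals).

    Returns ``(results, loci, candidates)``.
    """
    m = len(trait_frames)
    if m < 2:
        raise ValueError("need at least 2 traits")
    base = trait_frames[0][["SNP", "CHR", "BP"]].copy()
    zs = {f"Z_trait{1}": trait_frames[0]["Z"].to_numpy()}
    merged = base.assign(**zs)
    merged["Z_trait1"] = trait_frames[0]["Z"].to_numpy()
    for j, df in enumerate(trait_frames[1:], start=2):
        right = df[["SNP", "Z"]].rename(columns={"Z": f"Z_trait{j}"})
        merged = merged.merge(right, on="SNP", how="inner")
    merged = merged.sort_values(
        ["CHR", "BP"], key=lambda s: pd.to_numeric(s, errors="coerce")
    ).reset_index(drop=True)

    lambdas = []
    p_adj = np.empty((len(merged), m))
    for j in range(m):
        z = merged[f"Z_trait{j + 1}"].to_numpy()
        if gc_adjust:
            p_adj[:, j], lam = background_adjust(z)
        else:
            p_adj[:, j] = np.maximum(stats.chi2.sf(z**2, 1), P_FLOOR)
            lam = 1.0
        lambdas.append(lam)
        merged[f"P_adj_trait{j + 1}"] = p_adj[:, j]

    if exclude_gws_single is not None:
        keep = ~(p_adj < exclude_gws_single).any(axis=1)
        merged = merged.loc[keep].reset_index(drop=True)
        p_adj = p_adj[keep]

    r = np.atleast_1d(overlap_statistic(p_adj, alternative=alternative))
    per_trait = [p_adj[:, j] for j in range(m)] if null == "empirical" else None
    joint_p = np.atleast_1d(overlap_pvalue(r, m, null=null, per_trait_ps=per_trait))
    merged["R"] = r
    merged["JOINT_P"] = joint_p
    merged["Q"] = fdr_qvalues(joint_p)
    merged.attrs["lambdas"] = lambdas

    loci = select_loci(merged, q_cutoff=q_loci, merge_window=merge_window, genes=genes)
    candidates = merged.loc[merged["Q"] <= q_candidates].reset_index(drop=True)
    logger.info(
        "joint scan: %d variants, lambdas=%s, %d loci at q<=%g, %d candidates at q<=%g",
        len(merged), [f"{l:.3f}" for l in lambdas], len(loci), q_loci,
        len(candidates), q_candidates,
    )
    return merged, loci, candidates
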