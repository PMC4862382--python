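"""Thresholded polygenic risk scores and reciprocal cross-trait prediction.

A risk score for an individual is the sum over included markers of risk
alleles times the marker's effect weight (log odds ratio for a binary
source trait, regression beta for a quantitative one), normalized to the
average per-allele weight: score_i = sum_j dosage_ij * w_j / (2 * M_i)
with M_i the number of non-missing scored markers for individual i.  The
normalization is an affine rescaling and leaves regression tests and
variance explained unchanged.  Markers are included at successive source
P-value thresholds; the standard ladder is 5e-5, 5e-4, 5e-3, 5e-2, 5e-1.

Prediction of the target phenotype uses linear regression (quantitative)
or logistic regression (binary), always adjusting for sex, age and study
(as indicator variables).  Variance explained is reported as incremental
R-squared over the covariates-only model for linear fits and Nagelkerke's
R-squared (full vs covariates-only likelihoods) for logistic fits.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("pleioscan")

#: the standard inclusion-threshold ladder
DEFAULT_THRESHOLDS = (5e-5, 5e-4, 5e-3, 5e-2, 5e-1)

PRS_RESULT_COLUMNS = [
    "threshold", "beta", "se", "stat", "p", "r2", "n_markers", "n_individuals",
]


def compute_risk_scores(
    weights: pd.DataFrame,
    dosages: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-individual normalized risk scores at each inclusion threshold.

    Parameters
    ----------
    weights
        Canonical summary-statistics frame of the source trait, already
        harmonized to the dosage data's allele coding (BETA counts copies
        of the dosage-counted allele).
    dosages
        individuals x variants frame (index = individual id, columns =
        variant ids, values 0/1/2 or NaN for missing).
    thresholds
        P-value cutoffs; markers with source P <= T are scored at T.

    Returns a long frame (individual_id, threshold, score, n_markers);
    thresholds passed by zero markers are flagged with NaN scores and
    n_markers = 0 so downstream regression can skip them.
    """
    thresholds = list(thresholds)
    if any(t <= 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    shared = weights["SNP"].isin(dosages.columns)
    w = weights.loc[shared]
    frames = []
    for t in thresholds:
        sel = w.loc[w["P"] <= t]
        if sel.empty:
            logger.warning("threshold %g: no markers pass; scores undefined", t)
            frames.append(
                pd.DataFrame(
                    {
                        "individual_id": dosages.index,
                        "threshold": t,
                        "score": np.nan,
                        "n_markers": 0,
                    }
                )
            )
            continue
        D = dosages[sel["SNP"]].to_numpy(dtype=float)
        wvec = sel["BETA"].to_numpy()
        present = ~np.isnan(D)
        M = present.sum(axis=1)
        num = np.where(present, D, 0.0) @ wvec
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(M > 0, num / (2.0 * M), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": dosages.index,
                    "threshold": t,
                    "score": score,
                    "n_markers": M,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _design(pheno: pd.DataFrame, score: np.ndarray | None):
    """Covariate design with intercept, sex, age, study dummies (+ score)."""
    cols = [np.ones(len(pheno))]
    names = ["const"]
    for c in ("sex", "age"):
        if c in pheno.columns:
            cols.append(pheno[c].to_numpy(dtype=float))
            names.append(c)
    if "study" in pheno.columns:
        dummies = pd.get_dummies(pheno["study"], prefix="study", drop_first=True,
                                 dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
            names.append(str(c))
    if score is not None:
        cols.append(score)
        names.append("score")
    X = np.column_stack(cols)
    return pd.DataFrame(X, columns=names, index=pheno.index)


def nagelkerke_r2(ll_full: float, ll_null: float, n: int) -> float:
    """Nagelkerke's rescaled likelihood R-squared of full vs null model."""
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_null / n)
    if max_r2 <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_r2, 0.0, 1.0))


def predict_trait(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    trait_kind: str,
    phenotype_column: str | None = None,
) -> pd.DataFrame:
    """Regress the target phenotype on the risk score at each threshold.

    ``scores`` is the long frame from :func:`compute_risk_scores`;
    ``phenotypes`` carries ``iid``, the phenotype column (default
    ``pheno_quant`` or ``pheno_bin`` by trait kind) and sex/age/study
    covariates.  Returns one row per threshold with the score term's
    beta/se/statistic/P and the variance explained (incremental R-squared
    for linear fits, Nagelkerke's R-squared for logistic fits).

    Complete separation in a logistic fit is flagged (``separation`` True,
    r2 = 1, P = NaN: unreliable).
    """
    if trait_kind not in ("binary", "quantitative"):
        raise ValueError("trait_kind must be 'binary' or 'quantitative'")
    if phenotype_column is None:
        phenotype_column = "pheno_bin" if trait_kind == "binary" else "pheno_quant"
    pheno = phenotypes.set_index("iid")
    rows = []
    for t, grp in scores.groupby("threshold", sort=True):
        grp = grp.set_index("individual_id")
        joined = pheno.join(grp[["score", "n_markers"]], how="inner").dropna(
            subset=["score", phenotype_column]
        )
        if grp["n_markers"].max() == 0 or joined.empty:
            logger.warning("threshold %g: skipped (no usable scores)", t)
            continue
        y = joined[phenotype_column].to_numpy(dtype=float)
        X_full = _design(joined, joined["score"].to_numpy())
        X_null = _design(joined, None)
        row = {
            "threshold": t,
            "n_markers": int(grp["n_markers"].max()),
            "n_individuals": len(joined),
            "separation": False,
        }
        if trait_kind == "quantitative":
            full = sm.OLS(y, X_full).fit()
            null = sm.OLS(y, X_null).fit()
            row.update(
                beta=full.params["score"], se=full.bse["score"],
                stat=full.tvalues["score"], p=full.pvalues["score"],
                r2=max(full.rsquared - null.rsquared, 0.0),
            )
        else:
            try:
                full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
                null = sm.Logit(y, X_null).fit(disp=0, maxiter=200)
                converged = full.mle_retvals.get("converged", True)
                r2 = nagelkerke_r2(full.llf, null.llf, len(y))
                if not converged or not np.isfinite(full.bse["score"]) or \
                        full.bse["score"] > 1e3:
                    raise ValueError("separation suspected")
                row.update(
                    beta=full.params["score"], se=full.bse["score"],
                    stat=full.tvalues["score"], p=full.pvalues["score"], r2=r2,
                )
            except Exception:  # perfect separation or non-convergence
                logger.warning("threshold %g: logistic separation; P unreliable", t)
                row.update(beta=np.nan, se=np.nan, stat=np.nan, p=np.nan,
                           r2=1.0, separation=True)
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out[PRS_RESULT_COLUMNS + ["separation"]]
    return out


def reciprocal_analysis(
    sumstats_a: pd.DataFrame,
    dosages_b: pd.DataFrame,
    phenotypes_b: pd.DataFrame,
    trait_kind_b: str,
    sumstats_b: pd.DataFrame,
    dosages_a: pd.DataFrame,
    phenotypes_a: pd.DataFrame,
    trait_kind_a: str,
    thresholds=DEFAULT_THRESHOLDS,
    alpha: float = 0.05,
):
    """Reciprocal risk-score prediction between two traits.

    Direction "a_to_b": trait A's summary statistics weight trait B's
    cohort, predicting B's phenotype; "b_to_a" is the mirror image.  Each
    result table has one row per threshold with a ``significant`` flag at
    the score term's P < ``alpha``.

    Returns ``{"a_to_b": table, "b_to_a": table}``.
    """
    out = {}
    for label, (ss, dos, phe, kind) in {
        "a_to_b": (sumstats_a, dosages_b, phenotypes_b, trait_kind_b),
        "b_to_a": (sumstats_b, dosages_a, phenotypes_a, trait_kind_a),
    }.items():
        scores = compute_risk_scores(ss, dos, thresholds)
        res = predict_trait(scores, phe, kind)
        if not res.empty:
            res["significant"] = res["p"] < alpha
        out[label] = res
        logger.info("reciprocal %s: %d thresholds fitted", label, len(res))
    return out


def reciprocal_from_study(study: dict, thresholds=DEFAULT_THRESHOLDS, alpha=0.05):
    """Run the reciprocal analysis on a simulated study (see
    :func:`pleioscan.synthetic_data.reciprocal_study`).

    Direction ``a_to_b`` uses the binary trait's summary statistics to
    predict the quantitative phenotype in its held-out target cohort;
    ``b_to_a`` is the mirror image.
    """
    return reciprocal_analysis(
        study["ss_binary"],
        study["target_quant"].dosage_frame(),
        study["target_quant"].phenotype_frame(),
        "quantitative",
        study["ss_quant"],
        study["target_binary"].dosage_frame(),
        study["target_binary"].phenotype_frame(),
        "binary",
        thresholds=thresholds,
        alpha=alpha,
    )
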