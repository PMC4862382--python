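"""Reading, validation, harmonization and writing of GWAS summary statistics.

Summary statistics live in pandas DataFrames with the canonical column set
``SNP CHR BP A1 A2 BETA SE Z P N`` (tab-separated on disk, A1 = effect
allele, BETA on the log-odds scale for binary traits).  Coordinates are
1-based inclusive throughout the package; BED input (0-based half-open) is
converted on read.  Chromosome labels are normalized by stripping any
``chr`` prefix, with X encoded as ``23`` so chromosomes sort numerically.

P-values are tied to Z-scores through the two-sided normal tail
``p = 2 * Phi(-|z|)``; for ``|z| > 37`` the tail underflows in double
precision, so the conversion runs in log space and P is floored at 1e-300.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pleioscan")

#: canonical summary-statistics column order (the on-disk dialect)
SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "Z", "P", "N"]

#: smallest representable P-value; Table-scale joint P-values reach 1e-24,
#: and squaring in the overlap test must not underflow to exactly 0.
P_FLOOR = 1e-300

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


@dataclass(frozen=True)
class TraitMeta:
    """Describes one trait's phenotype scale.

    ``binary`` traits carry effects as log odds ratios; ``quantitative``
    traits carry linear regression slopes.
    """

    trait_name: str
    trait_kind: str  # "binary" | "quantitative"

    def __post_init__(self) -> None:
        if self.trait_kind not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")

    @property
    def effect_scale(self) -> str:
        return "log_odds" if self.trait_kind == "binary" else "linear"


@dataclass(frozen=True)
class GeneInterval:
    """One gene's genomic span, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class HarmonizeReport:
    """Bookkeeping from pairing two traits' summary statistics."""

    n_shared: int = 0
    n_swapped: int = 0
    n_strand_flipped: int = 0
    n_palindromic_dropped: int = 0
    n_irreconcilable_dropped: int = 0
    dropped_ids: list = field(default_factory=list)


class SumstatsError(ValueError):
    """Raised for malformed or inconsistent summary-statistics input."""


# ---------------------------------------------------------------------------
# Z <-> P conversion


def zscore_to_pvalue(z):
    """Two-sided normal-tail P-value for Z, safe for very large |z|.

    Computed in log space (``log p = log 2 + log Phi(-|z|)``) so that
    statistics far beyond |z| = 37 map to the 1e-300 floor instead of 0.
    """
    z = np.asarray(z, dtype=float)
    logp = np.log(2.0) + stats.norm.logsf(np.abs(z))
    p = np.exp(logp)
    return np.maximum(p, P_FLOOR)


def pvalue_to_zscore(p, sign=None):
    """|Z| whose two-sided normal tail equals ``p``; signed if ``sign`` given."""
    p = np.asarray(p, dtype=float)
    z = stats.norm.isf(p / 2.0)
    if sign is not None:
        z = z * np.sign(sign)
    return z


# ---------------------------------------------------------------------------
# chromosome handling


def normalize_chrom(label) -> str:
    """Strip a ``chr`` prefix and encode X/Y/MT numerically for sortability."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    upper = s.upper()
    return {"X": "23", "Y": "24", "M": "25", "MT": "25"}.get(upper, s)


def _chrom_sort_key(chroms: pd.Series) -> pd.Series:
    return pd.to_numeric(chroms, errors="coerce").fillna(99).astype(int)


def sort_by_position(df: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by (chromosome, position)."""
    key = _chrom_sort_key(df["CHR"])
    order = np.lexsort((df["BP"].to_numpy(), key.to_numpy()))
    return df.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# summary statistics reader / writer


def _fail_rows(mask: np.ndarray, message: str) -> None:
    """Raise naming the first offending 1-based data line (header is line 1)."""
    if mask.any():
        line = int(np.flatnonzero(mask)[0]) + 2
        raise SumstatsError(f"{message} (line {line})")


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and complete a raw summary-statistics frame in place.

    Missing Z is reconstructed as BETA/SE; missing P from Z via the normal
    tail.  Violations raise :class:`SumstatsError` naming the offending
    input line.
    """
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsError(f"missing required columns: {missing}")
    df = df.copy()

    for col in ("BETA", "SE", "Z", "P"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        _fail_rows(bad.to_numpy(), f"non-numeric value in column {col}")
        df[col] = coerced
    for col, kind in (("BP", "position"), ("N", "sample size")):
        coerced = pd.to_numeric(df[col], errors="coerce")
        _fail_rows(coerced.isna().to_numpy(), f"missing or non-numeric {kind}")
        _fail_rows((coerced <= 0).to_numpy(), f"non-positive {kind}")
        df[col] = coerced.astype(np.int64)

    df["CHR"] = df["CHR"].map(normalize_chrom)
    df["A1"] = df["A1"].astype(str).str.upper()
    df["A2"] = df["A2"].astype(str).str.upper()
    bad_allele = ~(df["A1"].isin(_VALID_ALLELES) & df["A2"].isin(_VALID_ALLELES))
    _fail_rows(bad_allele.to_numpy(), "allele is not a single A/C/G/T base")
    _fail_rows((df["A1"] == df["A2"]).to_numpy(), "effect allele equals other allele")

    dup = df["SNP"][df["SNP"].duplicated()]
    if len(dup):
        raise SumstatsError(f"duplicate variant ids: {sorted(set(dup))}")

    _fail_rows((df["SE"] <= 0).to_numpy(), "standard error must be > 0")

    need_z = df["Z"].isna()
    df.loc[need_z, "Z"] = df.loc[need_z, "BETA"] / df.loc[need_z, "SE"]
    _fail_rows(df["Z"].isna().to_numpy(), "cannot determine Z (need Z or BETA+SE)")

    sign_clash = (
        df["BETA"].notna()
        & (df["BETA"] != 0)
        & (df["Z"] != 0)
        & (np.sign(df["BETA"]) != np.sign(df["Z"]))
    )
    _fail_rows(sign_clash.to_numpy(), "sign of Z disagrees with sign of BETA")

    need_p = df["P"].isna()
    df.loc[need_p, "P"] = zscore_to_pvalue(df.loc[need_p, "Z"].to_numpy())
    _fail_rows(
        ((df["P"] <= 0) | (df["P"] > 1)).to_numpy(), "P-value outside (0, 1]"
    )

    # stated P wildly inconsistent with Z is suspicious but tolerated (files
    # round P aggressively); warn rather than reject
    expect = zscore_to_pvalue(df["Z"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(df["P"].to_numpy() - expect) / expect
    n_off = int((rel > 1e-3).sum())
    if n_off:
        logger.warning("%d P-values deviate >0.1%% from their Z-scores", n_off)

    return sort_by_position(df[SUMSTATS_COLUMNS])


def read_sumstats(path, meta: TraitMeta | None = None) -> pd.DataFrame:
    """Read a tab-separated summary-statistics file into the canonical frame.

    Parameters
    ----------
    path
        TSV file with header ``SNP CHR BP A1 A2 BETA SE Z P N``.
    meta
        Optional trait description; recorded in ``df.attrs['trait']``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    df = validate_sumstats(df)
    if meta is not None:
        df.attrs["trait"] = meta
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write the canonical dialect back to disk (X as chromosome 23)."""
    out = df[SUMSTATS_COLUMNS].copy()
    out["CHR"] = out["CHR"].map(normalize_chrom)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# harmonization


def harmonize(a: pd.DataFrame, b: pd.DataFrame):
    """Pair two traits' summary statistics on shared variants.

    Trait B is aligned to trait A's allele coding: a swapped effect/other
    pair negates B's BETA and Z; strand flips (A<->T, C<->G complements)
    are reconciled; strand-ambiguous palindromic variants (A/T or C/G in
    either trait) are dropped and counted, as are irreconcilable allele
    pairs.

    Returns
    -------
    (paired, report)
        ``paired`` has one row per retained shared variant with trait A's
        coordinates/alleles and suffixed per-trait statistics columns
        (``BETA_a`` ... ``N_b``); ``report`` is a :class:`HarmonizeReport`.
    """
    merged = a.merge(b, on="SNP", suffixes=("_a", "_b"), how="inner")
    report = HarmonizeReport()
    if merged.empty:
        cols = ["SNP", "CHR", "BP", "A1", "A2"] + [
            f"{c}_{t}" for t in ("a", "b") for c in ("BETA", "SE", "Z", "P", "N")
        ]
        return pd.DataFrame(columns=cols), report

    a1a, a2a = merged["A1_a"], merged["A2_a"]
    a1b, a2b = merged["A1_b"], merged["A2_b"]
    comp = lambda s: s.map(_COMPLEMENT)  # noqa: E731

    palindromic = (a1a == comp(a2a)) | (a1b == comp(a2b))
    same = (a1b == a1a) & (a2b == a2a)
    swapped = (a1b == a2a) & (a2b == a1a)
    flipped = (comp(a1b) == a1a) & (comp(a2b) == a2a)
    flip_swapped = (comp(a1b) == a2a) & (comp(a2b) == a1a)

    keep = ~palindromic & (same | swapped | flipped | flip_swapped)
    negate = ~palindromic & (swapped | flip_swapped)

    report.n_palindromic_dropped = int(palindromic.sum())
    irreconcilable = ~palindromic & ~keep
    report.n_irreconcilable_dropped = int(irreconcilable.sum())
    report.dropped_ids = merged.loc[palindromic | irreconcilable, "SNP"].tolist()
    report.n_swapped = int((swapped | flip_swapped)[keep].sum())
    report.n_strand_flipped = int((flipped | flip_swapped)[keep].sum())
    for snp in merged.loc[irreconcilable, "SNP"]:
        logger.info("harmonize: dropping %s (irreconcilable allele pair)", snp)

    out = merged.loc[keep].copy()
    out.loc[negate[keep], ["BETA_b", "Z_b"]] *= -1.0
    out = out.rename(columns={"CHR_a": "CHR", "BP_a": "BP", "A1_a": "A1", "A2_a": "A2"})
    out = out.drop(columns=["CHR_b", "BP_b", "A1_b", "A2_b"])
    out = sort_by_position(out)
    report.n_shared = len(out)
    return out, report


# ---------------------------------------------------------------------------
# annotation formats: BED genes, GMT pathways, PPI edge list


def read_gene_bed(path) -> pd.DataFrame:
    """Read 4+ column BED gene annotation into 1-based inclusive intervals.

    BED is 0-based half-open on disk, so ``start`` gains 1 and ``end`` is
    kept.  Returns columns ``gene_id, chrom, start, end`` sorted by
    (chrom, start).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
        dtype={0: str, 3: str},
    )
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "gene_id"].iloc[0]
        raise SumstatsError(f"gene {bad}: empty or inverted interval")
    key = _chrom_sort_key(df["chrom"])
    order = np.lexsort((df["start"].to_numpy(), key.to_numpy()))
    return df.iloc[order][["gene_id", "chrom", "start", "end"]].reset_index(drop=True)


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    """Write 1-based inclusive gene intervals as 4-column BED."""
    out = genes.copy()
    out["start"] = out["start"].astype(np.int64) - 1
    out[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: ``{pathway_id: (description, [genes])}``."""
    pathways = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SumstatsError(f"GMT line {lineno}: fewer than 3 fields")
            pid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if pid in pathways:
                raise SumstatsError(f"GMT line {lineno}: duplicate pathway {pid}")
            pathways[pid] = (desc, genes)
    return pathways


def write_gmt(pathways: dict, path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, genes) in pathways.items():
            fh.write("\t".join([pid, desc, *genes]) + "\n")


def read_ppi_edges(path) -> list:
    """Read an undirected two-column PPI edge list (self-loops dropped)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
    return [(u, v) for u, v in zip(df["a"], df["b"]) if u != v]


def write_ppi_edges(edges, path) -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
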