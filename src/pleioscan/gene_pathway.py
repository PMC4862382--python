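"""SNP-to-gene mapping, cross-trait gene merging, pathway enrichment and
pathway crosstalk.

Candidate markers are assigned to the gene whose interval contains them;
otherwise to the most proximate gene within a 50-kb flank on either side,
else left unmapped.  Per-trait gene lists are merged by a 2-of-k rule,
optionally purged of the strongly linked HLA genes, and tested for
pathway over-representation with the one-sided hypergeometric tail
P(X >= k) against a finite reference gene universe, keeping only pathways
with at least 3 list genes and at most 300 reference genes before
Benjamini–Hochberg adjustment.  Crosstalk between enriched pathways is the
count of protein–protein-interaction edges linking their observed gene
sets, assessed against a size-matched random-gene-set permutation null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("pleioscan")

#: default gene-mapping flank in bp (5' and 3')
DEFAULT_FLANK = 50_000

#: HLA genes removed before pathway analysis (strong linkage disequilibrium)
DEFAULT_HLA_GENES = (
    "HLA-B", "HLA-C", "HLA-DOA", "HLA-DQA1", "HLA-DQB1", "HLA-DRB1", "HLA-G",
)

ENRICHMENT_COLUMNS = [
    "pathway_id", "genes_in_pathway", "genes_observed", "genes_expected",
    "ratio", "raw_p", "adj_p", "observed_genes",
]


# ---------------------------------------------------------------------------
# SNP -> gene mapping


def map_snp_to_gene(
    chrom: str, pos: int, genes: pd.DataFrame, flank: int = DEFAULT_FLANK
):
    """Gene assignment for a single position, or None if unmapped.

    Containment wins; otherwise the nearest gene boundary within ``flank``
    bp on either side; equidistant ties break toward the smaller gene
    start.  ``genes`` has 1-based inclusive columns gene_id/chrom/start/end.
    """
    sub = genes.loc[genes["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        return None
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    dist = np.maximum.reduce([start - pos, pos - end, np.zeros(len(sub))])
    best = np.min(dist)
    if best > flank:
        return None
    hits = np.flatnonzero(dist == best)
    # ties (including multiple containing genes): smallest start coordinate
    winner = hits[np.argmin(start[hits])]
    return sub["gene_id"].iloc[winner]


def map_snps_to_genes(
    variants: pd.DataFrame, genes: pd.DataFrame, flank: int = DEFAULT_FLANK
) -> pd.DataFrame:
    """Vectorized gene assignment for a variant table (columns CHR, BP).

    Returns a copy of ``variants`` with a ``gene_id`` column (NaN when no
    gene lies within the flank).  Same semantics as :func:`map_snp_to_gene`.
    """
    out = variants.copy()
    assigned = np.full(len(variants), None, dtype=object)
    for chrom, grp in variants.groupby(variants["CHR"].astype(str), sort=False):
        sub = genes.loc[genes["chrom"].astype(str) == chrom]
        if sub.empty:
            continue
        start = sub["start"].to_numpy()[None, :]
        end = sub["end"].to_numpy()[None, :]
        pos = grp["BP"].to_numpy()[:, None]
        dist = np.maximum.reduce(
            [start - pos, pos - end, np.zeros((len(grp), len(sub)))]
        )
        # tie-break toward smaller start: stable argmin over genes sorted by start
        order = np.argsort(start[0], kind="stable")
        dist = dist[:, order]
        ids = sub["gene_id"].to_numpy()[order]
        best_idx = np.argmin(dist, axis=1)
        best = dist[np.arange(len(grp)), best_idx]
        hit = best <= flank
        vals = np.where(hit, ids[best_idx], None)
        assigned[variants.index.get_indexer(grp.index)] = vals
    out["gene_id"] = assigned
    return out


def candidate_genes(
    candidates: pd.DataFrame, genes: pd.DataFrame, flank: int = DEFAULT_FLANK
) -> list:
    """Sorted unique genes hit by a candidate-marker table (one count per
    gene regardless of how many markers map to it)."""
    mapped = map_snps_to_genes(candidates, genes, flank)["gene_id"].dropna()
    return sorted(set(mapped))


# ---------------------------------------------------------------------------
# merging and filtering gene lists


def merge_trait_genes(gene_lists, min_traits: int = 2) -> list:
    """Genes present in at least ``min_traits`` of the per-trait lists."""
    gene_lists = list(gene_lists)
    if min_traits > len(gene_lists):
        raise ValueError(
            f"min_traits={min_traits} exceeds the {len(gene_lists)} lists supplied"
        )
    counts: dict = {}
    for lst in gene_lists:
        for g in set(lst):
            counts[g] = counts.get(g, 0) + 1
    return sorted(g for g, c in counts.items() if c >= min_traits)


def filter_hla(genes, hla_ids=DEFAULT_HLA_GENES):
    """Remove HLA genes (exact id match); returns (filtered, removed_count)."""
    hla = set(hla_ids)
    kept = [g for g in genes if g not in hla]
    return kept, len(genes) - len(kept)


# ---------------------------------------------------------------------------
# hypergeometric enrichment


def hypergeom_enrich(
    gene_list,
    pathways: dict,
    reference,
    min_list_genes: int = 3,
    max_pathway_genes: int = 300,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each pathway.

    ``pathways`` maps pathway_id -> (description, genes) (GMT semantics);
    ``reference`` is the gene universe of size N.  Pathway genes are
    intersected with the reference; pathways with fewer than
    ``min_list_genes`` observed list genes or more than
    ``max_pathway_genes`` reference genes are excluded before the
    Benjamini–Hochberg adjustment.  raw_p is the upper tail P(X >= k) of
    Hypergeometric(N, K, n).

    Returns rows sorted by raw_p with a ``significant`` flag at
    adj_p < ``alpha``.
    """
    reference = set(reference)
    gene_set = set(gene_list)
    missing = gene_set - reference
    if missing:
        raise ValueError(
            f"gene(s) absent from the reference universe: {sorted(missing)[:5]}"
        )
    N, n = len(reference), len(gene_set)
    rows = []
    for pid, (_, members) in pathways.items():
        in_ref = set(members) & reference
        K = len(in_ref)
        observed = sorted(gene_set & in_ref)
        k = len(observed)
        if K > max_pathway_genes or k < min_list_genes:
            continue
        expected = n * K / N
        raw_p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "pathway_id": pid,
                "genes_in_pathway": K,
                "genes_observed": k,
                "genes_expected": expected,
                "ratio": k / expected if expected > 0 else np.nan,
                "raw_p": min(raw_p, 1.0),
                "observed_genes": observed,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS + ["significant"])
    out["adj_p"] = multipletests(out["raw_p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["adj_p"] < alpha
    out = out.sort_values(["raw_p", "pathway_id"], kind="stable").reset_index(drop=True)
    return out[ENRICHMENT_COLUMNS + ["significant"]]


# ---------------------------------------------------------------------------
# pathway crosstalk


def _crosstalk_score(edges_idx: np.ndarray, in_a: np.ndarray, in_b: np.ndarray) -> int:
    """PPI edges with one endpoint in each set (shared genes count through
    their incident edges; self-loops were dropped on read)."""
    u, v = edges_idx[:, 0], edges_idx[:, 1]
    return int(((in_a[u] & in_b[v]) | (in_b[u] & in_a[v])).sum())


def crosstalk_network(
    enriched: pd.DataFrame,
    ppi_edges,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Permutation test of PPI connectivity between enriched pathway pairs.

    For every unordered pair of enriched pathways the score counts PPI
    edges joining their observed gene sets.  The null redraws, ``n_perm``
    times, two random gene sets of the same sizes from the PPI node
    universe and rescores; perm_p = (1 + #{null >= observed}) / (n_perm+1).
    Pairs with perm_p < ``alpha`` are retained (all pairs if ``keep_all``).

    ``enriched`` needs columns pathway_id, adj_p, observed_genes.  Edge
    weight is perm_p and node weight the pathway's adj_p, mirroring the
    usual crosstalk-graph rendering.
    """
    if len(enriched) < 2:
        return pd.DataFrame(
            columns=["PATHWAY_A", "PATHWAY_B", "SCORE", "PERM_P", "significant"]
        )
    nodes = sorted({g for e in ppi_edges for g in e})
    node_idx = {g: i for i, g in enumerate(nodes)}
    edges_idx = np.array(
        [(node_idx[u], node_idx[v]) for u, v in ppi_edges if u != v], dtype=np.int64
    ).reshape(-1, 2)
    rng = np.random.default_rng(seed)

    ordered = enriched.sort_values("pathway_id", kind="stable")
    sets = {
        row["pathway_id"]: np.array(
            [node_idx[g] for g in row["observed_genes"] if g in node_idx],
            dtype=np.int64,
        )
        for _, row in ordered.iterrows()
    }

    def membership(idx_arr):
        mask = np.zeros(len(nodes), dtype=bool)
        mask[idx_arr] = True
        return mask

    rows = []
    pids = list(sets)
    for i in range(len(pids)):
        for j in range(i + 1, len(pids)):
            a, b = pids[i], pids[j]
            size_a, size_b = len(sets[a]), len(sets[b])
            obs = (
                _crosstalk_score(edges_idx, membership(sets[a]), membership(sets[b]))
                if edges_idx.size
                else 0
            )
            if edges_idx.size and len(nodes) >= size_a and len(nodes) >= size_b:
                null_ge = 0
                for _ in range(n_perm):
                    ra = rng.choice(len(nodes), size=size_a, replace=False)
                    rb = rng.choice(len(nodes), size=size_b, replace=False)
                    if _crosstalk_score(edges_idx, membership(ra), membership(rb)) >= obs:
                        null_ge += 1
                perm_p = (1 + null_ge) / (n_perm + 1)
            else:
                perm_p = 1.0
            rows.append(
                {"PATHWAY_A": a, "PATHWAY_B": b, "SCORE": obs, "PERM_P": perm_p,
                 "significant": perm_p < alpha}
            )
    out = pd.DataFrame(rows)
    logger.info(
        "crosstalk: %d pairs tested, %d retained at perm P < %g",
        len(out), int(out["significant"].sum()), alpha,
    )
    if not keep_all:
        out = out.loc[out["significant"]].reset_index(drop=True)
    return out
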