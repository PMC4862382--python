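"""End-to-end orchestration: simulate -> scan -> PRS -> joint test -> pathways.

A run is described by a flat ``key = value`` configuration file (or a
:class:`RunConfig` built in code).  Stages execute in dependency order;
every file written is recorded in a manifest with a SHA-256 content
checksum, so identical configuration + seed reproduces identical
checksums.  Defaults are the analysis constants used throughout the
package: the five risk-score thresholds, loci at q <= 0.05, candidate
markers at q <= 0.16, 50-kb gene flank, pathway significance at adjusted
P < 0.05 and crosstalk edges at permutation P < 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gene_pathway, joint_test, prs, sumstats_io, synthetic_data
from .gene_pathway import DEFAULT_FLANK
from .prs import DEFAULT_THRESHOLDS, PRS_RESULT_COLUMNS

logger = logging.getLogger("pleioscan")

ENRICHMENT_HEADER = {
    "pathway_id": "Pathway",
    "observed_genes": "Genes found in pathway",
    "genes_in_pathway": "# gene in pathway",
    "genes_observed": "# gene observed",
    "genes_expected": "# gene expected",
    "ratio": "Observed/expected ratio",
    "raw_p": "Raw P-value",
    "adj_p": "Adjusted P-value",
}


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the standard analysis constants."""

    # stage toggles
    simulate: bool = True
    prs: bool = True
    joint: bool = True
    pathways: bool = True
    # synthetic-data conditions (see synthetic_data.SimConfig)
    n_individuals: int = 2000
    n_variants: int = 3000
    n_causal: int = 120
    n_shared_causal: int = 50
    shared_effect_corr: float = 0.8
    effect_sd: float = 0.12
    prevalence: float = 0.30
    n_smoking_traits: int = 3
    n_genes: int = 300
    n_pathways: int = 20
    pathway_causal_enrichment: float = 4.0
    n_enriched_pathways: int = 5
    ppi_edge_prob: float = 0.01
    ppi_within_pathway_prob: float = 0.05
    # analysis constants
    thresholds: tuple = DEFAULT_THRESHOLDS
    q_loci: float = 0.05
    q_candidates: float = 0.16
    flank: int = DEFAULT_FLANK
    merge_window: int = 250_000
    min_traits: int = 2
    n_perm: int = 1000
    enrich_alpha: float = 0.05
    perm_alpha: float = 0.05
    seed: int = 0
    # paths
    out_dir: str = "pleioscan_out"
    # optional external inputs (used when the simulate stage is off)
    genes_path: str = ""
    gmt_path: str = ""
    ppi_path: str = ""
    sumstats_paths: tuple = ()

    def validate(self) -> None:
        for name in ("genes_path", "gmt_path", "ppi_path"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for p in self.sumstats_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"sumstats path {p} does not exist")
        if not self.simulate:
            if self.joint and not self.sumstats_paths:
                raise ValueError("joint stage needs sumstats_paths when simulate is off")
            if self.pathways and not (self.genes_path and self.gmt_path and self.ppi_path):
                raise ValueError(
                    "pathways stage needs genes/gmt/ppi paths when simulate is off"
                )


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def load_config(path) -> RunConfig:
    """Parse a flat ``key = value`` configuration file ('#' comments)."""
    values: dict = {}
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
            default = getattr(RunConfig, key, None)
            if isinstance(default, bool):
                values[key] = _BOOL[raw.lower()]
            elif isinstance(default, int):
                values[key] = int(raw)
            elif isinstance(default, float):
                values[key] = float(raw)
            elif isinstance(default, tuple):
                parts = [s for s in raw.replace(",", " ").split() if s]
                values[key] = tuple(
                    float(s) if key == "thresholds" else s for s in parts
                )
            else:
                values[key] = raw
    return RunConfig(**values)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, root: Path):
        self.root = root
        self.files: dict = {}

    def add(self, path: Path) -> None:
        self.files[str(path.relative_to(self.root))] = _sha256(path)

    def write(self) -> Path:
        out = self.root / "manifest.json"
        out.write_text(json.dumps(self.files, indent=2, sort_keys=True) + "\n")
        return out


def _write_tsv(df: pd.DataFrame, path: Path, manifest: _Manifest, columns=None) -> None:
    out = df[columns] if columns else df
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")
    manifest.add(path)


def _stage_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    The simulated study has one binary (schizophrenia-like) GWAS cohort,
    ``n_smoking_traits`` quantitative GWAS cohorts sharing the same causal
    architecture (fresh individuals each), and two held-out target cohorts
    for the reciprocal risk-score arm.  A stage failure propagates after
    logging the stage name.
    """
    config.validate()
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(root)
    seeds = _stage_seeds(config.seed, config.n_smoking_traits + 4)

    sim_kwargs = dict(
        n_individuals=config.n_individuals,
        n_variants=config.n_variants,
        n_causal_a=config.n_causal,
        n_causal_b=config.n_causal,
        n_shared_causal=config.n_shared_causal,
        shared_effect_corr=config.shared_effect_corr,
        effect_sd_a=config.effect_sd,
        effect_sd_b=config.effect_sd,
        prevalence=config.prevalence,
        n_genes=config.n_genes,
        n_pathways=config.n_pathways,
        pathway_causal_enrichment=config.pathway_causal_enrichment,
        n_enriched_pathways=config.n_enriched_pathways,
        ppi_edge_prob=config.ppi_edge_prob,
        ppi_within_pathway_prob=config.ppi_within_pathway_prob,
    )

    sumstats: dict = {}
    genes = pathways = ppi = None
    target_quant = target_binary = None

    if config.simulate:
        logger.info("stage simulate: drawing cohorts and annotation")
        try:
            base_cfg = synthetic_data.SimConfig(seed=seeds[0], **sim_kwargs)
            scz_cohort = synthetic_data.simulate_cohort(base_cfg)
            truth = scz_cohort.truth
            sumstats["scz"] = synthetic_data.scan_summary_stats(scz_cohort, "binary")
            for i in range(config.n_smoking_traits):
                cfg_i = synthetic_data.SimConfig(seed=seeds[1 + i], **sim_kwargs)
                cohort = synthetic_data.simulate_cohort(cfg_i, truth=truth)
                sumstats[f"smoke{i + 1}"] = synthetic_data.scan_summary_stats(
                    cohort, "quant"
                )
            tq_cfg = synthetic_data.SimConfig(
                seed=seeds[config.n_smoking_traits + 1], **sim_kwargs
            )
            target_quant = synthetic_data.simulate_cohort(tq_cfg, truth=truth)
            tb_cfg = synthetic_data.SimConfig(
                seed=seeds[config.n_smoking_traits + 2], **sim_kwargs
            )
            target_binary = synthetic_data.simulate_cohort(tb_cfg, truth=truth)
            genes, pathways, ppi = synthetic_data.simulate_annotation(base_cfg, truth)

            for name, df in sumstats.items():
                path = root / f"{name}.sumstats.tsv"
                sumstats_io.write_sumstats(df, path)
                manifest.add(path)
            for label, cohort in (("nd_target", target_quant), ("scz_target", target_binary)):
                dpath = root / f"{label}.dosages.tsv"
                cohort.dosage_frame().to_csv(dpath, sep="\t")
                manifest.add(dpath)
                ppath = root / f"{label}.pheno.tsv"
                cohort.phenotype_frame().to_csv(ppath, sep="\t", index=False)
                manifest.add(ppath)
            gpath = root / "genes.bed"
            sumstats_io.write_gene_bed(genes, gpath)
            manifest.add(gpath)
            mpath = root / "pathways.gmt"
            sumstats_io.write_gmt(pathways, mpath)
            manifest.add(mpath)
            epath = root / "ppi.edges"
            sumstats_io.write_ppi_edges(ppi, epath)
            manifest.add(epath)
        except Exception:
            logger.error("stage simulate failed; downstream stages aborted")
            raise
    else:
        if config.sumstats_paths:
            for p in config.sumstats_paths:
                sumstats[Path(p).stem] = sumstats_io.read_sumstats(p)
        if config.genes_path:
            genes = sumstats_io.read_gene_bed(config.genes_path)
        if config.gmt_path:
            pathways = sumstats_io.read_gmt(config.gmt_path)
        if config.ppi_path:
            ppi = sumstats_io.read_ppi_edges(config.ppi_path)

    if config.prs and config.simulate:
        logger.info("stage prs: reciprocal risk-score prediction")
        try:
            tables = prs.reciprocal_analysis(
                sumstats["scz"],
                target_quant.dosage_frame(),
                target_quant.phenotype_frame(),
                "quantitative",
                sumstats["smoke1"],
                target_binary.dosage_frame(),
                target_binary.phenotype_frame(),
                "binary",
                thresholds=config.thresholds,
            )
            _write_tsv(
                tables["a_to_b"], root / "prs_scz_to_nd.tsv", manifest,
                columns=PRS_RESULT_COLUMNS,
            )
            _write_tsv(
                tables["b_to_a"], root / "prs_nd_to_scz.tsv", manifest,
                columns=PRS_RESULT_COLUMNS,
            )
        except Exception:
            logger.error("stage prs failed; downstream stages aborted")
            raise

    candidates_per_trait: dict = {}
    if config.joint:
        logger.info("stage joint: weakest-link scans")
        try:
            if config.simulate:
                pairs = [
                    (name, sumstats["scz"], sumstats[name])
                    for name in sumstats
                    if name != "scz"
                ]
            else:
                names = list(sumstats)
                pairs = [
                    (names[j], sumstats[names[0]], sumstats[names[j]])
                    for j in range(1, len(names))
                ]
            for name, a, b in pairs:
                paired, report = sumstats_io.harmonize(a, b)
                frames = [
                    paired[["SNP", "CHR", "BP"]].assign(Z=paired[f"Z_{t}"])
                    for t in ("a", "b")
                ]
                results, loci, cand = joint_test.run_joint_scan(
                    frames,
                    q_loci=config.q_loci,
                    q_candidates=config.q_candidates,
                    merge_window=config.merge_window,
                    genes=genes,
                )
                logger.info(
                    "joint %s: %d shared variants (%d dropped), %d loci, %d candidates",
                    name, report.n_shared,
                    report.n_palindromic_dropped + report.n_irreconcilable_dropped,
                    len(loci), len(cand),
                )
                _write_tsv(results, root / f"joint_{name}.tsv", manifest)
                _write_tsv(
                    loci, root / f"loci_{name}.tsv", manifest,
                    columns=["LEAD_SNP", "CHR", "START", "END", "N_MARKERS", "GENE"],
                )
                candidates_per_trait[name] = cand
        except Exception:
            logger.error("stage joint failed; downstream stages aborted")
            raise

    if config.pathways:
        logger.info("stage pathways: gene mapping, enrichment, crosstalk")
        try:
            if genes is None or pathways is None or ppi is None:
                raise ValueError("pathways stage requires gene/pathway/PPI annotation")
            if not candidates_per_trait:
                raise ValueError("pathways stage requires joint-stage candidates")
            per_trait_genes = [
                gene_pathway.candidate_genes(cand, genes, config.flank)
                for cand in candidates_per_trait.values()
            ]
            min_traits = min(config.min_traits, len(per_trait_genes))
            merged = gene_pathway.merge_trait_genes(per_trait_genes, min_traits)
            filtered, n_hla = gene_pathway.filter_hla(merged)
            logger.info(
                "pathways: %d merged genes (>=%d traits), %d after HLA filter",
                len(merged), min_traits, len(filtered),
            )
            gene_list_path = root / "merged_genes.txt"
            gene_list_path.write_text("".join(f"{g}\n" for g in filtered))
            manifest.add(gene_list_path)

            reference = genes["gene_id"].tolist()
            enriched = gene_pathway.hypergeom_enrich(
                filtered, pathways, reference, alpha=config.enrich_alpha
            )
            table = enriched.rename(columns=ENRICHMENT_HEADER)[
                list(ENRICHMENT_HEADER.values())
            ].copy()
            table["Genes found in pathway"] = table["Genes found in pathway"].map(
                ", ".join
            )
            _write_tsv(table, root / "enrichment.tsv", manifest)
            logger.info(
                "pathways: %d pathways tested, %d significant at adjusted P < %g",
                len(enriched), int(enriched["significant"].sum()), config.enrich_alpha,
            )

            net = gene_pathway.crosstalk_network(
                enriched.loc[enriched["significant"]],
                ppi,
                n_perm=config.n_perm,
                alpha=config.perm_alpha,
                seed=seeds[-1],
            )
            _write_tsv(
                net, root / "crosstalk.tsv", manifest,
                columns=["PATHWAY_A", "PATHWAY_B", "SCORE", "PERM_P"],
            )
        except Exception:
            logger.error("stage pathways failed")
            raise

    manifest.write()
    logger.info("pipeline complete: %d files in %s", len(manifest.files), root)
    return manifest.files
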