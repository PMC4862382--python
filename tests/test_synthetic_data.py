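"""Generator: determinism, liability model, scan calibration, annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pleioscan.synthetic_data as sd
from pleioscan import joint_test as jt
from pleioscan import gene_pathway as gp


SMALL = dict(n_individuals=500, n_variants=200, n_causal_a=10, n_causal_b=10,
             n_shared_causal=5, n_genes=20)


class TestSimConfig:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_individuals=0),
            dict(n_shared_causal=50, n_causal_a=10, n_causal_b=60),
            dict(maf_range=(0.0, 0.5)),
            dict(maf_range=(0.1, 0.6)),
            dict(prevalence=1.0),
            dict(shared_effect_corr=1.5),
            dict(effect_sd_a=0.0),
        ],
    )
    def test_invalid_configs_rejected_before_sampling(self, bad):
        kw = {**SMALL, **bad}
        with pytest.raises(ValueError):
            sd.SimConfig(**kw)


class TestSimulateCohort:
    def test_identical_seed_bit_identical(self):
        cfg = sd.SimConfig(seed=11, **SMALL)
        a, b = sd.simulate_cohort(cfg), sd.simulate_cohort(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(a.phenotype_quant, b.phenotype_quant)
        np.testing.assert_array_equal(a.phenotype_binary, b.phenotype_binary)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_dosage_frequencies_match_mafs(self):
        cfg = sd.SimConfig(seed=5, n_individuals=4000, n_variants=100,
                           n_causal_a=0, n_causal_b=0, n_shared_causal=0)
        co = sd.simulate_cohort(cfg)
        freq = co.dosages.mean(axis=0) / 2
        maf = co.variants["MAF"].to_numpy()
        se = np.sqrt(maf * (1 - maf) / (2 * cfg.n_individuals))
        assert (np.abs(freq - maf) < 4 * se).mean() > 0.95

    def test_half_prevalence_with_no_effects(self):
        cfg = sd.SimConfig(seed=2, prevalence=0.5, covariate_effects=(0, 0, 0),
                           n_causal_a=0, n_causal_b=0, n_shared_causal=0,
                           n_individuals=4000, n_variants=50)
        co = sd.simulate_cohort(cfg)
        se = np.sqrt(0.25 / 4000)
        assert abs(co.phenotype_binary.mean() - 0.5) < 3 * se

    def test_perfect_effect_correlation_is_proportional(self):
        cfg = sd.SimConfig(seed=3, shared_effect_corr=1.0, **SMALL)
        truth = sd.simulate_cohort(cfg).truth
        shared = truth.loc[truth["causal_a"] & truth["causal_b"]]
        np.testing.assert_allclose(shared["effect_a"], shared["effect_b"],
                                   rtol=1e-12)

    def test_truth_reuse_keeps_architecture_fresh_individuals(self):
        cfg = sd.SimConfig(seed=4, **SMALL)
        a = sd.simulate_cohort(cfg)
        b = sd.simulate_cohort(sd.with_seed(cfg, 99), truth=a.truth)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert not np.array_equal(a.dosages, b.dosages)

    def test_liability_scale_heritability(self):
        # realized var(G)/(var(G)+1) should match 2*sum maf(1-maf) e^2 over
        # (same + 1) within 10% relative, averaged over seeds, no covariates
        real, theo = [], []
        for seed in range(10):
            cfg = sd.SimConfig(seed=seed, n_individuals=20_000, n_variants=400,
                               n_causal_a=0, n_causal_b=100, n_shared_causal=0,
                               covariate_effects=(0, 0, 0))
            co = sd.simulate_cohort(cfg)
            vg = co.genetic_liability.var()
            real.append(vg / (vg + 1))
            maf = co.truth["MAF"].to_numpy()
            eff = co.truth["effect_b"].to_numpy()
            h = float((2 * maf * (1 - maf)) @ (eff**2))
            theo.append(h / (h + 1))
        assert np.mean(real) == pytest.approx(np.mean(theo), rel=0.10)


class TestScanSummaryStats:
    def test_perfect_fit_recovers_slope_exactly(self):
        cfg = sd.SimConfig(seed=0, n_individuals=6, n_variants=1,
                           n_causal_a=0, n_causal_b=0, n_shared_causal=0)
        co = sd.simulate_cohort(cfg)
        co.dosages = np.array([[0], [1], [2], [0], [1], [2]], dtype=np.int8)
        co.phenotype_quant = co.dosages[:, 0].astype(float)
        ss = sd.scan_summary_stats(co, "quant", include_covariates=False)
        assert ss["BETA"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert ss["P"].iloc[0] == sd.zscore_to_pvalue(ss["Z"].iloc[0])

    def test_null_scan_pvalues_uniform(self):
        cfg = sd.SimConfig(seed=8, n_individuals=800, n_variants=5000,
                           n_causal_a=0, n_causal_b=0, n_shared_causal=0)
        co = sd.simulate_cohort(cfg)
        ss = sd.scan_summary_stats(co, "quant")
        p = ss["P"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01
        frac = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 5000)
        assert abs(frac - 0.05) < 3 * se

    def test_binary_scan_null_calibrated(self):
        cfg = sd.SimConfig(seed=9, n_individuals=1500, n_variants=1000,
                           n_causal_a=0, n_causal_b=0, n_shared_causal=0)
        co = sd.simulate_cohort(cfg)
        ss = sd.scan_summary_stats(co, "binary")
        frac = (ss["P"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < 3.5 * se

    def test_monomorphic_variant_flagged(self):
        cfg = sd.SimConfig(seed=1, **SMALL)
        co = sd.simulate_cohort(cfg)
        co.dosages[:, 3] = 0
        ss = sd.scan_summary_stats(co, "quant")
        row = ss.iloc[3]
        assert row["MONOMORPHIC"] and row["Z"] == 0 and row["P"] == 1.0

    def test_strong_shared_variant_wins_joint_scan(self):
        # one shared causal variant, effect 0.5 per allele at MAF 0.3,
        # n = 2,000: it should carry the smallest overlap P essentially always
        wins = 0
        reps = 20
        for seed in range(reps):
            cfg = sd.SimConfig(seed=seed, n_individuals=2000, n_variants=400,
                               n_causal_a=1, n_causal_b=1, n_shared_causal=1)
            truth = sd._draw_truth(cfg, np.random.default_rng(seed))
            truth.loc[:, ["causal_a", "causal_b"]] = False
            truth.loc[:, ["effect_a", "effect_b"]] = 0.0
            truth.loc[200, ["causal_a", "causal_b"]] = True
            truth.loc[200, ["effect_a", "effect_b"]] = 0.5
            truth.loc[200, "MAF"] = 0.3
            co = sd.simulate_cohort(cfg, truth=truth)
            frames = [sd.scan_summary_stats(co, "quant"),
                      sd.scan_summary_stats(co, "binary")]
            results, _, _ = jt.run_joint_scan(frames)
            if results.loc[results["JOINT_P"].idxmin(), "SNP"] == "rs201":
                wins += 1
        assert wins >= int(0.95 * reps)


class TestSimulateAnnotation:
    def test_zero_gaps_cover_all_variants(self):
        cfg = sd.SimConfig(seed=6, n_individuals=10, n_variants=40,
                           n_causal_a=0, n_causal_b=0, n_shared_causal=0,
                           n_genes=40, gene_length_range=(10_000, 10_000),
                           gene_gap_range=(0, 0))
        genes, _, _ = sd.simulate_annotation(cfg)
        variants = pd.DataFrame({"CHR": "1", "BP": (np.arange(40) + 1) * 10_000})
        mapped = gp.map_snps_to_genes(variants, genes, flank=0)
        assert mapped["gene_id"].notna().all()

    def test_too_many_genes_rejected(self):
        cfg = sd.SimConfig(seed=6, n_individuals=10, n_variants=20,
                           n_causal_a=0, n_causal_b=0, n_shared_causal=0,
                           n_genes=100, gene_length_range=(10_000, 10_000),
                           gene_gap_range=(0, 0))
        with pytest.raises(ValueError, match="do not fit"):
            sd.simulate_annotation(cfg)

    def test_empty_ppi_yields_no_crosstalk(self):
        cfg = sd.SimConfig(seed=6, ppi_edge_prob=0.0,
                           ppi_within_pathway_prob=0.0, **SMALL)
        _, pathways, edges = sd.simulate_annotation(cfg)
        assert edges == []
        enriched = pd.DataFrame(
            {
                "pathway_id": ["PW1", "PW2"],
                "adj_p": [0.01, 0.02],
                "observed_genes": [pathways["PW1"][1][:3], pathways["PW2"][1][:3]],
            }
        )
        net = gp.crosstalk_network(enriched, edges, n_perm=50, keep_all=True)
        assert (net["SCORE"] == 0).all() and (net["PERM_P"] == 1.0).all()

    def test_enriched_pathway_recovered_downstream(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            cfg = sd.SimConfig(seed=seed, n_individuals=10, n_variants=3000,
                               n_causal_a=120, n_causal_b=120, n_shared_causal=50,
                               n_genes=200, n_pathways=10,
                               pathway_causal_enrichment=10.0,
                               n_enriched_pathways=1)
            co = sd.simulate_cohort(cfg)
            genes, pathways, _ = sd.simulate_annotation(cfg, co.truth)
            causal = co.truth.loc[co.truth["causal_a"] | co.truth["causal_b"]]
            gene_list = gp.candidate_genes(causal, genes, flank=0)
            enriched = gp.hypergeom_enrich(
                gene_list, pathways, genes["gene_id"].tolist()
            )
            if not enriched.empty and enriched["pathway_id"].iloc[0] == "PW1":
                hits += 1
        assert hits >= int(0.90 * reps)

    def test_annotation_deterministic(self):
        cfg = sd.SimConfig(seed=12, **SMALL)
        g1, p1, e1 = sd.simulate_annotation(cfg)
        g2, p2, e2 = sd.simulate_annotation(cfg)
        pd.testing.assert_frame_equal(g1, g2)
        assert p1 == p2 and e1 == e2
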