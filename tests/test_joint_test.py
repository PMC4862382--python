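"""Weakest-link overlap statistic, genomic control, FDR and locus merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pleioscan import joint_test as jt
from conftest import make_sumstats


class TestBackgroundAdjust:
    def test_null_median_leaves_pvalues_unchanged(self):
        # z chosen so median(z^2) is exactly the chi^2_1 median -> lambda = 1
        base = np.sqrt(jt.CHI2_1_MEDIAN)
        z = np.concatenate([np.full(150, base), np.full(75, 0.1), np.full(75, 3.0)])
        p, lam = jt.background_adjust(z)
        assert lam == pytest.approx(1.0)
        np.testing.assert_allclose(p, stats.chi2.sf(z**2, 1), rtol=1e-12)

    def test_scale_equivariance(self, rng):
        z = rng.normal(size=5000) * 1.4  # inflated null
        p1, lam1 = jt.background_adjust(z)
        p2, lam2 = jt.background_adjust(z * np.sqrt(2))
        assert lam2 == pytest.approx(2 * lam1, rel=1e-12)
        np.testing.assert_allclose(p2, p1, atol=1e-10)

    def test_recovers_planted_inflation(self):
        lams = []
        for seed in range(10):
            z = np.random.default_rng(seed).normal(size=20_000) * np.sqrt(1.3)
            _, lam = jt.background_adjust(z)
            lams.append(lam)
        assert np.mean(lams) == pytest.approx(1.3, rel=0.05)

    def test_deflation_not_applied(self, rng):
        z = rng.normal(size=5000) * 0.5
        p, lam = jt.background_adjust(z)
        assert lam < 1
        np.testing.assert_allclose(p, stats.chi2.sf(z**2, 1), rtol=1e-12)

    def test_few_variants_skips_adjustment(self, rng):
        z = rng.normal(size=50) * 3
        _, lam = jt.background_adjust(z)
        assert lam == 1.0


class TestOverlapStatistic:
    def test_definition_and_idempotence(self):
        assert jt.overlap_statistic([[0.3, 0.01]]) == pytest.approx(0.3)
        assert jt.overlap_statistic([[0.7, 0.7, 0.7]]) == pytest.approx(0.7)

    def test_matches_sort_oracle(self, rng):
        p = rng.uniform(1e-6, 1.0, size=(200, 5))
        r = jt.overlap_statistic(p)
        oracle = np.sort(p, axis=1)[:, -1]
        np.testing.assert_array_equal(r, oracle)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            jt.overlap_statistic([[0.0, 0.5]])
        with pytest.raises(ValueError):
            jt.overlap_statistic([[1.2, 0.5]])


class TestOverlapPvalue:
    def test_boundary_and_closed_form(self):
        assert jt.overlap_pvalue(1.0, 3) == pytest.approx(1.0)
        assert jt.overlap_pvalue(0.1, 2) == pytest.approx(0.01)

    def test_monte_carlo_agrees_with_square_law(self, rng):
        u = rng.uniform(size=(10**6, 2))
        r = u.max(axis=1)
        hat = (r <= 0.3).mean()
        se = np.sqrt(0.09 * 0.91 / 10**6)
        assert abs(hat - 0.09) < 3 * se

    def test_empirical_null_requires_distributions(self):
        with pytest.raises(ValueError):
            jt.overlap_pvalue(0.1, 2, null="empirical")

    def test_empirical_null_tracks_uniform(self, rng):
        ps = [rng.uniform(size=50_000) for _ in range(2)]
        r = np.array([0.05, 0.2, 0.6])
        emp = jt.overlap_pvalue(r, 2, null="empirical", per_trait_ps=ps)
        np.testing.assert_allclose(emp, r**2, rtol=0.05)


class TestThresholdAndWorstCase:
    def test_two_trait_genomewide_threshold(self):
        # sqrt(5e-8) = 2.236e-4, printed as 2.2e-4
        assert jt.per_trait_threshold(5e-8, 2) == pytest.approx(2.2e-4, rel=0.02)
        assert jt.per_trait_threshold(0.25, 2) == pytest.approx(0.5)
        assert jt.per_trait_threshold(0.07, 1) == pytest.approx(0.07)

    def test_worst_case_reduces_to_nominal_for_one_trait(self):
        assert jt.worst_case_fpr(0.05, 1) == pytest.approx(0.05)

    def test_worst_case_by_simulation(self, rng):
        # one trait pinned at an extreme signal, the other null-uniform
        n = 10**6
        r = np.maximum(1e-300, rng.uniform(size=n))
        rate = (r**2 <= 5e-8).mean()
        expect = jt.worst_case_fpr(5e-8, 2)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(rate - expect) < 3 * se


def bh_stepup_oracle(p):
    """Plain-python BH step-up, independent of the implementation path."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, n * p[i] / rank)
        q[i] = running
    return q


class TestFdrQvalues:
    def test_hand_computed_example(self):
        q = jt.fdr_qvalues([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(q, [0.05] * 5, rtol=1e-12)

    def test_single_p_is_its_own_q(self):
        assert jt.fdr_qvalues([0.37])[0] == pytest.approx(0.37)

    def test_empty_input(self):
        assert jt.fdr_qvalues([]).size == 0

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_stepup_oracle(self, p):
        np.testing.assert_allclose(jt.fdr_qvalues(p), bh_stepup_oracle(p), rtol=1e-9)


class TestAicRationale:
    def test_factor_two_gives_the_016_tier(self):
        assert round(jt.aic_qvalue_rationale(2.0), 2) == 0.16

    def test_zero_penalty_full_mass(self):
        assert jt.aic_qvalue_rationale(0.0) == pytest.approx(1.0)

    def test_classic_significance_point(self):
        assert jt.aic_qvalue_rationale(3.841) == pytest.approx(0.05, abs=5e-4)


def results_frame(bp, joint_p, q, chrom="1"):
    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(len(bp))],
            "CHR": chrom,
            "BP": bp,
            "JOINT_P": joint_p,
            "Q": q,
        }
    )


class TestSelectLoci:
    def test_singleton_locus(self):
        res = results_frame([100], [1e-8], [1e-4])
        loci = jt.select_loci(res)
        assert len(loci) == 1 and loci["N_MARKERS"].iloc[0] == 1

    def test_chaining_within_window(self):
        res = results_frame([1000, 1010], [1e-8, 1e-9], [1e-4, 1e-4])
        loci = jt.select_loci(res, merge_window=250_000)
        assert len(loci) == 1
        assert loci["N_MARKERS"].iloc[0] == 2
        assert loci["LEAD_SNP"].iloc[0] == "rs1"  # smaller joint P leads

    def test_lead_tie_breaks_to_smaller_position(self):
        res = results_frame([1000, 2000], [1e-8, 1e-8], [1e-4, 1e-4])
        assert jt.select_loci(res)["LEAD_SNP"].iloc[0] == "rs0"

    def test_matches_union_find_oracle(self, rng):
        for _ in range(5):
            bp = np.sort(rng.choice(10**7, size=50, replace=False))
            res = results_frame(bp, rng.uniform(1e-12, 1e-6, 50), np.full(50, 0.01))
            window = 250_000
            loci = jt.select_loci(res, merge_window=window)
            # brute force: connected components of the within-window graph
            parent = list(range(50))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(50):
                for j in range(i + 1, 50):
                    if abs(int(bp[i]) - int(bp[j])) <= window:
                        parent[find(i)] = find(j)
            comps = {}
            for i in range(50):
                comps.setdefault(find(i), []).append(i)
            got = sorted(
                (int(r.START), int(r.END), int(r.N_MARKERS))
                for r in loci.itertuples()
            )
            want = sorted(
                (int(bp[min(ix)]), int(bp[max(ix)]), len(ix))
                for ix in comps.values()
            )
            assert got == want


class TestRunJointScan:
    def planted_pair(self, rng, n=2000, planted_z=6.5):
        z_a = rng.normal(size=n)
        z_b = rng.normal(size=n)
        z_a[42] = planted_z
        z_b[42] = planted_z
        return [make_sumstats(z_a), make_sumstats(z_b)]

    def test_planted_shared_variant_recovered(self, rng):
        frames = self.planted_pair(rng)
        results, loci, cand = jt.run_joint_scan(frames)
        assert loci["LEAD_SNP"].iloc[0] == "rs43"
        assert results.loc[results["SNP"] == "rs43", "Q"].iloc[0] <= 0.05
        assert "rs43" in set(cand["SNP"])

    def test_single_trait_signal_excluded_by_weakest_link(self, rng):
        z_a = rng.normal(size=500)
        z_b = rng.normal(size=500)
        z_a[7] = 7.94  # p ~ 1e-15
        z_b[7] = stats.norm.isf(0.1)  # two-sided p = 0.2
        frames = [make_sumstats(z_a), make_sumstats(z_b)]
        results, loci, _ = jt.run_joint_scan(frames, gc_adjust=False)
        row = results.loc[results["SNP"] == "rs8"].iloc[0]
        assert row["R"] == pytest.approx(0.2, rel=1e-3)
        assert row["JOINT_P"] == pytest.approx(0.04, rel=1e-3)
        assert "rs8" not in set(loci["LEAD_SNP"])

    def test_trait_order_symmetry(self, rng):
        frames = self.planted_pair(rng)
        res_ab, loci_ab, _ = jt.run_joint_scan(frames)
        res_ba, loci_ba, _ = jt.run_joint_scan(frames[::-1])
        np.testing.assert_allclose(res_ab["JOINT_P"], res_ba["JOINT_P"], rtol=1e-12)
        np.testing.assert_allclose(res_ab["Q"], res_ba["Q"], rtol=1e-12)
        pd.testing.assert_frame_equal(
            loci_ab[["LEAD_SNP", "START", "END", "N_MARKERS"]],
            loci_ba[["LEAD_SNP", "START", "END", "N_MARKERS"]],
        )

    def test_lowering_one_p_never_hurts(self, rng):
        z_a = rng.normal(size=300)
        z_b = rng.normal(size=300)
        frames = [make_sumstats(z_a), make_sumstats(z_b)]
        res, _, _ = jt.run_joint_scan(frames, gc_adjust=False)
        z_b2 = z_b.copy()
        j = 17
        z_b2[j] = 5.0  # strengthen one variant in one trait
        res2, _, _ = jt.run_joint_scan(
            [make_sumstats(z_a), make_sumstats(z_b2)], gc_adjust=False
        )
        assert res2["R"].iloc[j] <= res["R"].iloc[j] + 1e-15
        assert res2["JOINT_P"].iloc[j] <= res["JOINT_P"].iloc[j] + 1e-15
        assert res2["Q"].iloc[j] <= res["Q"].iloc[j] + 1e-12

    def test_rejection_rate_calibrated_under_null(self, rng):
        u = rng.uniform(size=(10**6, 2))
        joint_p = np.atleast_1d(
            jt.overlap_pvalue(jt.overlap_statistic(u), 2)
        )
        for alpha in (0.05, 0.01):
            rate = (joint_p <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / 10**6)
            assert abs(rate - alpha) < 3 * se
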