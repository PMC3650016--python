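"""Exact Poisson two-library test, BH-FDR and regulation calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import ac_exact, ac_pvalue_exact, bh_stepup_bruteforce
from duomics.dge import (
    ac_probability,
    ac_pvalue_two_sided,
    bh_fdr,
    call_regulation,
    run_dge,
)


class TestAcProbability:
    def test_closed_form_zero_counts_equal_depths(self):
        assert ac_probability(0, 0, 10**6, 10**6) == pytest.approx(0.5, rel=1e-12)

    def test_pmf_symmetric_in_x_y_for_equal_depths(self):
        assert ac_probability(3, 7, 10**6, 10**6) == pytest.approx(
            ac_probability(7, 3, 10**6, 10**6), rel=1e-12
        )

    @pytest.mark.parametrize(
        "x, y, n1, n2",
        [(5, 15, 10**6, 10**6), (0, 9, 2 * 10**6, 10**6), (30, 2, 10**6, 3 * 10**6)],
    )
    def test_matches_exact_rational_oracle(self, x, y, n1, n2):
        assert ac_probability(x, y, n1, n2) == pytest.approx(
            float(ac_exact(x, y, n1, n2)), rel=1e-10
        )

    def test_oracle_grid_small_counts(self):
        n1, n2 = 12_350_974, 11_667_849
        xs = np.repeat(np.arange(31), 31)
        ys = np.tile(np.arange(31), 31)
        got = ac_probability(xs, ys, n1, n2)
        exact = np.array([float(ac_exact(int(x), int(y), n1, n2)) for x, y in zip(xs, ys)])
        assert np.max(np.abs(got - exact)) < 1e-12

    @pytest.mark.parametrize("x", [0, 3, 40])
    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    def test_sums_to_one_over_y(self, x, ratio):
        n1 = 10**6
        n2 = int(ratio * n1)
        ys = np.arange(0, 4000)
        total = ac_probability(np.full_like(ys, x), ys, n1, n2).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            ac_probability(-1, 3, 10**6, 10**6)


class TestAcPvalue:
    def test_observation_at_conditional_center_not_significant(self):
        assert ac_pvalue_two_sided(10, 10, 10**6, 10**6) >= 0.5

    def test_extreme_tail(self):
        assert ac_pvalue_two_sided(0, 100, 10**6, 10**6) < 1e-20

    @pytest.mark.parametrize(
        "x, y, n1, n2",
        [(5, 15, 10**6, 10**6), (3, 7, 2 * 10**6, 10**6), (0, 4, 10**6, 10**6),
         (25, 25, 10**6, 2 * 10**6), (12, 0, 10**6, 10**6)],
    )
    def test_matches_exact_tail_sum_oracle(self, x, y, n1, n2):
        assert ac_pvalue_two_sided(x, y, n1, n2) == pytest.approx(
            float(ac_pvalue_exact(x, y, n1, n2)), rel=1e-9
        )

    def test_monotone_in_tail_deviation(self):
        """Moving y outward along either tail never increases the p-value."""
        x, n1, n2 = 20, 10**6, 10**6
        ys = np.arange(20, 120)
        ps = ac_pvalue_two_sided(np.full_like(ys, x), ys, n1, n2)
        assert np.all(np.diff(ps) <= 1e-12)
        ys_down = np.arange(20, -1, -1)
        ps_down = ac_pvalue_two_sided(np.full_like(ys_down, x), ys_down, n1, n2)
        assert np.all(np.diff(ps_down) <= 1e-12)

    def test_in_unit_interval(self):
        p = ac_pvalue_two_sided(1000, 1, 10**6, 10**6)
        assert 0.0 < p <= 1.0


class TestBhFdr:
    def test_hand_stepup_computation(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_ties_preserved(self):
        out = bh_fdr([0.2, 0.2, 0.2])
        assert out == pytest.approx([0.2, 0.2, 0.2])

    def test_empty_gives_empty(self):
        assert bh_fdr([]).size == 0

    def test_outputs_dominate_inputs_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        out = bh_fdr(p)
        assert np.all(out >= p - 1e-15) and np.all(out <= 1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_bruteforce_stepup_definition(self, p):
        assert bh_fdr(p) == pytest.approx(bh_stepup_bruteforce(np.array(p)), abs=1e-12)


class TestCallRegulation:
    @pytest.mark.parametrize(
        "lr, q, expected",
        [
            (1.0, 0.001, "up"),          # both thresholds inclusive
            (2.3, 0.5, "not_significant"),
            (-1.7, 1e-5, "down"),
            (-1.0, 0.001, "down"),
            (0.9, 1e-9, "not_significant"),
            (math.inf, 1e-9, "up"),
        ],
    )
    def test_threshold_rule(self, lr, q, expected):
        assert call_regulation(lr, q) == expected

    def test_nan_ratio_rejected(self):
        with pytest.raises(ValueError):
            call_regulation(math.nan, 0.01)


class TestRunDge:
    def test_identical_counts_equal_depths_nothing_called(self):
        counts = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(20)],
             "count_s": [50] * 20, "count_r": [50] * 20, "length_nt": [1000] * 20}
        )
        res = run_dge(counts)
        assert (res["call"] == "not_significant").all()

    def test_row_order_equivariance(self, small_counts):
        res1 = run_dge(small_counts)
        res2 = run_dge(small_counts.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(res1, res2)

    def test_single_zero_side_gets_infinite_ratio_but_is_testable(self):
        counts = pd.DataFrame(
            {"gene_id": ["a", "b"], "count_s": [0, 1000],
             "count_r": [1000, 1000], "length_nt": [500, 500]}
        )
        res = run_dge(counts).set_index("gene_id")
        assert math.isinf(res.loc["a", "log2_ratio"]) and res.loc["a", "log2_ratio"] > 0
        assert 0 <= res.loc["a", "p_value"] <= 1

    def test_all_zero_gene_excluded_from_testing(self):
        counts = pd.DataFrame(
            {"gene_id": ["a", "b"], "count_s": [0, 100],
             "count_r": [0, 100], "length_nt": [500, 500]}
        )
        res = run_dge(counts).set_index("gene_id")
        assert math.isnan(res.loc["a", "p_value"])
        assert res.loc["a", "call"] == "not_significant"

    def test_null_type_one_error_controlled(self):
        """Under the null the exact test is conservative: P(p <= a) <= a + 3 sd."""
        from duomics.simulate import SimConfig, simulate_counts

        cfg = SimConfig(n_genes=5000, frac_de=0.0, seed=11)
        counts, _ = simulate_counts(cfg)
        res = run_dge(counts)
        p = res["p_value"].dropna().to_numpy()
        for alpha in (0.05, 0.01):
            frac = float((p <= alpha).mean())
            bound = alpha + 3 * math.sqrt(alpha * (1 - alpha) / p.size)
            assert frac <= bound

    def test_recovers_known_de_genes(self):
        """Power at 4-fold effects and adequate depth: >=90% recall, <=5% false calls."""
        from duomics.simulate import SimConfig, simulate_counts

        cfg = SimConfig(n_genes=2000, depth_s=2.5e6, depth_r=2.5e6,
                        frac_de=0.05, effect_log2=2.0, seed=7)
        counts, truth = simulate_counts(cfg)
        res = run_dge(counts)
        merged = res.merge(truth, on="gene_id")
        called = merged["call"] != "not_significant"
        sens = (called & merged["is_de"]).sum() / merged["is_de"].sum()
        false_rate = (called & ~merged["is_de"]).sum() / max(int(called.sum()), 1)
        assert sens >= 0.9
        assert false_rate <= 0.05
        # calls have the right sign
        sign_ok = merged[called & merged["is_de"]]
        assert all(
            (row.true_log2fc > 0) == (row.call == "up") for row in sign_ok.itertuples()
        )
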