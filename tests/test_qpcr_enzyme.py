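"""qPCR relative quantification and enzyme-activity statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from duomics.qpcr_enzyme import (
    analyze_plate,
    anova_lsd,
    composite_reference,
    ddct_fold,
    fit_kinetic_slope,
    gst_activity,
    pnod_activity,
    strain_ratios,
)
from duomics.simulate import (
    SimConfig,
    simulate_ct_plate,
    simulate_enzyme_assays,
    simulate_kinetic_trace,
    simulate_standard_curve,
)


class TestCompositeReference:
    @pytest.mark.parametrize("refs, expected", [([20.0, 20.0], 20.0), ([18.0, 22.0], 20.0),
                                                ([19.3], 19.3)])
    def test_arithmetic_mean_of_reference_cts(self, refs, expected):
        assert composite_reference(refs) == pytest.approx(expected)


class TestDdctFold:
    @pytest.mark.parametrize(
        "args, expected",
        [((24, 20, 24, 20), 1.0), ((23, 20, 24, 20), 2.0), ((26, 20, 24, 20), 0.25)],
    )
    def test_closed_form(self, args, expected):
        assert ddct_fold(*args) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(
        cts=st.tuples(*[st.floats(5, 35) for _ in range(4)]),
        shift=st.floats(-10, 10),
    )
    def test_invariant_under_common_ct_shift(self, cts, shift):
        shifted = tuple(c + shift for c in cts)
        assert ddct_fold(*shifted) == pytest.approx(ddct_fold(*cts), rel=1e-9)


class TestAnalyzePlate:
    def test_no_effect_no_noise_gives_unit_fold(self):
        cfg = SimConfig(ct_noise_sd=0.0, seed=1)
        plate = simulate_ct_plate(cfg, true_fold=1.0)
        res = analyze_plate(plate)
        assert res.loc[0, "fold"] == pytest.approx(1.0)
        assert res.loc[0, "significant_code"] == "ns"

    def test_exact_twofold_without_noise(self):
        cfg = SimConfig(ct_noise_sd=0.0, seed=1)
        plate = simulate_ct_plate(cfg, true_fold=2.0)
        assert analyze_plate(plate).loc[0, "fold"] == pytest.approx(2.0)

    @pytest.mark.parametrize("true_fold", [2.0, 11.0])
    def test_parameter_recovery_under_noise(self, true_fold):
        """Fold recovered within +/-15% at Ct noise sd 0.1 and 3 replicates,
        averaged over independent plates."""
        folds = []
        for seed in range(10):
            cfg = SimConfig(ct_noise_sd=0.1, n_replicates=3, seed=100 + seed)
            plate = simulate_ct_plate(cfg, true_fold=true_fold)
            folds.append(analyze_plate(plate).loc[0, "fold"])
        est = math.exp(np.mean(np.log(folds)))
        assert abs(est / true_fold - 1.0) <= 0.15

    def test_strong_effect_flagged_significant(self):
        cfg = SimConfig(ct_noise_sd=0.05, seed=3)
        plate = simulate_ct_plate(cfg, true_fold=11.0)
        assert analyze_plate(plate).loc[0, "significant_code"] in ("*", "**")


class TestEnzymeActivities:
    def test_zero_slope_zero_activity(self):
        assert gst_activity(0.0, 0.5) == 0.0

    def test_slope_normalised_per_mg(self):
        assert gst_activity(0.5, 0.25) == pytest.approx(2.0)

    def test_kinetic_slope_recovered_from_noisy_trace(self):
        trace = simulate_kinetic_trace(slope_od_per_min=1.12, noise_sd=0.002, seed=8)
        slope = fit_kinetic_slope(trace["time_min"], trace["od"])
        assert slope == pytest.approx(1.12, rel=0.02)

    def test_standard_curve_inversion_exact_on_line(self):
        curve = [(0.0, 0.0), (1.0, 2.0), (2.0, 4.0)]
        assert pnod_activity(1.0, curve) == pytest.approx(0.5)

    def test_standard_point_maps_to_its_concentration(self):
        curve = [(0.0, 0.02), (0.5, 1.02), (1.0, 2.02)]
        assert pnod_activity(1.02, curve) == pytest.approx(0.5, abs=1e-9)

    def test_noisy_curve_matches_normal_equations(self):
        curve = simulate_standard_curve(slope_od_per_unit=2.0, noise_sd=0.002, seed=4)
        pts = np.array(curve)
        X = np.column_stack([np.ones(len(pts)), pts[:, 0]])
        a, b = np.linalg.solve(X.T @ X, X.T @ pts[:, 1])
        assert pnod_activity(1.0, curve) == pytest.approx((1.0 - a) / b, rel=1e-9)

    def test_flat_curve_rejected(self):
        with pytest.raises(ValueError):
            pnod_activity(1.0, [(0.0, 1.0), (1.0, 1.0)])


class TestStrainRatios:
    def test_published_pnod_means_reproduce_ratio(self):
        assay = pd.DataFrame(
            {"strain": ["TH-S"] * 3 + ["TH-2000"] * 3, "replicate": [1, 2, 3] * 2,
             "value": [5.86] * 3 + [16.50] * 3}
        )
        assert strain_ratios(assay)["TH-2000"] == pytest.approx(2.816)

    def test_identical_means_unit_ratio(self):
        assay = pd.DataFrame(
            {"strain": ["TH-S", "TH-S", "TH-R", "TH-R"], "replicate": [1, 2, 1, 2],
             "value": [4.0, 6.0, 5.0, 5.0]}
        )
        assert strain_ratios(assay)["TH-R"] == pytest.approx(1.0)

    def test_simple_ratio_rounding(self):
        assay = pd.DataFrame(
            {"strain": ["TH-S", "TH-S", "TH-2000", "TH-2000"], "replicate": [1, 2, 1, 2],
             "value": [4.0, 4.0, 10.0, 10.0]}
        )
        assert strain_ratios(assay)["TH-2000"] == pytest.approx(2.5)


class TestAnovaLsd:
    def test_identical_groups_share_one_letter(self):
        assay = pd.DataFrame(
            {"strain": ["TH-S"] * 3 + ["TH-R"] * 3 + ["TH-2000"] * 3,
             "replicate": [1, 2, 3] * 3, "value": [2.0] * 9}
        )
        summary, _, p = anova_lsd(assay)
        assert set(summary["letter"]) == {"A"}
        assert p == pytest.approx(1.0)

    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(6)
        rows = []
        for strain, mean in [("TH-S", 1.0), ("TH-R", 10.0), ("TH-2000", 100.0)]:
            for rep in range(1, 6):
                rows.append((strain, rep, mean + rng.normal(0, 0.1)))
        summary, f, p = anova_lsd(pd.DataFrame(rows, columns=["strain", "replicate", "value"]))
        assert list(summary["letter"]) == ["A", "B", "C"]
        assert list(summary["strain"]) == ["TH-2000", "TH-R", "TH-S"]  # descending means
        assert p < 1e-6

    def test_scale_equivariance_of_letters(self):
        cfg = SimConfig(seed=15)
        assay = simulate_enzyme_assays(
            cfg, {"TH-S": 1.12, "TH-R": 1.35, "TH-2000": 2.02},
            {"TH-S": 0.0769, "TH-R": 0.0799, "TH-2000": 0.1118},
        )
        doubled = assay.assign(value=assay["value"] * 2)
        s1, f1, p1 = anova_lsd(assay)
        s2, f2, p2 = anova_lsd(doubled)
        assert list(s1["letter"]) == list(s2["letter"])
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_anova_p_consistent_with_permutation_null(self):
        """Parametric ANOVA p agrees with a label-permutation approximation."""
        rng = np.random.default_rng(3)
        rows = []
        for strain, mean in [("TH-S", 1.0), ("TH-R", 1.3), ("TH-2000", 1.5)]:
            for rep in range(1, 6):
                rows.append((strain, rep, mean + rng.normal(0, 0.4)))
        assay = pd.DataFrame(rows, columns=["strain", "replicate", "value"])
        _, f_obs, p_obs = anova_lsd(assay)

        from scipy.stats import f_oneway

        values = assay["value"].to_numpy()
        n_perm, hits = 4000, 0
        for _ in range(n_perm):
            perm = rng.permutation(values)
            f_perm = f_oneway(perm[:5], perm[5:10], perm[10:]).statistic
            hits += f_perm >= f_obs
        p_perm = (hits + 1) / (n_perm + 1)
        assert abs(p_perm - p_obs) < 3 * math.sqrt(p_obs * (1 - p_obs) / n_perm) + 0.01

    def test_too_few_replicates_rejected(self):
        assay = pd.DataFrame(
            {"strain": ["TH-S", "TH-R"], "replicate": [1, 1], "value": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            anova_lsd(assay)
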