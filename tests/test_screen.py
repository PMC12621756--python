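import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunotwin import (
    PlateLayout,
    classify_synergy,
    compute_drug_effects,
    correct_dmso_drift,
    cross_cohort_correlation,
    cumulative_effect,
    categorize_effect,
    specificity_index,
)
from immunotwin import test_effects as effect_significance
from immunotwin.screen import compare_cohorts, roughness, vehicle_sd


class TestDriftCorrection:
    def test_constant_row(self):
        fitted = correct_dmso_drift(np.full(12, 2.5))
        np.testing.assert_allclose(fitted, 2.5, atol=1e-10)

    def test_linear_drift_reproduced(self):
        x = np.arange(12.0)
        y = 1.0 + 0.05 * x
        fitted = correct_dmso_drift(y)
        # order-2 smoothing spline reproduces an exact line; least-squares
        # line oracle
        coef = np.polyfit(x, y, 1)
        np.testing.assert_allclose(fitted, np.polyval(coef, x), atol=1e-8)

    def test_roughness_monotone_in_smoothing(self, rng):
        y = rng.normal(0, 0.3, size=12) + np.linspace(0, 1, 12)
        rough = [roughness(correct_dmso_drift(y, smoothing=s)) for s in (0.1, 1.5, 10.0)]
        assert rough[0] >= rough[1] >= rough[2] - 1e-12

    def test_nonfinite_rejected(self):
        y = np.full(12, 1.0)
        y[3] = np.nan
        with pytest.raises(ValueError):
            correct_dmso_drift(y)


class TestDrugEffects:
    def test_treated_equals_control_gives_zero(self):
        layout = PlateLayout.default(["SA"])
        plate = pd.DataFrame(np.full((3, 12), 1.3), index=["f1", "f2", "f3"])
        eff = compute_drug_effects(plate, layout)
        np.testing.assert_allclose(eff.to_numpy(), 0.0, atol=1e-10)

    def test_full_screen_effect_count(self):
        # 9 drugs x 4,480 features per cohort analysis
        layout = PlateLayout.default([f"drug{i}" for i in range(9)])
        rng = np.random.default_rng(1)
        plate = pd.DataFrame(
            rng.normal(1.0, 0.05, size=(4480, 12)),
            index=[f"f{i}" for i in range(4480)],
        )
        eff = compute_drug_effects(plate, layout)
        assert eff.size == 40_320

    def test_planted_shift_recovered(self, rng):
        # with a generous smoothing budget the spline reduces to the weighted
        # least-squares parabola, which absorbs a known fraction (the hat
        # value) of the drug's own shift; the oracle is that hat matrix
        layout = PlateLayout.default(["SA"])
        col = layout.drug_columns["SA"]
        x = np.arange(12.0)
        X = np.column_stack([np.ones(12), x, x**2])
        w = np.ones(12)
        w[list(layout.vehicle_columns)] = 2.0
        # the fitting library's weights multiply residuals inside the square,
        # so the equivalent weighted-least-squares weight is w**2
        W = np.diag(w**2)
        H = X @ np.linalg.solve(X.T @ W @ X, X.T @ W)
        delta = 0.25
        expected = delta * (1 - H[col, col])
        n = 200
        effects = []
        for _ in range(n):
            row = np.full(12, 1.0) + rng.normal(0, 0.02, 12)
            row[col] += delta
            eff = compute_drug_effects(
                pd.DataFrame([row], index=["f"]), layout
            ).iloc[0, 0]
            effects.append(eff)
        mean = np.mean(effects)
        ci = 1.96 * np.std(effects) / np.sqrt(n)
        assert abs(mean - expected) < ci + 0.005

    def test_layout_validation(self):
        with pytest.raises(ValueError):
            PlateLayout(drug_columns={"SA": 0})  # collides with vehicle column
        with pytest.raises(ValueError):
            PlateLayout(drug_columns={"SA": 12})


class TestSignificance:
    def test_zero_effects_not_significant(self):
        eff = pd.DataFrame({"SA": [0.0, 0.0]}, index=["f1", "f2"])
        out = effect_significance({"D1": eff, "D2": eff, "D3": eff})
        assert not out["significant"].any()
        assert out["p"].isna().all()  # zero variance reported as undefined

    def test_bh_matches_hand_oracle(self):
        # p = (0.01, 0.02, 0.03, 0.04) at FDR 0.05: step-up compares p(i) to
        # 0.05*i/4 = (0.0125, 0.025, 0.0375, 0.05) -> all rejected
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.04])
        rej, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert rej.all()
        # brute-force step-up oracle
        def bh_oracle(pvals, alpha):
            m = len(pvals)
            order = np.argsort(pvals)
            thresh = alpha * (np.arange(1, m + 1)) / m
            passed = np.where(np.sort(pvals) <= thresh)[0]
            k = passed.max() + 1 if len(passed) else 0
            rejected = np.zeros(m, bool)
            rejected[order[:k]] = True
            return rejected

        rng = np.random.default_rng(3)
        for _ in range(20):
            pv = rng.uniform(size=rng.integers(2, 20))
            np.testing.assert_array_equal(
                multipletests(pv, alpha=0.05, method="fdr_bh")[0],
                bh_oracle(pv, 0.05),
            )

    def test_planted_effect_detected_null_controlled(self, rng):
        n_feat, n_donors = 300, 8
        frames = {}
        for d in range(n_donors):
            vals = rng.normal(0, 0.05, size=n_feat)
            vals[:5] += 0.5  # five real effects
            frames[f"D{d}"] = pd.DataFrame({"SA": vals}, index=[f"f{i}" for i in range(n_feat)])
        out = effect_significance(frames)
        sig = out["significant"].to_numpy()
        assert sig[:5].all()
        # realized false positives consistent with FDR 0.05 control
        assert sig[5:].mean() < 0.05


class TestCategorization:
    @pytest.mark.parametrize(
        "effect, response, stim, unstim, expected",
        [
            (0.2, 0.0, "LPS", True, "stimulatory/amplifying|baseline"),
            (-0.1, 0.3, "LPS", False, "inhibitory/neutralizing|strong"),
            (0.1, 0.05, "LPS", False, "stimulatory/amplifying|weak"),
            (-0.1, -0.3, "LPS", False, "stimulatory/amplifying|weak"),
        ],
    )
    def test_examples(self, effect, response, stim, unstim, expected):
        assert categorize_effect(effect, response, stim, unstim) == expected

    def test_categories_partition_significant_set(self, rng):
        effects = rng.normal(0, 0.2, size=50)
        responses = rng.normal(0, 0.2, size=50)
        cats = [
            categorize_effect(e, r, "LPS", is_unstimulated=(i % 5 == 0))
            for i, (e, r) in enumerate(zip(effects, responses))
        ]
        from immunotwin.screen import CATEGORIES

        assert all(c in CATEGORIES for c in cats)
        assert len(cats) == 50  # every effect falls in exactly one category


class TestSpecificity:
    @pytest.mark.parametrize(
        "p, np_, expected",
        [(0.2, 0.2, 0.0), (0.2, 0.0, 1.0), (0.3, 0.1, 0.5), (-0.2, 0.2, 1.0)],
    )
    def test_examples(self, p, np_, expected):
        assert specificity_index(p, np_) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        assert np.isnan(specificity_index(0.0, 0.0))

    @given(
        st.floats(-5, 5).filter(lambda x: abs(x) > 1e-6),
        st.floats(-5, 5).filter(lambda x: abs(x) > 1e-6),
        st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_scale_invariance(self, a, b, c):
        assert specificity_index(a, b) == pytest.approx(specificity_index(b, a))
        assert specificity_index(c * a, c * b) == pytest.approx(
            specificity_index(a, b), rel=1e-9
        )


class TestSynergy:
    @pytest.mark.parametrize(
        "combo, a, b, tol, expected",
        [
            (0.3, 0.1, 0.2, 0.05, "additive"),
            (-0.4, -0.1, -0.1, 0.05, "synergistic"),
            (0.1, 0.2, 0.2, 0.05, "antagonistic"),
            (0.5, 0.2, 0.2, 0.05, "synergistic"),
        ],
    )
    def test_examples(self, combo, a, b, tol, expected):
        assert classify_synergy(combo, a, b, tol) == expected

    def test_vehicle_sd_tolerance(self):
        layout = PlateLayout.default(["SA"])
        plate = pd.DataFrame(
            [[1.0, 0, 0, 0, 0, 1.2, 0, 0, 0, 0, 0, 1.1]], index=["f"]
        )
        sd = vehicle_sd(plate, layout)
        assert sd["f"] == pytest.approx(np.std([1.0, 1.2, 1.1], ddof=1))


class TestCrossCohort:
    def test_identical_and_anticorrelated(self, rng):
        base = rng.normal(size=20)
        df = pd.DataFrame(
            {
                "effect_pregnant": np.concatenate([base, base]),
                "effect_nonpregnant": np.concatenate([base, -base]),
                "marker": ["same"] * 20 + ["anti"] * 20,
            }
        )
        out = cross_cohort_correlation(df, "marker")
        assert out.loc["same", "pearson_r"] == pytest.approx(1.0)
        assert out.loc["anti", "pearson_r"] == pytest.approx(-1.0)

    def test_known_correlation_recovered(self, rng):
        n = 200
        shared = rng.normal(size=n)
        a = shared + rng.normal(size=n)
        b = shared + rng.normal(size=n)  # corr(a, b) = 0.5
        df = pd.DataFrame({"effect_pregnant": a, "effect_nonpregnant": b,
                           "marker": ["m"] * n})
        r = cross_cohort_correlation(df, "marker").loc["m", "pearson_r"]
        assert r == pytest.approx(0.5, abs=3 / np.sqrt(n))

    def test_degenerate_variance_nan(self):
        df = pd.DataFrame({"effect_pregnant": [1.0, 1.0, 1.0],
                           "effect_nonpregnant": [0.1, 0.2, 0.3],
                           "marker": ["m"] * 3})
        assert np.isnan(cross_cohort_correlation(df, "marker").loc["m", "pearson_r"])


class TestCumulativeEffect:
    def test_examples(self):
        assert cumulative_effect([], []) == 0.0
        assert cumulative_effect([0.1, -0.2], [True, True]) == pytest.approx(0.3)
        assert cumulative_effect([0.1, -0.2, 5.0], [True, True, False]) == pytest.approx(0.3)


class TestCohortComparison:
    def test_prefilter_and_detection(self, rng):
        a = pd.DataFrame({"f_big": rng.normal(0.5, 0.1, 20),
                          "f_small": rng.normal(0.02, 0.01, 20)})
        b = pd.DataFrame({"f_big": rng.normal(0.0, 0.1, 20),
                          "f_small": rng.normal(0.0, 0.01, 20)})
        out = compare_cohorts(a, b)
        assert out.loc["f_big", "significant"]
        assert not out.loc["f_small", "tested"]  # group difference below 0.05
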