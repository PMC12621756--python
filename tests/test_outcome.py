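import numpy as np
import pandas as pd
import pytest

from immunotwin import (
    StabilitySelector,
    TimeToLaborModel,
    expected_pregnancy_length,
    feature_importance,
    preterm_auroc,
    treatment_effect,
)
from immunotwin.outcome import attribution_matrix


def _signal_data(seed, n=100, p=200, support=(3, 50, 120), betas=(2.0, -2.0, 1.5),
                 noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[list(support)] = betas
    y = X @ beta + rng.normal(0, noise, size=n)
    return X, y


class TestStabilitySelection:
    def test_planted_support_recovered(self):
        for seed in range(3):
            X, y = _signal_data(100 + seed)
            sel = StabilitySelector(random_state=seed).fit(X, y)
            sup = set(np.where(sel.support_mask_)[0])
            assert {3, 50, 120} <= sup
            assert len(sup - {3, 50, 120}) <= 1

    def test_null_selects_almost_nothing(self):
        # the false-discovery surrogate keeps null selections at the noise
        # level: a couple of features out of 200 at most
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 200))
        y = rng.normal(size=100)
        counts = [
            StabilitySelector(random_state=s).fit(X, y).support_mask_.sum()
            for s in range(3)
        ]
        assert max(counts) <= 3

    def test_duplicated_informative_feature(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 50))
        X[:, 40] = X[:, 10]
        y = 2 * X[:, 10] + rng.normal(0, 0.5, 100)
        sel = StabilitySelector(random_state=0).fit(X, y)
        sup = set(np.where(sel.support_mask_)[0])
        assert sup & {10, 40}  # at least one of the pair

    def test_noise_false_selection_controlled(self):
        # across replicates, selected noise-feature frequency stays low
        spurious = []
        for seed in range(10):
            X, y = _signal_data(200 + seed, p=100, support=(1, 2), betas=(2, 2))
            sel = StabilitySelector(random_state=seed).fit(X, y)
            spurious.append(int(np.sum(sel.noise_frequencies_ >= sel.threshold_)))
        assert np.mean(spurious) <= 1.0

    def test_transform_api(self):
        X, y = _signal_data(7, p=50, support=(1,), betas=(3.0,))
        sel = StabilitySelector(random_state=0).fit(X, y)
        assert sel.transform(X).shape[1] == sel.support_mask_.sum()


def _cohort(seed=0, n_patients=20, spp=2):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        u = rng.normal()
        for s in range(spp):
            day = rng.uniform(160, 270)
            rows.append({"patient": f"P{p}", "signal": u + rng.normal(0, 0.1),
                         "day": day})
    df = pd.DataFrame(rows)
    X = pd.DataFrame({
        "signal": df["signal"],
        "junk1": rng.normal(size=len(df)),
        "junk2": rng.normal(size=len(df)),
    })
    y = 40.0 * df["signal"].to_numpy() + 100.0
    return X, y, df


class TestTimeToLaborModel:
    def test_recovers_deterministic_signal(self):
        X, y, df = _cohort(seed=1, n_patients=30)
        m = TimeToLaborModel(selector=StabilitySelector(random_state=0),
                             random_state=0)
        m.fit(X, y, groups=df["patient"])
        oof = m.oof_report()
        assert oof["pearson_r"].iloc[0] > 0.9

    def test_folds_are_patient_disjoint(self):
        X, y, df = _cohort(seed=2)
        m = TimeToLaborModel(random_state=0).fit(X, y, groups=df["patient"])
        fold = pd.Series(m.fold_of_sample_, index=df.index)
        per_patient_folds = df.groupby("patient").apply(
            lambda g: fold[g.index].nunique(), include_groups=False
        )
        assert (per_patient_folds == 1).all()

    def test_fold_membership_independent_of_sample_order(self):
        X, y, df = _cohort(seed=3)
        m1 = TimeToLaborModel(random_state=0).fit(X, y, groups=df["patient"])
        perm = np.random.default_rng(0).permutation(len(y))
        m2 = TimeToLaborModel(random_state=0).fit(
            X.iloc[perm].reset_index(drop=True), y[perm],
            groups=df["patient"].iloc[perm].reset_index(drop=True),
        )
        f1 = {p: m1.fold_of_sample_[df["patient"] == p][0] for p in df["patient"].unique()}
        f2 = {}
        dfp = df["patient"].iloc[perm].reset_index(drop=True)
        for p in dfp.unique():
            f2[p] = m2.fold_of_sample_[dfp == p][0]
        # same patients grouped together regardless of row order
        assert all(
            len({f1[p] for p in grp}) == 1
            for grp in [[p for p in f1 if f2[p] == k] for k in set(f2.values())]
        )

    def test_constant_target_reported(self):
        X, y, df = _cohort(seed=4)
        y[:] = 42.0
        m = TimeToLaborModel(random_state=0).fit(X, y, groups=df["patient"])
        oof = m.oof_report()
        assert np.isnan(oof["pearson_r"].iloc[0])
        assert np.allclose(m.oof_predictions_, 42.0, atol=1.0)

    def test_single_patient_rejected(self):
        X, y, df = _cohort(seed=5, n_patients=1)
        with pytest.raises(ValueError):
            TimeToLaborModel().fit(X, y, groups=df["patient"])

    def test_auroc_criterion_requires_labels(self):
        X, y, df = _cohort(seed=6)
        with pytest.raises(ValueError):
            TimeToLaborModel(criterion="auroc").fit(X, y, groups=df["patient"])


class TestExpectedPregnancyLength:
    def test_sum(self):
        assert expected_pregnancy_length(210.0, 70.0) == pytest.approx(280.0)

    def test_perfect_predictions_auroc_one(self):
        lengths = np.array([280, 281, 240, 282, 238, 283.0])
        preterm = lengths < 259
        assert preterm_auroc(lengths, preterm) == 1.0

    def test_shuffled_labels_auroc_near_half(self):
        rng = np.random.default_rng(0)
        n = 400
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.3
        aucs = [
            preterm_auroc(scores, np.random.default_rng(s).permutation(labels))
            for s in range(50)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_degenerate_labels_nan(self):
        assert np.isnan(preterm_auroc([1.0, 2.0], [False, False]))


class TestTreatmentEffect:
    def _fitted(self):
        X, y, df = _cohort(seed=7, n_patients=24)
        m = TimeToLaborModel(random_state=0).fit(X, y, groups=df["patient"])
        return m, X, y, df

    def test_identical_rows_give_exact_zero(self):
        m, X, y, df = self._fitted()
        rep = treatment_effect(m, X, {"drug": X.copy()}, df["patient"],
                               gestational_day=df["day"])
        assert (rep.samples["delta_drug"] == 0).all()
        assert (rep.per_patient["delta_drug"] == 0).all()

    def test_shifted_signal_changes_prediction_sign(self):
        m, X, y, df = self._fitted()
        treated = X.copy()
        treated["signal"] = treated["signal"] + 1.0  # model depends positively
        rep = treatment_effect(m, X, {"drug": treated}, df["patient"])
        assert (rep.per_patient["delta_drug"] > 0).mean() >= 0.9
        assert rep.fraction_positive["drug"] >= 0.9

    def test_rolling_average_of_constant_is_constant(self):
        m, X, y, df = self._fitted()
        rep = treatment_effect(m, X, {"drug": X.copy()}, df["patient"],
                               gestational_day=df["day"])
        assert np.allclose(rep.rolling["drug"], 0.0)

    def test_feature_index_mismatch_rejected(self):
        m, X, y, df = self._fitted()
        bad = X.rename(columns={"junk1": "other"})
        with pytest.raises(ValueError):
            treatment_effect(m, X, {"drug": bad}, df["patient"])


class TestFeatureImportance:
    def test_single_feature_holds_all_mass(self):
        X, y, df = _cohort(seed=8, n_patients=30)
        m = TimeToLaborModel(selector=StabilitySelector(random_state=0),
                             random_state=0)
        m.fit(X, y, groups=df["patient"])
        imp = feature_importance(m, X)
        if list(m.selected_features_) == ["signal"]:
            assert imp.loc["signal", "mean_abs_attribution"] == imp[
                "mean_abs_attribution"
            ].sum()

    def test_additivity_contract(self):
        X, y, df = _cohort(seed=9)
        m = TimeToLaborModel(random_state=0).fit(X, y, groups=df["patient"])
        contribs = attribution_matrix(m, X)
        preds = m.predict(X)
        np.testing.assert_allclose(contribs.sum(axis=1), preds, rtol=1e-4, atol=1e-3)

    def test_symmetric_features_share_attribution(self):
        rng = np.random.default_rng(10)
        n = 400
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = X["a"].to_numpy() + X["b"].to_numpy()
        groups = np.repeat(np.arange(n // 2), 2)
        m = TimeToLaborModel(
            selector=StabilitySelector(threshold=0.5, random_state=0),
            random_state=0,
        ).fit(X, y, groups=groups)
        imp = feature_importance(m, X)
        a, b = imp["mean_abs_attribution"].loc[["a", "b"]]
        assert abs(a - b) / max(a, b) < 0.1
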