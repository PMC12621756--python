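"""Sparse outcome modeling and simulated treatment-effect readout.

Time to labor is predicted from untreated twin feature matrices in two
stages. Noise-augmented stability selection first screens features: the
matrix is augmented with artificial noise features (permuted copies of real
columns by default), sparse linear models are fitted on repeated subsamples
across a penalty grid, and per-feature selection frequencies are thresholded
where an estimated false-discovery surrogate over the noise features is
minimized. A gradient-boosted tree ensemble is then fitted on the selected
features under patient-grouped cross-validation (no patient ever appears in
both train and test of a fold), with its hyperparameters chosen by grid
search. Treatment effects are read out per sample as the difference between
the held-out fold model's predictions on the treated and untreated twin
rows, summarized as a 30-day rolling average over gestational age and as a
per-patient aggregate (sum across that patient's samples, a proxy for
repeated dosing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import lasso_path
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold
from xgboost import XGBRegressor

PRETERM_CUTOFF_DAYS = 259.0  # 37 completed weeks


class StabilitySelector(SelectorMixin, BaseEstimator):
    """Noise-augmented stability selection for sparse linear signal.

    Parameters
    ----------
    n_noise : int, "match", or "2x"
        Number of artificial noise features; "match" uses one per real
        feature, "2x" (default) two per real feature — the larger pool
        stabilizes the false-discovery surrogate.
    noise_mode : {"permute", "gaussian"}
        Build noise features by permuting real columns (preserves marginals)
        or by standard-normal draws.
    n_subsamples : int
        Subsample replicates (>= 10 recommended for real runs).
    alphas : sequence of float
        Lasso penalty grid as fractions of the data-derived maximal penalty
        (the smallest penalty with an empty model); per feature the selection
        frequency is the max over the grid.
    sample_fraction : float
        Fraction of samples per subsample (drawn without replacement).
    threshold : float or None
        Fixed selection-frequency cutoff; None uses the data-driven rule
        minimizing the false-discovery surrogate
        (1 + #noise >= t) / max(1, #real >= t) over t.
    """

    def __init__(self, n_noise="2x", noise_mode="permute", n_subsamples=50,
                 alphas=(0.05, 0.1, 0.2, 0.3, 0.5), sample_fraction=0.5,
                 threshold=None, min_threshold=0.5, random_state=0):
        self.n_noise = n_noise
        self.noise_mode = noise_mode
        self.n_subsamples = n_subsamples
        self.alphas = alphas
        self.sample_fraction = sample_fraction
        self.threshold = threshold
        self.min_threshold = min_threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        if self.n_noise == "match":
            k = p
        elif self.n_noise == "2x":
            k = 2 * p
        else:
            k = int(self.n_noise)
        if self.noise_mode == "permute":
            src = rng.integers(0, p, size=k)
            noise = np.stack([rng.permutation(X[:, j]) for j in src], axis=1)
        elif self.noise_mode == "gaussian":
            noise = rng.normal(size=(n, k))
        else:
            raise ValueError("noise_mode must be 'permute' or 'gaussian'")
        Z = np.hstack([X, noise])
        mu, sd = Z.mean(0), Z.std(0)
        sd[sd == 0] = 1.0
        Zs = (Z - mu) / sd
        yc = y - y.mean()

        alpha_max = np.max(np.abs(Zs.T @ yc)) / n
        alphas = alpha_max * np.asarray(self.alphas, dtype=float)

        m = max(2, int(round(self.sample_fraction * n)))
        counts = np.zeros((len(alphas), p + k))
        for b in range(self.n_subsamples):
            idx = rng.choice(n, size=m, replace=False)
            _, coefs, _ = lasso_path(Zs[idx], yc[idx], alphas=alphas, max_iter=2000)
            counts += (coefs != 0).T
        freq = counts / self.n_subsamples
        freq_max = freq.max(axis=0)  # per-feature max over the penalty path
        self.frequencies_ = freq_max[:p]
        self.noise_frequencies_ = freq_max[p:]

        if self.threshold is not None:
            thr = float(self.threshold)
        else:
            grid = np.arange(self.min_threshold, 1.0 + 1e-9, 0.01)
            best, thr = np.inf, 1.0
            for t in grid:
                n_noise_sel = int(np.sum(self.noise_frequencies_ >= t))
                n_real_sel = int(np.sum(self.frequencies_ >= t))
                fdp = (1 + n_noise_sel) / max(1, n_real_sel)
                if fdp <= best:
                    best, thr = fdp, t
        self.threshold_ = thr
        self.support_mask_ = self.frequencies_ >= thr
        if not self.support_mask_.any():
            import warnings

            warnings.warn("stability selection returned an empty feature set")
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        return self.support_mask_


def _xgb(params: Mapping, seed: int) -> XGBRegressor:
    defaults = dict(n_estimators=100, max_depth=3, learning_rate=0.1,
                    subsample=0.9, reg_lambda=1.0, n_jobs=1,
                    random_state=seed, verbosity=0)
    defaults.update(params)
    return XGBRegressor(**defaults)


def expected_pregnancy_length(predicted_time_to_labor, gestational_day):
    """Expected gestational length: day at sampling + predicted time to labor."""
    return np.asarray(gestational_day, dtype=float) + np.asarray(
        predicted_time_to_labor, dtype=float
    )


def preterm_auroc(ega_scores, preterm_labels) -> float:
    """AUROC for identifying preterm samples from the expected length.

    Shorter expected length indicates preterm, so the score enters negated.
    """
    labels = np.asarray(preterm_labels, dtype=bool)
    if labels.all() or not labels.any():
        return float("nan")
    return float(roc_auc_score(labels, -np.asarray(ega_scores, dtype=float)))


class TimeToLaborModel(BaseEstimator, RegressorMixin):
    """Stability-selected gradient-boosted regression with grouped CV.

    fit(X, y, groups=patient_ids) runs stability selection, grid-searches
    the boosting hyperparameters under patient-grouped K-fold CV (criterion
    "rmse" on the regression, or "auroc" of the derived preterm
    classification when gestational days and labels are supplied), stores
    per-fold models and out-of-fold predictions, and refits a final model on
    all samples. If selection returns no features, all are used (logged via
    warning from the selector).
    """

    def __init__(self, selector=None, xgb_grid=None, n_splits=4, criterion="rmse",
                 preterm_cutoff=PRETERM_CUTOFF_DAYS, random_state=0):
        self.selector = selector
        self.xgb_grid = xgb_grid
        self.n_splits = n_splits
        self.criterion = criterion
        self.preterm_cutoff = preterm_cutoff
        self.random_state = random_state

    def _grid(self) -> list[dict]:
        grid = self.xgb_grid or {"max_depth": [2, 3], "n_estimators": [100], "learning_rate": [0.1]}
        keys = list(grid)
        return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]

    def fit(self, X, y, groups=None, gestational_day=None, preterm=None):
        if groups is None:
            raise ValueError("patient groups are required for grouped CV")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        if len(uniq) < 2:
            raise ValueError("need >= 2 patients to form grouped folds")
        n_splits = min(self.n_splits, len(uniq))
        if self.criterion == "auroc" and (gestational_day is None or preterm is None):
            raise ValueError("criterion='auroc' needs gestational_day and preterm labels")
        if self.criterion not in ("rmse", "auroc"):
            raise ValueError("criterion must be 'rmse' or 'auroc'")

        sel = self.selector if self.selector is not None else StabilitySelector(
            random_state=self.random_state)
        sel.fit(X.to_numpy(), y)
        mask = sel._get_support_mask()
        if not mask.any():
            mask = np.ones(X.shape[1], dtype=bool)
        self.selector_ = sel
        self.selected_features_ = list(X.columns[mask])
        Xs = X.loc[:, self.selected_features_]

        gkf = GroupKFold(n_splits=n_splits)
        splits = list(gkf.split(Xs, y, groups))
        best_score, best_params = np.inf, self._grid()[0]
        for params in self._grid():
            oof = np.full(len(y), np.nan)
            for tr, te in splits:
                m = _xgb(params, self.random_state)
                m.fit(Xs.iloc[tr], y[tr])
                oof[te] = m.predict(Xs.iloc[te])
            if self.criterion == "rmse":
                score = float(np.sqrt(np.mean((oof - y) ** 2)))
            else:
                ega = expected_pregnancy_length(oof, gestational_day)
                auc = preterm_auroc(ega, preterm)
                score = -auc if np.isfinite(auc) else np.inf
            if score < best_score:
                best_score, best_params = score, params
        self.best_params_ = best_params
        self.best_score_ = best_score

        self.fold_models_ = []
        self.fold_of_sample_ = np.full(len(y), -1)
        oof = np.full(len(y), np.nan)
        for fold_i, (tr, te) in enumerate(splits):
            m = _xgb(best_params, self.random_state)
            m.fit(Xs.iloc[tr], y[tr])
            oof[te] = m.predict(Xs.iloc[te])
            self.fold_models_.append(m)
            self.fold_of_sample_[te] = fold_i
        self.oof_predictions_ = oof
        self.groups_ = groups
        self.y_ = y

        self.model_ = _xgb(best_params, self.random_state)
        self.model_.fit(Xs, y)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.array(X.columns)
        return self

    def predict(self, X):
        X = pd.DataFrame(X)
        return self.model_.predict(X.loc[:, self.selected_features_])

    def oof_report(self) -> pd.DataFrame:
        r = np.corrcoef(self.oof_predictions_, self.y_)[0, 1] if np.std(
            self.oof_predictions_) > 0 else np.nan
        return pd.DataFrame(
            {
                "prediction": self.oof_predictions_,
                "observed": self.y_,
                "fold": self.fold_of_sample_,
                "patient": self.groups_,
            }
        ).assign(pearson_r=r)


def treatment_effect(
    model: TimeToLaborModel,
    untreated: pd.DataFrame,
    treated: Mapping[str, pd.DataFrame],
    patient_ids: Sequence,
    gestational_day: Sequence[float] | None = None,
    aggregate: str = "sum",
    rolling_window: float = 30.0,
) -> "TwinPredictionReport":
    """Per-sample and per-patient simulated drug effects on time to labor.

    For every sample the prediction comes from the fold model for which that
    sample's patient was held out, applied to the untreated row and to each
    drug's treated row; the delta is treated minus untreated. Per-patient
    aggregates sum (or average) the patient's sample deltas; the rolling
    summary averages deltas over a left-closed ``rolling_window``-day window
    anchored on gestational day.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")
    feats = model.selected_features_
    for d, m in treated.items():
        if list(m.columns) != list(untreated.columns):
            raise ValueError(f"treated matrix for {d!r} has a different feature index")
    patient_ids = np.asarray(patient_ids)
    fold_of = model.fold_of_sample_
    preds_unt = np.full(len(untreated), np.nan)
    deltas = {d: np.full(len(untreated), np.nan) for d in treated}
    for fold_i, fm in enumerate(model.fold_models_):
        rows = np.where(fold_of == fold_i)[0]
        if len(rows) == 0:
            continue
        pu = fm.predict(untreated.iloc[rows][feats])
        preds_unt[rows] = pu
        for d, m in treated.items():
            deltas[d][rows] = fm.predict(m.iloc[rows][feats]) - pu

    samples = pd.DataFrame({"patient_id": patient_ids}, index=untreated.index)
    samples["prediction_untreated"] = preds_unt
    if gestational_day is not None:
        samples["gestational_day"] = np.asarray(gestational_day, dtype=float)
    for d in treated:
        samples[f"delta_{d}"] = deltas[d]

    per_patient = samples.groupby("patient_id")[[f"delta_{d}" for d in treated]].agg(aggregate)
    fraction_positive = {d: float(np.mean(per_patient[f"delta_{d}"] > 0)) for d in treated}

    rolling = None
    if gestational_day is not None:
        order = samples.sort_values("gestational_day")
        rolling = {}
        for d in treated:
            vals = []
            for day in order["gestational_day"]:
                win = order[(order["gestational_day"] > day - rolling_window)
                            & (order["gestational_day"] <= day)]
                vals.append(float(win[f"delta_{d}"].mean()))
            rolling[d] = pd.Series(vals, index=order.index)
        rolling = order[["gestational_day"]].join(pd.DataFrame(rolling))

    return TwinPredictionReport(
        samples=samples,
        per_patient=per_patient,
        fraction_positive=fraction_positive,
        rolling=rolling,
    )


@dataclass
class TwinPredictionReport:
    """Treatment-effect readout: per-sample deltas, patient aggregates,
    fraction of patients with a positive aggregate, and the rolling summary."""

    samples: pd.DataFrame
    per_patient: pd.DataFrame
    fraction_positive: dict[str, float]
    rolling: pd.DataFrame | None = None


def feature_importance(model: TimeToLaborModel, X: pd.DataFrame) -> pd.DataFrame:
    """Additive per-feature attributions (exact for tree ensembles).

    Uses tree-path attributions whose per-sample sum plus the expected value
    equals the prediction; the summary is the mean absolute attribution,
    descending.
    """
    Xs = pd.DataFrame(X).loc[:, model.selected_features_]
    booster = model.model_.get_booster()
    import xgboost as xgb

    contribs = booster.predict(xgb.DMatrix(Xs), pred_contribs=True)
    per_feature = contribs[:, :-1]  # last column is the bias term
    summary = pd.DataFrame(
        {
            "feature": model.selected_features_,
            "mean_abs_attribution": np.mean(np.abs(per_feature), axis=0),
        }
    ).sort_values("mean_abs_attribution", ascending=False).set_index("feature")
    summary.attrs["base_value"] = float(contribs[0, -1])
    return summary


def attribution_matrix(model: TimeToLaborModel, X: pd.DataFrame) -> np.ndarray:
    """Raw per-sample attribution matrix including the bias column."""
    import xgboost as xgb

    Xs = pd.DataFrame(X).loc[:, model.selected_features_]
    return model.model_.get_booster().predict(xgb.DMatrix(Xs), pred_contribs=True)
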