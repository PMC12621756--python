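"""Drug-effect statistics for the 96-well perturbation screen.

Each donor's plate carries stimulations as rows and treatments as columns,
with vehicle (DMSO) controls in columns 1, 6 and 12. A weighted smoothing
spline fitted across the 12 columns (per donor, per feature) models slow
acquisition-time drift; drug effects are differences to the spline's
column-specific corrected vehicle value. On top of this sit the screen's
univariate statistics: paired t tests with Benjamini-Hochberg correction,
six-way effect categorization, cross-cohort correlation, a pregnancy
specificity index, synergy classification for a drug combination, and
cumulative effect magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

from .tables import VEHICLE, classify_response_strength

N_COLUMNS = 12
VEHICLE_COLUMNS = (0, 5, 11)  # 0-based plate columns 1, 6, 12

CATEGORIES = tuple(
    f"{direction}|{tier}"
    for direction in ("stimulatory/amplifying", "inhibitory/neutralizing")
    for tier in ("baseline", "strong", "weak")
)


@dataclass(frozen=True)
class PlateLayout:
    """12-column treatment layout with vehicle controls at columns 1, 6, 12."""

    drug_columns: Mapping[str, int] = field(default_factory=dict)  # drug -> 0-based column
    vehicle_columns: tuple[int, ...] = VEHICLE_COLUMNS

    def __post_init__(self):
        if len(self.vehicle_columns) != 3:
            raise ValueError("layout requires exactly 3 vehicle columns")
        used = set(self.vehicle_columns)
        for drug, col in self.drug_columns.items():
            if col in used:
                raise ValueError(f"column {col} assigned twice (drug {drug})")
            if not (0 <= col < N_COLUMNS):
                raise ValueError(f"column {col} outside the 12-column plate")
            used.add(col)

    @classmethod
    def default(cls, drugs: Sequence[str]) -> "PlateLayout":
        free = [c for c in range(N_COLUMNS) if c not in VEHICLE_COLUMNS]
        if len(drugs) > len(free):
            raise ValueError(f"at most {len(free)} drugs fit on the plate")
        return cls(drug_columns={d: free[i] for i, d in enumerate(drugs)})


def correct_dmso_drift(
    values: Sequence[float],
    vehicle_columns: Sequence[int] = VEHICLE_COLUMNS,
    k: int = 2,
    smoothing: float = 1.5,
    drug_weight: float = 1.0,
    vehicle_weight: float = 2.0,
) -> np.ndarray:
    """Column-specific corrected vehicle reference for one feature row.

    Fits a weighted smoothing spline of order ``k`` across all 12 column
    values (vehicle columns at double weight) and returns its fitted value at
    every column position. The smoothing parameter follows the fitting
    library's native convention (an upper bound on the weighted residual sum
    of squares), so a constant row returns the constant and an exactly linear
    drift is reproduced to numerical tolerance.
    """
    y = np.asarray(values, dtype=float)
    if y.shape != (N_COLUMNS,):
        raise ValueError(f"expected {N_COLUMNS} column values, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in feature row")
    x = np.arange(N_COLUMNS, dtype=float)
    w = np.full(N_COLUMNS, drug_weight)
    w[list(vehicle_columns)] = vehicle_weight
    spl = UnivariateSpline(x, y, w=w, k=k, s=smoothing)
    return spl(x)


def roughness(fitted: Sequence[float]) -> float:
    """Sum of squared second differences of a fitted curve."""
    f = np.asarray(fitted, dtype=float)
    return float(np.sum(np.diff(f, n=2) ** 2))


def compute_drug_effects(
    plate_values: pd.DataFrame,
    layout: PlateLayout,
    k: int = 2,
    smoothing: float = 1.5,
) -> pd.DataFrame:
    """Drug effects for one donor: features x drugs, vs drift-corrected control.

    ``plate_values`` is features (rows, one per cell type x marker x
    stimulation) by 12 plate columns of arcsinh medians. The spline is fitted
    per feature row (so per stimulation, as rows of the plate correspond to
    stimulations); the effect is treated value minus the corrected control at
    the treated column.
    """
    if plate_values.shape[1] != N_COLUMNS:
        raise ValueError("plate_values must have 12 columns")
    effects = {}
    for feat, row in plate_values.iterrows():
        corrected = correct_dmso_drift(row.to_numpy(), layout.vehicle_columns, k, smoothing)
        effects[feat] = {
            drug: row.iloc[col] - corrected[col] for drug, col in layout.drug_columns.items()
        }
    out = pd.DataFrame.from_dict(effects, orient="index")
    out.index.name = "feature"
    return out


def vehicle_sd(plate_values: pd.DataFrame, layout: PlateLayout) -> pd.Series:
    """Per-feature intra-assay SD from the vehicle triplicate."""
    v = plate_values.iloc[:, list(layout.vehicle_columns)]
    return v.std(axis=1, ddof=1)


def test_effects(
    effects_by_donor: Mapping[str, pd.DataFrame],
    fdr: float = 0.05,
    family: str = "all",
) -> pd.DataFrame:
    """Paired t test of per-donor drug effects against zero, BH-corrected.

    ``effects_by_donor`` maps donor -> (features x drugs) effect frame with a
    shared index. The paired design (treated vs its corrected control within
    donor) reduces to a one-sample t test on the per-donor differences.
    ``family='all'`` corrects across every (feature, drug) test in the
    analysis; ``family='per_drug'`` corrects within each drug separately.
    Zero-variance effect vectors yield NaN p, reported, never significant.
    """
    if family not in ("all", "per_drug"):
        raise ValueError("family must be 'all' or 'per_drug'")
    donors = list(effects_by_donor)
    if len(donors) < 2:
        raise ValueError("need >= 2 donors for a paired test")
    stacked = np.stack([effects_by_donor[d].to_numpy() for d in donors])  # donors x feat x drug
    first = effects_by_donor[donors[0]]
    n_feat, n_drug = first.shape

    mean = stacked.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_1samp(stacked, 0.0, axis=0)
    rows = []
    for i, feat in enumerate(first.index):
        for j, drug in enumerate(first.columns):
            rows.append({"feature": feat, "drug": drug, "effect": mean[i, j], "p": p[i, j]})
    table = pd.DataFrame(rows)

    table["q"] = np.nan
    table["significant"] = False

    def _adjust(df: pd.DataFrame) -> pd.DataFrame:
        ok = df["p"].notna()
        if ok.any():
            rej, q, _, _ = multipletests(df.loc[ok, "p"], alpha=fdr, method="fdr_bh")
            df.loc[ok, "q"] = q
            df.loc[ok, "significant"] = rej
        return df

    if family == "all":
        table = _adjust(table)
    else:
        table = table.groupby("drug", group_keys=False)[table.columns].apply(_adjust)
    return table.set_index(["feature", "drug"])


def categorize_effect(
    effect: float,
    response: float,
    stimulation: str,
    is_unstimulated: bool,
    absolute_strength: bool = False,
) -> str:
    """Six-way effect category: direction x (baseline / strong / weak).

    For unstimulated features the direction is stimulatory iff the effect
    increases baseline activity. For stimulation-response features the effect
    is amplifying iff it moves the readout further from the unstimulated
    reference in the response's own direction; the tier is the response's
    strong/weak classification.
    """
    if is_unstimulated:
        tier = "baseline"
        amplifying = effect > 0
    else:
        tier = classify_response_strength(response, stimulation, absolute=absolute_strength)
        direction = np.sign(response) if response != 0 else 1.0
        amplifying = effect * direction > 0
    head = "stimulatory/amplifying" if amplifying else "inhibitory/neutralizing"
    return f"{head}|{tier}"


def specificity_index(effect_pregnant: float, effect_nonpregnant: float) -> float:
    """Cohort restriction of a drug effect: |dP - dNP| / (|dP| + |dNP|).

    0 for equal effects, 1 when the effect exists in exactly one cohort;
    undefined (NaN) when both are zero.
    """
    denom = abs(effect_pregnant) + abs(effect_nonpregnant)
    if denom == 0:
        return float("nan")
    return abs(effect_pregnant - effect_nonpregnant) / denom


def classify_synergy(
    effect_combo: float, effect_a: float, effect_b: float, tolerance: float
) -> str:
    """Combination-vs-sum classification: synergistic / additive / antagonistic.

    Additive iff |combo - (A + B)| <= tolerance; synergistic iff the combo
    exceeds the summed effect in the shared effect direction beyond the
    tolerance; antagonistic otherwise. The tolerance should reflect vehicle
    replicate noise (see :func:`vehicle_sd`).
    """
    expected = effect_a + effect_b
    if abs(effect_combo - expected) <= tolerance:
        return "additive"
    direction = np.sign(expected) if expected != 0 else np.sign(effect_combo)
    if (effect_combo - expected) * direction > 0:
        return "synergistic"
    return "antagonistic"


def cross_cohort_correlation(
    effects: pd.DataFrame,
    grouping: str,
) -> pd.DataFrame:
    """Per-group Pearson R between cohort-mean effects, plus mean magnitude.

    ``effects`` needs columns ``effect_pregnant``, ``effect_nonpregnant`` and
    the grouping column (``marker``, ``cell_type`` or ``stimulation``).
    Groups with fewer than 3 pairs or degenerate variance report NaN.
    """
    if grouping not in effects.columns:
        raise ValueError(f"grouping column {grouping!r} not present")
    rows = []
    for g, df in effects.groupby(grouping):
        a = df["effect_pregnant"].to_numpy()
        b = df["effect_nonpregnant"].to_numpy()
        if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(a, b).statistic)
        rows.append({grouping: g, "pearson_r": r,
                     "mean_effect_size": float(np.mean(np.abs(np.concatenate([a, b])))),
                     "n": len(a)})
    return pd.DataFrame(rows).set_index(grouping)


def cumulative_effect(effects: Sequence[float], significant: Sequence[bool]) -> float:
    """Sum of absolute significant effect sizes (magnitude aggregation)."""
    e = np.asarray(effects, dtype=float)
    s = np.asarray(significant, dtype=bool)
    if len(e) != len(s):
        raise ValueError("effects and significance flags differ in length")
    return float(np.sum(np.abs(e[s])))


def compare_cohorts(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    fdr: float = 0.05,
    prefilter: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney U per feature between two cohorts, BH-corrected.

    Only features whose absolute group difference in means exceeds
    ``prefilter`` (arcsinh) enter the corrected family; the others are
    reported untested.
    """
    common = values_a.columns.intersection(values_b.columns)
    rows = []
    for f in common:
        a = values_a[f].dropna().to_numpy()
        b = values_b[f].dropna().to_numpy()
        diff = float(np.mean(a) - np.mean(b)) if len(a) and len(b) else float("nan")
        tested = np.isfinite(diff) and abs(diff) > prefilter and len(a) > 1 and len(b) > 1
        if tested:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            p = float("nan")
        rows.append({"feature": f, "difference": diff, "p": p, "tested": tested})
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = np.nan
    out["significant"] = False
    ok = out["tested"] & out["p"].notna()
    if ok.any():
        rej, q, _, _ = multipletests(out.loc[ok, "p"], alpha=fdr, method="fdr_bh")
        out.loc[ok, "q"] = q
        out.loc[ok, "significant"] = rej
    return out
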