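"""Cross-validated evaluation of transport maps against observed responses.

Maps are scored on held-out donors under 4-fold donor cross-validation with
three metrics — MAE between predicted and observed population medians, MMD
between predicted and observed marker distributions, and the coefficient of
determination across markers — and compared against two controls: the
*identity baseline* (predict the held-out donor's own unperturbed
distribution, i.e. assume no effect) and the *training baseline* (predict
the perturbed distribution observed in the training donors, i.e. reuse
training data and ignore the held-out donor's state).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .tables import OVERLAP_MARKERS, UNSTIMULATED, VEHICLE, SingleCellTable
from .transport import ICNNConfig, ICNNTransport, _map_seed, stim_key


def mmd(
    sample_a,
    sample_b,
    gammas: Sequence[float] | None = None,
    estimator: str = "biased",
    max_cells: int = 2000,
    seed: int = 0,
) -> float:
    """Multi-scale Gaussian-kernel maximum mean discrepancy.

    The kernel is a sum of Gaussians at bandwidths spanning a small grid
    around the median pairwise distance (median heuristic) unless ``gammas``
    is given. ``estimator='biased'`` includes diagonal terms (0 for identical
    samples); ``'unbiased'`` excludes them. Symmetric in its arguments.
    Samples larger than ``max_cells`` are subsampled deterministically.
    """
    A = np.asarray(sample_a, dtype=float)
    B = np.asarray(sample_b, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each sample needs >= 2 cells")
    if A.shape[1] != B.shape[1]:
        raise ValueError("samples must share markers")
    rng = np.random.default_rng(seed)
    if len(A) > max_cells:
        A = A[rng.choice(len(A), max_cells, replace=False)]
    if len(B) > max_cells:
        B = B[rng.choice(len(B), max_cells, replace=False)]

    dAB = cdist(A, B, "sqeuclidean")
    dAA = cdist(A, A, "sqeuclidean")
    dBB = cdist(B, B, "sqeuclidean")
    if gammas is None:
        pooled = np.concatenate([dAB.ravel(), dAA.ravel(), dBB.ravel()])
        med = np.median(pooled[pooled > 0]) if np.any(pooled > 0) else 1.0
        gammas = [1.0 / (med * s) for s in (0.5, 1.0, 2.0)]
    total = 0.0
    nA, nB = len(A), len(B)
    for gm in gammas:
        kAB = np.exp(-gm * dAB).mean()
        if estimator == "biased":
            kAA = np.exp(-gm * dAA).mean()
            kBB = np.exp(-gm * dBB).mean()
        elif estimator == "unbiased":
            eAA = np.exp(-gm * dAA)
            eBB = np.exp(-gm * dBB)
            kAA = (eAA.sum() - np.trace(eAA)) / (nA * (nA - 1))
            kBB = (eBB.sum() - np.trace(eBB)) / (nB * (nB - 1))
        else:
            raise ValueError("estimator must be 'biased' or 'unbiased'")
        total += kAA + kBB - 2 * kAB
    if estimator == "biased":
        total = max(total, 0.0)
    return float(total)


def mae_medians(predicted, observed) -> float:
    """MAE between per-marker medians of two cell matrices."""
    p = np.median(np.asarray(predicted, dtype=float), axis=0)
    o = np.median(np.asarray(observed, dtype=float), axis=0)
    return float(np.mean(np.abs(p - o)))


def r2_medians(predicted, observed, mode: str = "cod") -> float:
    """R^2 of observed vs predicted medians across markers.

    ``mode='cod'`` is the coefficient of determination (1 - SS_res/SS_tot);
    ``mode='pearson2'`` the squared Pearson correlation.
    """
    p = np.median(np.asarray(predicted, dtype=float), axis=0)
    o = np.median(np.asarray(observed, dtype=float), axis=0)
    ss_tot = np.sum((o - o.mean()) ** 2)
    if ss_tot == 0:
        return float("nan")
    if mode == "cod":
        return float(1.0 - np.sum((o - p) ** 2) / ss_tot)
    if mode == "pearson2":
        return float(np.corrcoef(p, o)[0, 1] ** 2)
    raise ValueError("mode must be 'cod' or 'pearson2'")


def donor_folds(donors: Sequence[str], n_folds: int = 4, seed: int = 0) -> list[list[str]]:
    """Reproducible donor partition into n_folds disjoint folds."""
    donors = sorted(set(donors))
    if len(donors) < n_folds:
        raise ValueError(f"need >= {n_folds} donors, got {len(donors)}")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(donors))
    return [perm[i::n_folds] for i in range(n_folds)]


@dataclass
class EvalReport:
    """Per (cell type, perturbation, donor, method) metric table + folds."""

    metrics: pd.DataFrame
    folds: list[list[str]]

    def aggregate(self) -> pd.DataFrame:
        return (
            self.metrics.groupby(["cell_type", "perturbation", "method"])[["mae", "mmd", "r2"]]
            .mean()
            .reset_index()
        )


def evaluate_cv(
    tables: Sequence[SingleCellTable],
    config: ICNNConfig,
    markers: Sequence[str] = OVERLAP_MARKERS,
    stimulations: Sequence[str] | None = None,
    cell_types: Sequence[str] | None = None,
    n_folds: int = 4,
    seed: int = 0,
    mmd_max_cells: int = 1000,
) -> EvalReport:
    """Donor-grouped cross-validated evaluation of stimulation maps.

    Per fold, one map per (cell type, stimulation) is trained on training
    donors' vehicle cells only; predictions for each held-out donor transport
    that donor's own unstimulated cells and are scored against the donor's
    observed stimulated cells, alongside the identity and training baselines.
    """
    tables = [t for t in tables if t.treatment == VEHICLE]
    if cell_types is None:
        cell_types = sorted({t.cell_type for t in tables})
    if stimulations is None:
        stimulations = sorted({t.stimulation for t in tables if t.stimulation != UNSTIMULATED})
    donors = sorted({t.donor for t in tables})
    folds = donor_folds(donors, n_folds, seed)

    def cells(donor_set, ct, stim) -> np.ndarray | None:
        frames = [
            t.data[list(markers)]
            for t in tables
            if t.donor in donor_set and t.cell_type == ct and t.stimulation == stim
        ]
        if not frames:
            return None
        return pd.concat(frames).to_numpy()

    rows = []
    for fold_i, held in enumerate(folds):
        train = [d for d in donors if d not in held]
        for ct in cell_types:
            src_train = cells(train, ct, UNSTIMULATED)
            for s in stimulations:
                tgt_train = cells(train, ct, s)
                if src_train is None or tgt_train is None:
                    raise ValueError(f"fold {fold_i}: missing training data for ({ct}, {s})")
                est = ICNNTransport.from_config(config)
                est.set_params(seed=_map_seed(config.seed + fold_i, stim_key(ct, s)))
                est.fit(src_train, tgt_train)
                for d in held:
                    src_d = cells([d], ct, UNSTIMULATED)
                    obs_d = cells([d], ct, s)
                    if src_d is None or obs_d is None:
                        raise ValueError(f"fold {fold_i}: no held-out data for donor {d}, ({ct}, {s})")
                    preds = {
                        "model": est.transform(src_d),
                        "identity": src_d,
                        "training": tgt_train,
                    }
                    for method, pred in preds.items():
                        rows.append(
                            {
                                "fold": fold_i,
                                "donor": d,
                                "cell_type": ct,
                                "perturbation": s,
                                "method": method,
                                "mae": mae_medians(pred, obs_d),
                                "mmd": mmd(pred, obs_d, max_cells=mmd_max_cells, seed=seed),
                                "r2": r2_medians(pred, obs_d),
                            }
                        )
    return EvalReport(metrics=pd.DataFrame(rows), folds=folds)
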