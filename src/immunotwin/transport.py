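"""Optimal-transport perturbation maps via input-convex potentials.

A perturbation response (stimulation, or drug within a stimulation context)
is modeled as a Monge map pushing the unperturbed single-cell marker
distribution onto the perturbed one. The map is the gradient of a convex
potential g, learned jointly with a second convex potential f through the
dual (minimax) formulation of the squared-Wasserstein problem on *unpaired*
samples: g minimizes E_x[f(grad g(x)) - <x, grad g(x)>] over source cells x,
while f minimizes E_y[f(y)] - E_x[f(grad g(x))] over target cells y, with
alternating inner/outer updates. At the optimum grad g pushes the source
distribution onto the target; for Gaussians with shared covariance it
reduces to the mean shift.

Both potentials are input-convex neural networks (ICNN): hidden passthrough
weights are constrained non-negative after every update and the activation
is convex and non-decreasing (leaky ReLU), so convexity in the input holds
by construction. A learnable non-negative quadratic skip ``alpha/2 ||x||^2``
plus a linear skip makes the identity map (alpha = 1, net ~ 0) the natural
starting point. Gradients are computed analytically, including the
second-order term the g-objective needs (differentiating through grad g):
with piecewise-linear activations the double-backward pass has a closed form
that matches reverse-mode autodiff almost everywhere.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .tables import OVERLAP_MARKERS, UNSTIMULATED, VEHICLE, SingleCellTable, classify_response_strength


@dataclass(frozen=True)
class ICNNConfig:
    """Architecture and training settings for one potential pair.

    ``hidden_units`` is the bottleneck structure of the potentials; when set
    to None, four hidden layers of width ``latent_dim`` are used instead
    (``latent_dim`` is the single width knob of the reference ICNN
    formulation; the two parameterizations are alternatives, not composed).
    ``n_iters`` counts outer iterations; each performs ``inner_iters``
    updates of g followed by one update of f.
    """

    hidden_units: tuple[int, ...] | None = (128, 128, 64, 32)
    latent_dim: int = 42
    n_iters: int = 50_000
    inner_iters: int = 10
    lr: float = 1e-3
    batch_size: int = 256
    leak: float = 0.2
    seed: int = 0
    min_cells: int = 50

    def resolved_hidden(self) -> tuple[int, ...]:
        return self.hidden_units if self.hidden_units is not None else (self.latent_dim,) * 4


#: Training profiles: the full-scale screen profile and a reduced profile for
#: synthetic work and tests.
PROFILES: dict[str, ICNNConfig] = {
    "paper": ICNNConfig(),
    "test": ICNNConfig(hidden_units=(64, 64), n_iters=2000, inner_iters=5, batch_size=128),
    "tiny": ICNNConfig(hidden_units=(32, 32), n_iters=400, inner_iters=3, batch_size=128),
}


class _ICNN:
    """One input-convex potential with analytic gradient machinery."""

    def __init__(self, dim: int, hidden: Sequence[int], leak: float, rng: np.random.Generator):
        self.dim = dim
        self.hidden = list(hidden)
        self.leak = leak
        self.params: dict[str, np.ndarray] = {}
        prev = None
        for l, h in enumerate(self.hidden):
            self.params[f"A{l}"] = rng.normal(0.0, 1.0 / np.sqrt(dim), size=(h, dim))
            self.params[f"b{l}"] = np.zeros(h)
            if l > 0:
                self.params[f"W{l}"] = np.abs(rng.normal(0.0, 0.1 / np.sqrt(prev), size=(h, prev)))
            prev = h
        self.params["w_out"] = np.abs(rng.normal(0.0, 0.1 / np.sqrt(prev), size=prev))
        self.params["a_out"] = np.zeros(dim)
        self.params["b_out"] = np.zeros(1)
        self.params["alpha"] = np.ones(1)

    # -- forward passes -------------------------------------------------
    def _act(self, s):
        return np.where(s > 0, s, self.leak * s)

    def _dact(self, s):
        return np.where(s > 0, 1.0, self.leak)

    def forward(self, X: np.ndarray):
        """Potential values plus cached pre/post activations."""
        S, Z = [], []
        z = None
        for l in range(len(self.hidden)):
            s = X @ self.params[f"A{l}"].T + self.params[f"b{l}"]
            if l > 0:
                s = s + z @ self.params[f"W{l}"].T
            z = self._act(s)
            S.append(s)
            Z.append(z)
        vals = (
            Z[-1] @ self.params["w_out"]
            + X @ self.params["a_out"]
            + self.params["b_out"][0]
            + 0.5 * self.params["alpha"][0] * np.sum(X * X, axis=1)
        )
        return vals, S, Z

    def value(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def grad_x(self, X: np.ndarray, cache=None) -> np.ndarray:
        """Input gradient (the transport map when this potential is g)."""
        if cache is None:
            _, S, _ = self.forward(X)
        else:
            S = cache
        L = len(self.hidden)
        g = self.params["alpha"][0] * X + self.params["a_out"]
        r = np.broadcast_to(self.params["w_out"], (X.shape[0], self.hidden[-1]))
        for l in range(L - 1, -1, -1):
            u = r * self._dact(S[l])
            g = g + u @ self.params[f"A{l}"]
            if l > 0:
                r = u @ self.params[f"W{l}"]
        return g

    # -- parameter gradients --------------------------------------------
    def param_grad_value(self, X: np.ndarray, coeff: np.ndarray, grads: dict) -> None:
        """Accumulate d/dtheta mean_i coeff_i * phi(x_i) into ``grads``."""
        _, S, Z = self.forward(X)
        B = X.shape[0]
        c = coeff / B
        grads["w_out"] += Z[-1].T @ c
        grads["a_out"] += X.T @ c
        grads["b_out"] += np.array([c.sum()])
        grads["alpha"] += np.array([0.5 * np.sum(c * np.sum(X * X, axis=1))])
        r = c[:, None] * self.params["w_out"]
        for l in range(len(self.hidden) - 1, -1, -1):
            u = r * self._dact(S[l])
            grads[f"A{l}"] += u.T @ X
            grads[f"b{l}"] += u.sum(axis=0)
            if l > 0:
                grads[f"W{l}"] += u.T @ Z[l - 1]
                r = u @ self.params[f"W{l}"]

    def param_grad_directional(self, X: np.ndarray, U: np.ndarray, grads: dict) -> None:
        """Accumulate d/dtheta mean_i <u_i, grad phi(x_i)> into ``grads``.

        This is the second-order term: the directional derivative
        D_u phi = <u, grad phi(x)> is computed by a forward tangent pass, and
        its parameter gradient by backpropagating through that (linear)
        tangent computation. Activation-curvature terms vanish a.e. for
        piecewise-linear activations.
        """
        _, S, _ = self.forward(X)
        L = len(self.hidden)
        B = X.shape[0]
        D = [self._dact(s) for s in S]
        Zd: list[np.ndarray] = []
        zd = None
        for l in range(L):
            sd = U @ self.params[f"A{l}"].T
            if l > 0:
                sd = sd + zd @ self.params[f"W{l}"].T
            zd = D[l] * sd
            Zd.append(zd)
        grads["w_out"] += Zd[-1].sum(axis=0) / B
        grads["a_out"] += U.sum(axis=0) / B
        grads["alpha"] += np.array([np.sum(X * U) / B])
        rho = np.broadcast_to(self.params["w_out"] / B, (B, self.hidden[-1]))
        for l in range(L - 1, -1, -1):
            nu = rho * D[l]
            grads[f"A{l}"] += nu.T @ U
            if l > 0:
                grads[f"W{l}"] += nu.T @ Zd[l - 1]
                rho = nu @ self.params[f"W{l}"]

    def zero_grads(self) -> dict:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def clamp_convex(self) -> None:
        for k, v in self.params.items():
            if k.startswith("W") or k in ("w_out", "alpha"):
                np.maximum(v, 0.0, out=v)

    def convexity_ok(self) -> bool:
        return all(
            np.all(v >= 0)
            for k, v in self.params.items()
            if k.startswith("W") or k in ("w_out", "alpha")
        )

    def state(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: Mapping[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(state[k], dtype=float)


class _Adam:
    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


class TrainingError(RuntimeError):
    pass


class ICNNTransport(BaseEstimator, TransformerMixin):
    """Scikit-learn style estimator for one transport map.

    fit(X, y) takes *unpaired* samples: X are source (unperturbed) cells,
    y are target (perturbed) cells, both n_cells x n_markers on the arcsinh
    scale. transform(X) applies the learned map grad g cell-wise; the output
    keeps cell count and marker order. Deterministic under a fixed seed.
    """

    def __init__(self, hidden_units=(64, 64), latent_dim=42, n_iters=2000,
                 inner_iters=5, lr=1e-3, batch_size=128, leak=0.2, seed=0,
                 min_cells=50):
        self.hidden_units = hidden_units
        self.latent_dim = latent_dim
        self.n_iters = n_iters
        self.inner_iters = inner_iters
        self.lr = lr
        self.batch_size = batch_size
        self.leak = leak
        self.seed = seed
        self.min_cells = min_cells

    @classmethod
    def from_config(cls, config: ICNNConfig) -> "ICNNTransport":
        return cls(
            hidden_units=config.hidden_units, latent_dim=config.latent_dim,
            n_iters=config.n_iters, inner_iters=config.inner_iters,
            lr=config.lr, batch_size=config.batch_size, leak=config.leak,
            seed=config.seed, min_cells=config.min_cells,
        )

    def _hidden(self):
        return self.hidden_units if self.hidden_units is not None else (self.latent_dim,) * 4

    def fit(self, X, y):
        Xs = np.asarray(X, dtype=float)
        Xt = np.asarray(y, dtype=float)
        if Xs.ndim != 2 or Xt.ndim != 2 or Xs.shape[1] != Xt.shape[1]:
            raise ValueError(
                f"source/target dimension mismatch: {Xs.shape} vs {Xt.shape}"
            )
        if len(Xs) < self.min_cells or len(Xt) < self.min_cells:
            raise ValueError(
                f"need >= {self.min_cells} cells per side, got {len(Xs)}/{len(Xt)}"
            )
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        dim = Xs.shape[1]
        rng = np.random.default_rng(self.seed)
        f = _ICNN(dim, self._hidden(), self.leak, rng)
        g = _ICNN(dim, self._hidden(), self.leak, rng)
        opt_f = _Adam(f.params, self.lr)
        opt_g = _Adam(g.params, self.lr)
        B = min(self.batch_size, len(Xs), len(Xt))
        trace = []
        for it in range(self.n_iters):
            for _ in range(self.inner_iters):
                xb = Xs[rng.integers(0, len(Xs), size=B)]
                T = g.grad_x(xb)
                U = f.grad_x(T) - xb
                grads = g.zero_grads()
                g.param_grad_directional(xb, U, grads)
                opt_g.step(g.params, grads)
                g.clamp_convex()
            xb = Xs[rng.integers(0, len(Xs), size=B)]
            yb = Xt[rng.integers(0, len(Xt), size=B)]
            T = g.grad_x(xb)
            grads = f.zero_grads()
            f.param_grad_value(yb, np.ones(B), grads)
            f.param_grad_value(T, -np.ones(B), grads)
            opt_f.step(f.params, grads)
            f.clamp_convex()
            if it % max(1, self.n_iters // 50) == 0 or it == self.n_iters - 1:
                loss = float(np.mean(f.value(yb)) - np.mean(f.value(T)))
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"non-finite dual loss at iteration {it}; "
                        f"lr={self.lr}, batch={B}, dim={dim}"
                    )
                trace.append({"iteration": it, "dual_loss": loss})
        self.f_, self.g_ = f, g
        self.loss_trace_ = pd.DataFrame(trace)
        self.n_features_in_ = dim
        return self

    def transform(self, X):
        if not hasattr(self, "g_"):
            raise RuntimeError("transport map is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"cells have {X.shape[1] if X.ndim == 2 else '?'} markers, "
                f"map expects {self.n_features_in_}"
            )
        return self.g_.grad_x(X)

    def convexity_ok(self) -> bool:
        return self.f_.convexity_ok() and self.g_.convexity_ok()


# ---------------------------------------------------------------------------
# Transport maps over named marker spaces, and the atlas-level registry
# ---------------------------------------------------------------------------

@dataclass
class TransportMap:
    """A fitted map for one (cell type, perturbation), over named markers."""

    markers: tuple[str, ...]
    estimator: ICNNTransport | None = None
    identity: bool = False
    meta: dict = field(default_factory=dict)

    def transport(self, cells: pd.DataFrame) -> pd.DataFrame:
        missing = [m for m in self.markers if m not in cells.columns]
        if missing:
            raise ValueError(f"cells missing map markers: {missing}")
        sub = cells[list(self.markers)]
        if self.identity:
            return sub.copy()
        out = self.estimator.transform(sub.to_numpy())
        return pd.DataFrame(out, columns=list(self.markers), index=sub.index)


def stim_key(cell_type: str, stimulation: str) -> tuple:
    return ("stimulation", cell_type, stimulation)


def drug_key(cell_type: str, drug: str, context: str = UNSTIMULATED) -> tuple:
    return ("drug", cell_type, drug, context)


def _map_seed(master_seed: int, key: tuple) -> int:
    import zlib

    return int((int(master_seed) * 1_000_003 + zlib.crc32("|".join(map(str, key)).encode())) % (2**31 - 1))


class TransportRegistry:
    """Keyed collection of transport maps for an atlas.

    Keys are ``("stimulation", cell_type, stim)`` for stimulation-response
    maps (source: unstimulated vehicle cells) and
    ``("drug", cell_type, drug, context)`` for drug maps within a stimulation
    context (context ``"unstimulated"`` for drug-at-baseline maps).
    """

    def __init__(self, markers: Sequence[str] = OVERLAP_MARKERS):
        self.markers = tuple(markers)
        self.maps: dict[tuple, TransportMap] = {}
        self.skipped: list[dict] = []

    def __contains__(self, key):
        return tuple(key) in self.maps

    def get(self, key) -> TransportMap | None:
        return self.maps.get(tuple(key))

    def add(self, key, tmap: TransportMap) -> None:
        self.maps[tuple(key)] = tmap

    @classmethod
    def identity(cls, cell_types: Sequence[str], stimulations: Sequence[str] = (),
                 drugs: Sequence[str] = (), markers: Sequence[str] = OVERLAP_MARKERS,
                 ) -> "TransportRegistry":
        """All-identity registry: the exact no-effect null for end-to-end tests."""
        reg = cls(markers)
        for ct in cell_types:
            for s in stimulations:
                reg.add(stim_key(ct, s), TransportMap(reg.markers, identity=True))
            for d in drugs:
                reg.add(drug_key(ct, d), TransportMap(reg.markers, identity=True))
                for s in stimulations:
                    reg.add(drug_key(ct, d, s), TransportMap(reg.markers, identity=True))
        return reg


def strong_response_registry(
    tables: Sequence[SingleCellTable],
    markers: Sequence[str] = OVERLAP_MARKERS,
) -> dict[tuple[str, str], bool]:
    """Whether each (cell type, stimulation) shows >= 1 strong response.

    Computed on vehicle arms, pooling cells across donors and vehicle
    replicates; the response per marker is stimulated minus unstimulated
    pooled median.
    """
    pool: dict[tuple, list] = {}
    for t in tables:
        if t.treatment != VEHICLE:
            continue
        pool.setdefault((t.cell_type, t.stimulation), []).append(t.data)
    out: dict[tuple[str, str], bool] = {}
    for (ct, s), frames in pool.items():
        if s == UNSTIMULATED:
            continue
        base_frames = pool.get((ct, UNSTIMULATED))
        if base_frames is None:
            continue
        stim_med = pd.concat(frames).median()
        base_med = pd.concat(base_frames).median()
        strong = any(
            classify_response_strength(stim_med[m] - base_med[m], s) == "strong"
            for m in markers
        )
        out[(ct, s)] = strong
    return out


def _pool(tables: Sequence[SingleCellTable], cell_type: str, stimulation: str,
          treatment: str, markers: Sequence[str], max_cells: int, rng) -> np.ndarray | None:
    frames = [
        t.data[list(markers)]
        for t in tables
        if t.cell_type == cell_type and t.stimulation == stimulation and t.treatment == treatment
    ]
    if not frames:
        return None
    x = pd.concat(frames).to_numpy()
    if len(x) > max_cells:
        x = x[rng.choice(len(x), size=max_cells, replace=False)]
    return x


def train_atlas_models(
    tables: Sequence[SingleCellTable],
    config: ICNNConfig,
    markers: Sequence[str] = OVERLAP_MARKERS,
    cell_types: Sequence[str] | None = None,
    stimulations: Sequence[str] | None = None,
    drugs: Sequence[str] | None = None,
    strong_registry: Mapping[tuple[str, str], bool] | None = None,
    train_drug_in_context: bool = True,
    max_cells: int = 5000,
    hard_fail: bool = False,
) -> TransportRegistry:
    """Train the full registry of per-(cell type, perturbation) maps.

    Stimulation maps go from pooled unstimulated vehicle cells to pooled
    stimulated vehicle cells; they are trained only for combinations with at
    least one strong response (per ``strong_registry``, computed from the
    tables when not given). Drug maps go from vehicle to drug-treated cells
    within each stimulation context, plus the unstimulated-baseline context.
    Missing conditions are skipped and logged (or raised with
    ``hard_fail=True``). Per-map seeds expand deterministically from
    ``config.seed`` keyed by the map identity.
    """
    tables = list(tables)
    if cell_types is None:
        cell_types = sorted({t.cell_type for t in tables})
    if stimulations is None:
        stimulations = sorted({t.stimulation for t in tables if t.stimulation != UNSTIMULATED})
    if drugs is None:
        drugs = sorted({t.treatment for t in tables if t.treatment != VEHICLE})
    if strong_registry is None:
        strong_registry = strong_response_registry(tables, markers)

    reg = TransportRegistry(markers)
    rng = np.random.default_rng(config.seed)

    def _train(key, source, target):
        est = ICNNTransport.from_config(config)
        est.set_params(seed=_map_seed(config.seed, key))
        est.fit(source, target)
        reg.add(key, TransportMap(reg.markers, estimator=est,
                                  meta={"key": key, "seed": est.seed,
                                        "n_source": len(source), "n_target": len(target)}))

    def _skip(key, reason):
        if hard_fail:
            raise ValueError(f"cannot train {key}: {reason}")
        reg.skipped.append({"key": key, "reason": reason})

    for ct in cell_types:
        base = _pool(tables, ct, UNSTIMULATED, VEHICLE, markers, max_cells, rng)
        for s in stimulations:
            key = stim_key(ct, s)
            if not strong_registry.get((ct, s), False):
                _skip(key, "no strong response")
                continue
            tgt = _pool(tables, ct, s, VEHICLE, markers, max_cells, rng)
            if base is None or tgt is None:
                _skip(key, "missing condition")
                continue
            _train(key, base, tgt)
        for d in drugs:
            contexts = [UNSTIMULATED] + (list(stimulations) if train_drug_in_context else [])
            for s in contexts:
                if s != UNSTIMULATED and not strong_registry.get((ct, s), False):
                    _skip(drug_key(ct, d, s), "no strong response in context")
                    continue
                key = drug_key(ct, d, s)
                src = base if s == UNSTIMULATED else _pool(tables, ct, s, VEHICLE, markers, max_cells, rng)
                tgt = _pool(tables, ct, s, d, markers, max_cells, rng)
                if src is None or tgt is None:
                    _skip(key, "missing condition")
                    continue
                _train(key, src, tgt)
    return reg


# ---------------------------------------------------------------------------
# Registry persistence
# ---------------------------------------------------------------------------

def save_registry(reg: TransportRegistry, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"markers": list(reg.markers), "maps": [], "skipped": [
        {"key": list(s["key"]), "reason": s["reason"]} for s in reg.skipped]}
    for i, (key, tmap) in enumerate(sorted(reg.maps.items())):
        entry = {"key": list(key), "identity": tmap.identity, "meta": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in tmap.meta.items()}}
        if not tmap.identity:
            fname = f"map_{i:04d}.npz"
            est = tmap.estimator
            arrays = {f"f__{k}": v for k, v in est.f_.state().items()}
            arrays.update({f"g__{k}": v for k, v in est.g_.state().items()})
            np.savez(path / fname, **arrays)
            entry["file"] = fname
            entry["params"] = est.get_params()
        manifest["maps"].append(entry)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return path


def load_registry(path: str | Path) -> TransportRegistry:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    reg = TransportRegistry(tuple(manifest["markers"]))
    reg.skipped = [{"key": tuple(s["key"]), "reason": s["reason"]} for s in manifest["skipped"]]
    for entry in manifest["maps"]:
        key = tuple(entry["key"])
        if entry["identity"]:
            reg.add(key, TransportMap(reg.markers, identity=True, meta=entry.get("meta", {})))
            continue
        params = entry["params"]
        if isinstance(params.get("hidden_units"), list):
            params["hidden_units"] = tuple(params["hidden_units"])
        est = ICNNTransport(**params)
        data = np.load(path / entry["file"])
        dim = len(reg.markers)
        rng = np.random.default_rng(0)
        est.f_ = _ICNN(dim, est._hidden(), est.leak, rng)
        est.g_ = _ICNN(dim, est._hidden(), est.leak, rng)
        est.f_.load_state({k[3:]: data[k] for k in data.files if k.startswith("f__")})
        est.g_.load_state({k[3:]: data[k] for k in data.files if k.startswith("g__")})
        est.n_features_in_ = dim
        reg.add(key, TransportMap(reg.markers, estimator=est, meta=entry.get("meta", {})))
    return reg


def train_transport_map(source, target, config: ICNNConfig) -> ICNNTransport:
    """Functional wrapper: fit one map from source to target cells."""
    return ICNNTransport.from_config(config).fit(np.asarray(source), np.asarray(target))


def apply_transport(tmap, cells):
    """Apply a fitted map; accepts TransportMap (DataFrame) or estimator (array)."""
    if isinstance(tmap, TransportMap):
        return tmap.transport(cells)
    return tmap.transform(cells)
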