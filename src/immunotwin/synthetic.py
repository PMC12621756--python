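"""Ground-truth-annotated synthetic immunome data.

Emulates, on the arcsinh scale, the structure of an ex vivo whole-blood
perturbation screen: donor-heterogeneous baseline signaling, additive
stimulation and drug shifts (with optional interaction terms for planting
synergy), a clinical cohort whose time-to-labor outcome is a linear function
of planted immune features, and barcoded event streams for the combinatorial
debarcoder. Everything is seeded and deterministic so that each downstream
stage can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    CELL_TYPES_REDUCED,
    OVERLAP_MARKERS,
    UNSTIMULATED,
    VEHICLE,
    SingleCellTable,
    feature_name,
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Dimensions of a synthetic perturbation screen.

    Cell types, stimulations, treatments and markers are label lists; a
    vehicle arm (``DMSO``, three replicate columns) is always generated in
    addition to ``treatments``. One seed fixes every draw.
    """

    n_donors: int = 4
    n_cells: int = 1000
    cell_types: tuple[str, ...] = CELL_TYPES_REDUCED
    stimulations: tuple[str, ...] = ("LPS", "IL-246")
    treatments: tuple[str, ...] = ()
    markers: tuple[str, ...] = OVERLAP_MARKERS
    cohort: str = "pregnant"
    n_vehicle_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        for name, v in (("n_donors", self.n_donors), ("n_cells", self.n_cells)):
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        for name, v in (
            ("cell_types", self.cell_types),
            ("stimulations", self.stimulations),
            ("markers", self.markers),
        ):
            if len(v) < 1:
                raise ConfigurationError(f"{name} must be non-empty")


@dataclass
class GroundTruth:
    """Planted effects on the arcsinh scale.

    ``stim_effects`` / ``drug_effects`` map ``(cell_type, marker, label)`` to
    ``(delta, sigma_factor)``: an additive location shift and a multiplicative
    scale factor on the baseline cell-level spread. ``interactions`` maps
    ``(cell_type, marker, stimulation, treatment)`` to an extra additive shift
    (synergy planting). ``tau`` is the donor random-effect scale — one offset
    per (donor, cell type, marker), shared across all of that donor's
    conditions. ``outcome_weights`` defines the clinical link over feature
    names; ``outcome_noise`` is its Gaussian noise scale (days).
    """

    baseline: Mapping[tuple[str, str], float] = field(default_factory=dict)
    stim_effects: Mapping[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    drug_effects: Mapping[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    interactions: Mapping[tuple[str, str, str, str], float] = field(default_factory=dict)
    tau: float = 0.0
    cell_sd: float = 0.2
    drift_slope: float = 0.0
    outcome_weights: Mapping[str, float] = field(default_factory=dict)
    outcome_noise: float = 0.0
    heavy_tails: bool = False

    def __post_init__(self):
        for (ct, m, lab), (delta, sig) in {**self.stim_effects, **self.drug_effects}.items():
            if not np.isfinite(delta) or not np.isfinite(sig):
                raise ConfigurationError(f"non-finite effect for ({ct}, {m}, {lab})")
            if sig <= 0:
                raise ConfigurationError(f"scale factor must be > 0 for ({ct}, {m}, {lab})")
        if self.cell_sd <= 0:
            raise ConfigurationError("cell_sd must be > 0")
        if not np.isfinite(self.tau) or not np.isfinite(self.outcome_noise):
            raise ConfigurationError("tau and outcome_noise must be finite")

    @classmethod
    def null(cls, config: SyntheticConfig, **kwargs) -> "GroundTruth":
        """Truth covering every combination of ``config`` with zero effects."""
        stim = {
            (ct, m, s): (0.0, 1.0)
            for ct in config.cell_types
            for m in config.markers
            for s in config.stimulations
        }
        drug = {
            (ct, m, t): (0.0, 1.0)
            for ct in config.cell_types
            for m in config.markers
            for t in config.treatments
        }
        base = {(ct, m): 1.0 for ct in config.cell_types for m in config.markers}
        gt = cls(baseline=base, stim_effects=stim, drug_effects=drug, **kwargs)
        return gt

    @classmethod
    def from_effects(
        cls,
        config: SyntheticConfig,
        stim_effects: Mapping[tuple[str, str, str], float | tuple[float, float]] | None = None,
        drug_effects: Mapping[tuple[str, str, str], float | tuple[float, float]] | None = None,
        **kwargs,
    ) -> "GroundTruth":
        """Truth from sparse effect dicts; unlisted combinations are null.

        Scalar values are taken as pure location shifts (sigma factor 1).
        """
        gt = cls.null(config, **kwargs)
        stim = dict(gt.stim_effects)
        drug = dict(gt.drug_effects)
        for src, dst, kind in ((stim_effects, stim, "stimulation"), (drug_effects, drug, "treatment")):
            if not src:
                continue
            for key, val in src.items():
                if key not in dst:
                    raise ConfigurationError(
                        f"{kind} effect key {key} not covered by config"
                    )
                dst[key] = (float(val), 1.0) if np.isscalar(val) else (float(val[0]), float(val[1]))
        gt.stim_effects = stim
        gt.drug_effects = drug
        return gt

    def effect(self, kind: str, cell_type: str, marker: str, label: str) -> tuple[float, float]:
        table = self.stim_effects if kind == "stimulation" else self.drug_effects
        try:
            return table[(cell_type, marker, label)]
        except KeyError:
            raise ConfigurationError(
                f"ground truth has no {kind} effect for "
                f"(cell_type={cell_type!r}, marker={marker!r}, {kind}={label!r})"
            ) from None


def _donor_offsets(rng: np.random.Generator, config: SyntheticConfig, truth: GroundTruth,
                   donors: Sequence[str]) -> dict[tuple[str, str, str], float]:
    """One additive offset per (donor, cell type, marker), shared across conditions."""
    out = {}
    for d in donors:
        for ct in config.cell_types:
            draws = rng.normal(0.0, truth.tau, size=len(config.markers)) if truth.tau > 0 else np.zeros(len(config.markers))
            for m, off in zip(config.markers, draws):
                out[(d, ct, m)] = float(off)
    return out


def _draw_cells(rng: np.random.Generator, n: int, means: np.ndarray, sds: np.ndarray,
                heavy_tails: bool) -> np.ndarray:
    x = rng.normal(means, sds, size=(n, means.size))
    if heavy_tails:
        # 5% contamination at 4x spread, a crude robustness stressor
        mask = rng.random((n, means.size)) < 0.05
        x = np.where(mask, rng.normal(means, 4 * sds, size=(n, means.size)), x)
    return x


def _plate_columns(config: SyntheticConfig) -> dict[tuple[str, int], int]:
    """Treatment -> plate column (0-based), vehicles at columns 0, 5, 11."""
    vehicle_cols = [0, 5, 11][: config.n_vehicle_replicates]
    cols: dict[tuple[str, int], int] = {}
    for i, c in enumerate(vehicle_cols):
        cols[(VEHICLE, i)] = c
    free = [c for c in range(12) if c not in vehicle_cols]
    for i, t in enumerate(config.treatments):
        cols[(t, 0)] = free[i % len(free)]
    return cols


def generate_atlas(
    config: SyntheticConfig,
    truth: GroundTruth,
    donors: Sequence[str] | None = None,
) -> list[SingleCellTable]:
    """Synthetic perturbation atlas.

    For every (donor, cell type, stimulation incl. unstimulated, treatment
    arm incl. vehicle replicates) a table is drawn with per-marker mean
    ``baseline + donor offset + stim delta + drug delta + interaction
    (+ column drift)`` and spread ``cell_sd * sigma_stim * sigma_drug``.
    """
    rng = np.random.default_rng(config.seed)
    if donors is None:
        donors = [f"D{i + 1:02d}" for i in range(config.n_donors)]
    offsets = _donor_offsets(rng, config, truth, donors)
    cols = _plate_columns(config)

    arms = [(VEHICLE, r) for r in range(config.n_vehicle_replicates)]
    arms += [(t, 0) for t in config.treatments]
    stims = (UNSTIMULATED,) + tuple(config.stimulations)
    markers = list(config.markers)

    tables = []
    for d in donors:
        for ct in config.cell_types:
            off = np.array([offsets[(d, ct, m)] for m in markers])
            base = np.array([truth.baseline.get((ct, m), 1.0) for m in markers])
            for s in stims:
                if s == UNSTIMULATED:
                    sd_, ss_ = np.zeros(len(markers)), np.ones(len(markers))
                else:
                    eff = [truth.effect("stimulation", ct, m, s) for m in markers]
                    sd_ = np.array([e[0] for e in eff])
                    ss_ = np.array([e[1] for e in eff])
                for (t, rep) in arms:
                    if t == VEHICLE:
                        dd_, ds_ = np.zeros(len(markers)), np.ones(len(markers))
                    else:
                        eff = [truth.effect("treatment", ct, m, t) for m in markers]
                        dd_ = np.array([e[0] for e in eff])
                        ds_ = np.array([e[1] for e in eff])
                    inter = np.array([
                        truth.interactions.get((ct, m, s, t), 0.0) for m in markers
                    ]) if s != UNSTIMULATED and t != VEHICLE else np.zeros(len(markers))
                    drift = truth.drift_slope * cols[(t, rep)]
                    means = base + off + sd_ + dd_ + inter + drift
                    sds = truth.cell_sd * ss_ * ds_
                    x = _draw_cells(rng, config.n_cells, means, sds, truth.heavy_tails)
                    tables.append(
                        SingleCellTable(
                            data=pd.DataFrame(x, columns=markers),
                            donor=d,
                            cohort=config.cohort,
                            cell_type=ct,
                            stimulation=s,
                            treatment=t,
                            replicate=rep,
                        )
                    )
    return tables


def true_feature_value(truth: GroundTruth, config: SyntheticConfig, name: str) -> float:
    """Population-level expectation of a feature under the planted truth."""
    ct, m, s, stat = name.split("|")
    if stat == "baseline":
        return truth.baseline.get((ct, m), 1.0)
    return truth.effect("stimulation", ct, m, s)[0]


def generate_clinical_cohort(
    config: SyntheticConfig,
    truth: GroundTruth,
    n_patients: int,
    samples_per_patient: int | Sequence[int] = 3,
    gestational_day_range: tuple[float, float] = (160.0, 270.0),
    preterm_cutoff: float = 259.0,
    sample_jitter: float = 0.05,
    seed: int | None = None,
) -> tuple[list[SingleCellTable], pd.DataFrame, pd.DataFrame]:
    """Baseline-only clinical cohort with a planted outcome link.

    Each patient contributes 1-3 unstimulated, untreated samples. Per sample,
    time to labor = sum_f w_f * (true feature value for that patient/sample)
    + Gaussian noise (scale ``truth.outcome_noise``), clipped at 0. The
    term/preterm label compares gestational day + time to labor against
    ``preterm_cutoff`` (259 d = 37 weeks).

    Returns (cell tables, outcome table, true per-sample feature values).
    """
    if not truth.outcome_weights:
        raise ConfigurationError("outcome link weights are not defined")
    spp = np.atleast_1d(samples_per_patient)
    if np.any((spp < 1) | (spp > 3)):
        raise ConfigurationError("samples_per_patient must be within 1-3")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # validate link targets exist in the atlas feature space
    for name in truth.outcome_weights:
        ct, m, s, stat = name.split("|")
        if ct not in config.cell_types or m not in config.markers:
            raise ConfigurationError(f"outcome link feature {name!r} not in generated atlas")
        if stat == "response" and s not in config.stimulations:
            raise ConfigurationError(f"outcome link feature {name!r} not in generated atlas")

    markers = list(config.markers)
    patients = [f"P{i + 1:03d}" for i in range(n_patients)]
    offsets = _donor_offsets(rng, config, truth, patients)

    tables: list[SingleCellTable] = []
    outcome_rows = []
    truth_rows = []
    lo, hi = gestational_day_range
    for p in patients:
        n_s = int(spp[0]) if spp.size == 1 else int(rng.choice(spp))
        days = np.sort(rng.uniform(lo, hi, size=n_s))
        for j, day in enumerate(days):
            sid = f"{p}-s{j + 1}"
            latents: dict[str, float] = {}
            for ct in config.cell_types:
                base = np.array([truth.baseline.get((ct, m), 1.0) for m in markers])
                off = np.array([offsets[(p, ct, m)] for m in markers])
                jit = rng.normal(0.0, sample_jitter, size=len(markers)) if sample_jitter > 0 else np.zeros(len(markers))
                means = base + off + jit
                for m, mu in zip(markers, means):
                    latents[feature_name(ct, m, UNSTIMULATED, "baseline")] = float(mu)
                for s in config.stimulations:
                    for m in markers:
                        latents[feature_name(ct, m, s, "response")] = truth.effect("stimulation", ct, m, s)[0]
                x = _draw_cells(rng, config.n_cells, means,
                                np.full(len(markers), truth.cell_sd), truth.heavy_tails)
                tables.append(
                    SingleCellTable(
                        data=pd.DataFrame(x, columns=markers),
                        donor=sid,
                        cohort="clinical",
                        cell_type=ct,
                    )
                )
            ttl = sum(w * latents[f] for f, w in truth.outcome_weights.items())
            if truth.outcome_noise > 0:
                ttl += rng.normal(0.0, truth.outcome_noise)
            ttl = max(ttl, 0.0)
            length = day + ttl
            outcome_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": p,
                    "gestational_day": float(day),
                    "time_to_labor": float(ttl),
                    "gestational_length": float(length),
                    "preterm": bool(length < preterm_cutoff),
                }
            )
            truth_rows.append(pd.Series(latents, name=sid))
    outcomes = pd.DataFrame(outcome_rows).set_index("sample_id")
    true_features = pd.DataFrame(truth_rows)
    true_features.index.name = "sample_id"
    return tables, outcomes, true_features


def generate_barcoded_events(
    scheme,
    n_singlets: int,
    doublet_rate: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    positive_level: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthetic barcode-channel event stream with true provenance.

    Singlets carry ``positive_level`` on exactly the k channels of a code
    drawn uniformly from the scheme's full codebook, plus Gaussian noise
    truncated at 0. Doublets are the channel-wise maximum of two distinct
    random codes' noiseless patterns (plus noise). Returns (events, truth)
    where truth records each event's kind and source code(s).
    """
    if not (0.0 <= doublet_rate <= 1.0):
        raise ConfigurationError("doublet_rate must be in [0, 1]")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    codebook = list(scheme.codebook)
    n_channels = scheme.n_channels
    n_doublets = int(round(n_singlets * doublet_rate / (1 - doublet_rate))) if doublet_rate > 0 else 0

    def pattern(code) -> np.ndarray:
        v = np.zeros(n_channels)
        v[list(code)] = positive_level
        return v

    events, rows = [], []
    idx = rng.integers(0, len(codebook), size=n_singlets)
    for i in idx:
        events.append(pattern(codebook[i]))
        rows.append({"kind": "singlet", "code_a": codebook[i], "code_b": None})
    for _ in range(n_doublets):
        a, b = rng.choice(len(codebook), size=2, replace=False)
        events.append(np.maximum(pattern(codebook[a]), pattern(codebook[b])))
        rows.append({"kind": "doublet", "code_a": codebook[a], "code_b": codebook[b]})
    ev = np.array(events) if events else np.zeros((0, n_channels))
    if noise_sd > 0 and len(ev):
        ev = np.clip(ev + rng.normal(0.0, noise_sd, size=ev.shape), 0.0, None)
    order = rng.permutation(len(ev))
    truth = pd.DataFrame(rows).iloc[order].reset_index(drop=True) if rows else pd.DataFrame(
        columns=["kind", "code_a", "code_b"])
    return ev[order], truth
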