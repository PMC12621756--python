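"""Digital-twin expansion of baseline-only clinical samples.

A clinical sample arrives as gated unstimulated cells per cell type. The
stimulation maps simulate its response to each stimulation, yielding an
*untreated* feature row over the p x (s + 1) feature space (baseline medians
plus simulated response medians). Drug maps then produce one *treated* row
per drug over the identical feature index: drug-at-baseline maps transform
the unstimulated cells, and drug-within-stimulation maps are composed on the
simulated stimulated cells. Weak simulated responses (cross-sample median
below 0.1 arcsinh, computed on untreated rows) are removed from both
matrices so that the treated-minus-untreated contrast is well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import UNSTIMULATED, SingleCellTable, feature_name, parse_feature_name
from .transport import TransportRegistry, drug_key, stim_key

WEAK_RESPONSE_THRESHOLD = 0.1


@dataclass
class TwinFeatureSet:
    """Untreated and per-drug treated feature matrices on a shared index."""

    untreated: pd.DataFrame
    treated: dict[str, pd.DataFrame] = field(default_factory=dict)

    def penalized(self, threshold: float = WEAK_RESPONSE_THRESHOLD) -> "TwinFeatureSet":
        keep = penalize_weak(self.untreated, threshold)
        return TwinFeatureSet(
            untreated=self.untreated[keep],
            treated={d: m[keep] for d, m in self.treated.items()},
        )


def _sample_cells(tables: Sequence[SingleCellTable]) -> dict[str, dict[str, pd.DataFrame]]:
    """Group unstimulated clinical tables into sample -> cell type -> cells."""
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for t in tables:
        if t.stimulation != UNSTIMULATED:
            continue
        out.setdefault(t.donor, {})[t.cell_type] = t.data
    return out


def expand_baseline(
    cells_by_type: Mapping[str, pd.DataFrame],
    registry: TransportRegistry,
    stimulations: Sequence[str],
    cell_types: Sequence[str] | None = None,
) -> tuple[pd.Series, dict[str, pd.DataFrame]]:
    """Untreated feature row for one sample, plus simulated stimulated cells.

    Baseline features are the observed unstimulated medians; response
    features are median(transported) - median(baseline) per map. Missing
    maps or absent cell types yield NaN features with a warning. The
    simulated stimulated cells are returned for drug-map composition.
    """
    if cell_types is None:
        cell_types = sorted(cells_by_type)
    markers = registry.markers
    row: dict[str, float] = {}
    simulated: dict[str, pd.DataFrame] = {}
    for ct in cell_types:
        cells = cells_by_type.get(ct)
        if cells is None or len(cells) == 0:
            warnings.warn(f"no cells for cell type {ct!r}; features set to NaN")
            for m in markers:
                row[feature_name(ct, m, UNSTIMULATED, "baseline")] = np.nan
                for s in stimulations:
                    row[feature_name(ct, m, s, "response")] = np.nan
            continue
        base_med = cells[list(markers)].median()
        for m in markers:
            row[feature_name(ct, m, UNSTIMULATED, "baseline")] = base_med[m]
        for s in stimulations:
            tmap = registry.get(stim_key(ct, s))
            if tmap is None:
                for m in markers:
                    row[feature_name(ct, m, s, "response")] = np.nan
                continue
            moved = tmap.transport(cells)
            simulated[f"{ct}|{s}"] = moved
            mmed = moved.median()
            for m in markers:
                row[feature_name(ct, m, s, "response")] = mmed[m] - base_med[m]
    return pd.Series(row), simulated


def apply_treatments(
    cells_by_type: Mapping[str, pd.DataFrame],
    registry: TransportRegistry,
    drugs: Sequence[str],
    stimulations: Sequence[str],
    simulated: Mapping[str, pd.DataFrame] | None = None,
    cell_types: Sequence[str] | None = None,
) -> dict[str, pd.Series]:
    """Per-drug treated feature rows for one sample.

    For each drug, baseline features come from the drug-at-unstimulated map
    applied to the observed cells; response features compose the
    drug-within-stimulation map on the simulated stimulated cells (the
    stimulation map's output), with the treated baseline as the reference.
    """
    if cell_types is None:
        cell_types = sorted(cells_by_type)
    markers = registry.markers
    if simulated is None:
        _, simulated = expand_baseline(cells_by_type, registry, stimulations, cell_types)
    out: dict[str, pd.Series] = {}
    for drug in drugs:
        row: dict[str, float] = {}
        for ct in cell_types:
            cells = cells_by_type.get(ct)
            if cells is None or len(cells) == 0:
                for m in markers:
                    row[feature_name(ct, m, UNSTIMULATED, "baseline")] = np.nan
                    for s in stimulations:
                        row[feature_name(ct, m, s, "response")] = np.nan
                continue
            base_map = registry.get(drug_key(ct, drug, UNSTIMULATED))
            if base_map is None:
                treated_base = cells[list(markers)]
            else:
                treated_base = base_map.transport(cells)
            base_med = treated_base.median()
            for m in markers:
                row[feature_name(ct, m, UNSTIMULATED, "baseline")] = base_med[m]
            for s in stimulations:
                sim = simulated.get(f"{ct}|{s}")
                dmap = registry.get(drug_key(ct, drug, s))
                if sim is None:
                    for m in markers:
                        row[feature_name(ct, m, s, "response")] = np.nan
                    continue
                treated_stim = dmap.transport(sim) if dmap is not None else sim
                smed = treated_stim.median()
                for m in markers:
                    row[feature_name(ct, m, s, "response")] = smed[m] - base_med[m]
        out[drug] = pd.Series(row)
    return out


def expand_cohort(
    tables: Sequence[SingleCellTable],
    registry: TransportRegistry,
    drugs: Sequence[str],
    stimulations: Sequence[str],
    cell_types: Sequence[str] | None = None,
) -> TwinFeatureSet:
    """Expand every clinical sample into untreated + per-drug treated rows."""
    grouped = _sample_cells(tables)
    if cell_types is None:
        cell_types = sorted({ct for g in grouped.values() for ct in g})
    unt_rows, trt_rows = {}, {d: {} for d in drugs}
    for sid in sorted(grouped):
        row, simulated = expand_baseline(grouped[sid], registry, stimulations, cell_types)
        unt_rows[sid] = row
        for d, trow in apply_treatments(
            grouped[sid], registry, drugs, stimulations, simulated, cell_types
        ).items():
            trt_rows[d][sid] = trow
    untreated = pd.DataFrame(unt_rows).T
    untreated.index.name = "sample_id"
    treated = {}
    for d in drugs:
        m = pd.DataFrame(trt_rows[d]).T
        m.index.name = "sample_id"
        treated[d] = m[untreated.columns]
    return TwinFeatureSet(untreated=untreated, treated=treated)


def penalize_weak(
    features: pd.DataFrame, threshold: float = WEAK_RESPONSE_THRESHOLD
) -> list[str]:
    """Retained feature index after removing weak simulated responses.

    Response features whose median across samples is below ``threshold``
    (signed, matching the strong/weak convention) are dropped; baseline
    features are always retained. Apply the returned index to untreated and
    treated matrices alike.
    """
    if len(features) < 1:
        raise ValueError("need at least one sample")
    keep = []
    med = features.median(axis=0)
    for col in features.columns:
        _, _, _, stat = parse_feature_name(col)
        if stat == "baseline" or med[col] >= threshold:
            keep.append(col)
    return keep
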