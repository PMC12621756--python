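"""Single-cell marker tables, the arcsinh transform, and screen feature matrices.

Mass-cytometry intensities are analyzed on the arcsinh scale (``asinh(x / cofactor)``
with cofactor 5). Gated populations arrive as one table per condition — a
cells-by-markers matrix plus condition metadata (donor, cohort, cell type,
stimulation, treatment) — and are summarized into a samples-by-features matrix
of population medians: *baseline* features are unstimulated medians,
*response* features are stimulated minus unstimulated medians.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNSTIMULATED = "unstimulated"
VEHICLE = "DMSO"

COHORTS = ("pregnant", "non-pregnant", "clinical")

#: Intracellular functional markers shared between the perturbation screen and
#: baseline-only clinical panels; transport maps are trained on these 13.
OVERLAP_MARKERS = (
    "pSTAT1", "pSTAT3", "pSTAT4", "pSTAT5", "pSTAT6",
    "pMAPKAPK2", "pCREB", "pPLCg2", "pS6", "pERK12",
    "pP38", "pNFkB", "IkB",
)

#: Surface functional markers measured in the screen only.
SCREEN_ONLY_MARKERS = ("PD-1", "PD-L1", "CD25", "CD36", "CD44", "GLUT1", "HLA-DR")

STIMULATIONS = ("LPS", "IFNa", "IL-33", "GMCSF", "TNFa", "IL-246", "PI")

DRUGS = ("CHT", "MAP", "MF", "LPZ", "PRA", "RIF", "SA", "SALPZ", "THF")

#: Reduced cell-type set used by default in synthetic work; the full screen
#: gates 28 populations.
CELL_TYPES_REDUCED = ("Granulocytes", "cMC", "ncMC", "NK", "CD4Tnaive", "CD8Tnaive")

CELL_TYPES_FULL = CELL_TYPES_REDUCED + tuple(f"pop{i:02d}" for i in range(7, 29))

_META_COLUMNS = ("donor", "cohort", "cell_type", "stimulation", "treatment", "replicate")


class SchemaError(ValueError):
    """A table does not conform to the documented schema or panel."""


def arcsinh_transform(raw, cofactor: float = 5.0):
    """Variance-stabilizing transform ``asinh(raw / cofactor)``.

    Monotone and invertible; cofactor 5 is the mass-cytometry standard.
    """
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(raw, dtype=float) / cofactor)


def inverse_arcsinh(values, cofactor: float = 5.0):
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.sinh(np.asarray(values, dtype=float)) * cofactor


@dataclass(frozen=True)
class PanelDefinition:
    """Marker panel: phenotypic (gating) vs functional (readout) markers.

    ``overlap`` is the functional subset shared with a baseline-only clinical
    panel; it must be contained in ``functional``.
    """

    phenotypic: tuple[str, ...] = ()
    functional: tuple[str, ...] = OVERLAP_MARKERS + SCREEN_ONLY_MARKERS
    overlap: tuple[str, ...] = OVERLAP_MARKERS
    mass_channels: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.functional)) != len(self.functional):
            raise SchemaError("duplicate functional marker names")
        missing = set(self.overlap) - set(self.functional)
        if missing:
            raise SchemaError(f"overlap markers not in functional set: {sorted(missing)}")

    @property
    def markers(self) -> tuple[str, ...]:
        return self.functional


DEFAULT_PANEL = PanelDefinition()


@dataclass
class SingleCellTable:
    """One condition's cells-by-markers matrix (arcsinh scale) plus metadata."""

    data: pd.DataFrame
    donor: str
    cohort: str
    cell_type: str
    stimulation: str = UNSTIMULATED
    treatment: str = VEHICLE
    replicate: int = 0
    raw_scale: bool = False

    def __post_init__(self):
        if len(self.data) < 1:
            raise SchemaError("SingleCellTable requires at least one cell")
        if self.cohort not in COHORTS:
            raise SchemaError(f"unknown cohort {self.cohort!r}; expected one of {COHORTS}")

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def medians(self) -> pd.Series:
        """Per-marker median over cells (midpoint convention for even counts)."""
        return self.data.median(axis=0)

    def condition_key(self) -> tuple:
        return (self.donor, self.cell_type, self.stimulation, self.treatment, self.replicate)

    def validate_panel(self, panel: PanelDefinition) -> None:
        missing = [m for m in panel.markers if m not in self.data.columns]
        if missing:
            raise SchemaError(
                f"table {self.condition_key()} missing panel markers: {missing}"
            )

    def with_data(self, data: pd.DataFrame) -> "SingleCellTable":
        return replace(self, data=data)


def feature_name(cell_type: str, marker: str, stimulation: str, stat: str) -> str:
    """Compound feature key ``celltype|marker|stimulation|stat``."""
    return f"{cell_type}|{marker}|{stimulation}|{stat}"


def parse_feature_name(name: str) -> tuple[str, str, str, str]:
    parts = name.split("|")
    if len(parts) != 4:
        raise ValueError(f"not a feature name: {name!r}")
    return tuple(parts)  # type: ignore[return-value]


def write_cell_tables(tables: Iterable[SingleCellTable], path: str | Path) -> Path:
    """Write a collection as one long-format CSV plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames, manifest = [], []
    for i, t in enumerate(tables):
        df = t.data.copy()
        df.insert(0, "donor", t.donor)
        df.insert(1, "cohort", t.cohort)
        df.insert(2, "cell_type", t.cell_type)
        df.insert(3, "stimulation", t.stimulation)
        df.insert(4, "treatment", t.treatment)
        df.insert(5, "replicate", t.replicate)
        frames.append(df)
        manifest.append(
            {
                "donor": t.donor,
                "cohort": t.cohort,
                "cell_type": t.cell_type,
                "stimulation": t.stimulation,
                "treatment": t.treatment,
                "replicate": t.replicate,
                "n_cells": t.n_cells,
            }
        )
    long = pd.concat(frames, axis=0, ignore_index=True)
    long.to_csv(path / "cells.csv", index=False)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_cell_tables(path: str | Path, panel: PanelDefinition | None = None) -> list[SingleCellTable]:
    """Read a collection written by :func:`write_cell_tables`.

    Round-trips values and metadata exactly (up to CSV float formatting,
    written at full precision).
    """
    path = Path(path)
    f = path / "cells.csv" if path.is_dir() else path
    if not f.exists():
        raise FileNotFoundError(f)
    long = pd.read_csv(f)
    missing = [c for c in _META_COLUMNS if c not in long.columns]
    if missing:
        raise SchemaError(f"file {f} missing metadata columns: {missing}")
    marker_cols = [c for c in long.columns if c not in _META_COLUMNS]
    tables = []
    for key, grp in long.groupby(list(_META_COLUMNS), sort=False):
        donor, cohort, cell_type, stimulation, treatment, replicate = key
        t = SingleCellTable(
            data=grp[marker_cols].reset_index(drop=True),
            donor=str(donor),
            cohort=str(cohort),
            cell_type=str(cell_type),
            stimulation=str(stimulation),
            treatment=str(treatment),
            replicate=int(replicate),
        )
        if panel is not None:
            t.validate_panel(panel)
        tables.append(t)
    return tables


def classify_response_strength(
    response: float, stimulation: str, *, threshold: float = 0.1,
    il33_threshold: float = 0.01, absolute: bool = False,
) -> str:
    """Classify a stimulation response as ``"strong"`` or ``"weak"``.

    Strong iff the signed arcsinh difference to unstimulated exceeds 0.1
    (0.01 for IL-33). ``absolute=True`` compares |response| instead.
    """
    thr = il33_threshold if stimulation == "IL-33" else threshold
    value = abs(response) if absolute else response
    return "strong" if value > thr else "weak"


def _sample_key(t: SingleCellTable) -> tuple:
    return (t.donor, t.treatment, t.replicate)


def build_feature_matrix(
    tables: Sequence[SingleCellTable],
    panel: PanelDefinition | None = None,
    markers: Sequence[str] | None = None,
    stimulations: Sequence[str] | None = None,
    cell_types: Sequence[str] | None = None,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Samples-by-features matrix of population medians.

    A sample is a (donor, treatment, replicate) arm. For every
    (cell type, marker) the unstimulated median is a *baseline* feature; for
    every stimulation the stimulated-minus-unstimulated median difference is a
    *response* feature. With a complete grid the feature count is
    ``|cell types| x |markers| x (1 + |stimulations|)``.

    on_missing: ``"error"`` raises on absent conditions; ``"nan"`` records NaN.
    """
    if on_missing not in ("error", "nan"):
        raise ValueError("on_missing must be 'error' or 'nan'")
    tables = list(tables)
    if not tables:
        raise SchemaError("no tables given")
    if panel is not None:
        for t in tables:
            t.validate_panel(panel)
    if markers is None:
        markers = panel.markers if panel is not None else tables[0].markers
    if cell_types is None:
        cell_types = sorted({t.cell_type for t in tables})
    if stimulations is None:
        stimulations = sorted(
            {t.stimulation for t in tables if t.stimulation != UNSTIMULATED}
        )

    med: dict[tuple, pd.Series] = {}
    samples: list[tuple] = []
    for t in tables:
        sk = _sample_key(t)
        if sk not in samples:
            samples.append(sk)
        med[(sk, t.cell_type, t.stimulation)] = t.medians()
    samples = sorted(samples)

    columns = []
    for ct in cell_types:
        for m in markers:
            columns.append(feature_name(ct, m, UNSTIMULATED, "baseline"))
            for s in stimulations:
                columns.append(feature_name(ct, m, s, "response"))

    out = pd.DataFrame(np.nan, index=pd.Index(["|".join(map(str, s)) for s in samples], name="sample"),
                       columns=columns)
    for i, sk in enumerate(samples):
        row = out.index[i]
        for ct in cell_types:
            base = med.get((sk, ct, UNSTIMULATED))
            if base is None:
                if on_missing == "error":
                    raise SchemaError(f"missing unstimulated condition for sample={sk}, cell_type={ct}")
                continue
            for m in markers:
                out.loc[row, feature_name(ct, m, UNSTIMULATED, "baseline")] = base[m]
            for s in stimulations:
                stim = med.get((sk, ct, s))
                if stim is None:
                    if on_missing == "error":
                        raise SchemaError(f"missing condition sample={sk}, cell_type={ct}, stimulation={s}")
                    continue
                for m in markers:
                    out.loc[row, feature_name(ct, m, s, "response")] = stim[m] - base[m]
    return out


def split_feature_index(columns: Iterable[str]) -> pd.DataFrame:
    """Decompose compound feature names into their four components."""
    rows = [parse_feature_name(c) for c in columns]
    return pd.DataFrame(rows, columns=["cell_type", "marker", "stimulation", "stat"],
                        index=list(columns))
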