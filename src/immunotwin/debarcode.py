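"""Doublet-removing choose-k-of-n mass-tag debarcoding.

Each pooled sample is labeled with a unique k-subset of n metal channels
(default 4 of 9, giving C(9,4) = 126 codes). Because the channel union of two
distinct equal-size codes has more than k members, cross-sample doublets show
no gap between the k-th and (k+1)-th brightest barcode channels and are
rejected by the separation threshold. Codes are ranked by isotope purity; the
top m (default 96) are assigned to samples while the remainder monitor the
misassignment rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

UNASSIGNED = "unassigned"


def enumerate_codebook(n: int = 9, k: int = 4) -> list[tuple[int, ...]]:
    """All size-k channel subsets of range(n), in lexicographic order."""
    if not (0 < k < n):
        raise ValueError(f"require 0 < k < n, got n={n}, k={k}")
    return list(combinations(range(n), k))


def code_purity(code: Sequence[int], channel_purities: Sequence[float]) -> float:
    """Aggregate purity of a code: product of its channel purities.

    Isotope impurities act multiplicatively on the fraction of correctly
    tagged events, hence the product.
    """
    p = 1.0
    for c in code:
        p *= float(channel_purities[c])
    return p


def select_codes(
    codebook: Sequence[tuple[int, ...]],
    channel_purities: Sequence[float],
    m: int = 96,
) -> tuple[list[tuple[int, ...]], list[tuple[int, ...]]]:
    """Partition the codebook into the m highest-purity (selected) codes and
    the remainder (monitor set). Ties are broken lexicographically on the
    channel tuple so the partition is deterministic.
    """
    if m > len(codebook):
        raise ValueError(f"m={m} exceeds codebook size {len(codebook)}")
    ranked = sorted(codebook, key=lambda c: (-code_purity(c, channel_purities), c))
    return ranked[:m], ranked[m:]


@dataclass
class BarcodeScheme:
    """A choose-k-of-n codebook with its selected/monitor partition.

    ``channel_purities`` are per-channel isotopic purities in (0, 1]; real
    values are instrument-lot specific, so the shipped default (all 1.0) is a
    placeholder to be overridden from a scheme file.
    """

    n_channels: int = 9
    k: int = 4
    channel_purities: tuple[float, ...] = ()
    n_selected: int = 96
    separation_threshold: float = 0.1
    channel_names: tuple[str, ...] = ()
    codebook: list = field(init=False)
    selected: list = field(init=False)
    monitor: list = field(init=False)

    def __post_init__(self):
        if not (0.0 < self.separation_threshold < 1.0):
            raise ValueError("separation threshold must be in (0, 1)")
        if not self.channel_purities:
            self.channel_purities = (1.0,) * self.n_channels
        if len(self.channel_purities) != self.n_channels:
            raise ValueError("need one purity per channel")
        self.codebook = enumerate_codebook(self.n_channels, self.k)
        self.selected, self.monitor = select_codes(
            self.codebook, self.channel_purities, self.n_selected
        )

    @property
    def n_codes(self) -> int:
        return comb(self.n_channels, self.k)

    def is_selected(self, code: tuple[int, ...]) -> bool:
        return code in set(self.selected)


class Debarcoder(BaseEstimator):
    """Separation-threshold barcode assignment.

    fit() learns per-channel rescaling from the event stream (each channel is
    divided by its ``rescale_percentile``-th percentile over events);
    predict() then normalizes every event by its brightest rescaled channel,
    sorts the channels, computes the separation between the k-th and (k+1)-th
    values, and assigns the top-k channel set when the separation strictly
    exceeds the threshold and the set is a valid code. The per-event
    normalization makes assignment invariant to any common positive rescaling
    of an event's intensities. The threshold is applied on this rescaled
    separation; a raw-separation reading is a plausible alternative, noted in
    the methods documentation.
    """

    def __init__(self, scheme: BarcodeScheme | None = None, rescale_percentile: float = 95.0):
        self.scheme = scheme
        self.rescale_percentile = rescale_percentile

    def fit(self, X, y=None):
        X = self._check(X)
        scale = np.percentile(X, self.rescale_percentile, axis=0)
        scale[scale <= 0] = 1.0
        self.scale_ = scale
        return self

    def _check(self, X) -> np.ndarray:
        scheme = self.scheme or BarcodeScheme()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != scheme.n_channels:
            raise ValueError(
                f"events must have {scheme.n_channels} channels, got shape {X.shape}"
            )
        if not np.all(np.isfinite(X)) or np.any(X < 0):
            raise ValueError("intensities must be finite and >= 0")
        return X

    def _rescaled(self, X) -> np.ndarray:
        if not hasattr(self, "scale_"):
            self.fit(X)
        Z = X / self.scale_
        peak = Z.max(axis=1, keepdims=True)
        peak[peak <= 0] = 1.0
        return Z / peak

    def predict(self, X) -> list:
        """Per-event assignment: a code tuple or ``'unassigned'``."""
        scheme = self.scheme or BarcodeScheme()
        X = self._check(X)
        k = scheme.k
        Z = self._rescaled(X)
        order = np.argsort(-Z, axis=1, kind="stable")
        srt = -np.sort(-Z, axis=1)
        separation = srt[:, k - 1] - srt[:, k]
        valid = set(scheme.codebook)
        out = []
        for i in range(len(Z)):
            if separation[i] > scheme.separation_threshold:
                code = tuple(sorted(order[i, :k]))
                out.append(code if code in valid else UNASSIGNED)
            else:
                out.append(UNASSIGNED)
        return out

    def separations(self, X) -> np.ndarray:
        scheme = self.scheme or BarcodeScheme()
        X = self._check(X)
        Z = self._rescaled(X)
        srt = -np.sort(-Z, axis=1)
        return srt[:, scheme.k - 1] - srt[:, scheme.k]


def assign_events(events, scheme: BarcodeScheme) -> list:
    """Fit-and-predict convenience wrapper around :class:`Debarcoder`."""
    return Debarcoder(scheme).fit(events).predict(events)


def assignment_summary(assignments: Sequence, scheme: BarcodeScheme) -> dict:
    n = len(assignments)
    selected = set(scheme.selected)
    monitor = set(scheme.monitor)
    n_sel = sum(1 for a in assignments if a in selected)
    n_mon = sum(1 for a in assignments if a in monitor)
    assigned = n_sel + n_mon
    return {
        "n_events": n,
        "n_assigned": assigned,
        "assignment_rate": assigned / n if n else float("nan"),
        "n_selected": n_sel,
        "n_monitor": n_mon,
    }


def misassignment_rate(assignments: Sequence, scheme: BarcodeScheme) -> float:
    """Fraction of *assigned* events landing in monitor codes.

    Undefined (NaN) when no event was assigned.
    """
    s = assignment_summary(assignments, scheme)
    if s["n_assigned"] == 0:
        return float("nan")
    return s["n_monitor"] / s["n_assigned"]


def debarcode_table(events, scheme: BarcodeScheme) -> pd.DataFrame:
    """Events with their assignment and separation, for export."""
    db = Debarcoder(scheme).fit(events)
    assign = db.predict(events)
    sep = db.separations(events)
    return pd.DataFrame(
        {
            "assignment": ["+".join(map(str, a)) if a != UNASSIGNED else a for a in assign],
            "separation": sep,
            "in_monitor": [a in set(scheme.monitor) for a in assign],
        }
    )
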