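"""Entropy-weight composite scoring of regional indicator panels.

The entropy weight method assigns objective indicator weights from data
dispersion: an indicator whose column varies more across regions carries
lower information entropy and therefore a larger weight.  Scores are the
weight-averaged min-max standardized indicator values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class IndicatorPanel:
    """A regions x indicators nonnegative value matrix for one cross-section.

    Parameters
    ----------
    values : (n, m) array of nonnegative floats.
    region_ids : n unique region labels, in file order.
    indicator_ids : m indicator column names.
    year : optional year tag.
    """

    values: np.ndarray
    region_ids: list[str]
    indicator_ids: list[str]
    year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = list(self.region_ids)
        self.indicator_ids = list(self.indicator_ids)
        self.validate()

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("panel values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 2:
            raise ValueError(f"panel needs at least 2 regions, got {n}")
        if m < 1:
            raise ValueError("panel needs at least 1 indicator")
        if len(self.region_ids) != n:
            raise ValueError("region_ids length does not match row count")
        if len(self.indicator_ids) != m:
            raise ValueError("indicator_ids length does not match column count")
        if len(set(self.region_ids)) != n:
            dupes = sorted({r for r in self.region_ids if self.region_ids.count(r) > 1})
            raise ValueError(f"duplicate region ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite cell at region {self.region_ids[bad[0]]!r}, "
                f"indicator {self.indicator_ids[bad[1]]!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative cell at region {self.region_ids[bad[0]]!r}, "
                f"indicator {self.indicator_ids[bad[1]]!r}"
            )


@dataclass
class CapacityResult:
    """Weights, entropies and composite capacity scores for one panel."""

    weights: np.ndarray
    entropies: np.ndarray
    diff_coeffs: np.ndarray
    scores: np.ndarray
    standardized: np.ndarray
    region_ids: list[str] = field(default_factory=list)
    indicator_ids: list[str] = field(default_factory=list)
    year: int | None = None

    def to_dict(self) -> dict:
        return {
            "year": self.year,
            "weights": dict(zip(self.indicator_ids, map(float, self.weights))),
            "entropies": dict(zip(self.indicator_ids, map(float, self.entropies))),
            "diff_coeffs": dict(zip(self.indicator_ids, map(float, self.diff_coeffs))),
            "scores": dict(zip(self.region_ids, map(float, self.scores))),
        }


def standardize_minmax(panel: IndicatorPanel | np.ndarray) -> np.ndarray:
    """Column-wise min-max standardization onto [0, 1].

    A constant column (max == min) maps to all zeros: it carries no
    discriminating information.
    """
    x = panel.values if isinstance(panel, IndicatorPanel) else np.asarray(panel, dtype=float)
    cmin = x.min(axis=0)
    cmax = x.max(axis=0)
    span = cmax - cmin
    out = np.zeros_like(x)
    ok = span > 0
    out[:, ok] = (x[:, ok] - cmin[ok]) / span[ok]
    return out


def column_proportions(std_matrix: np.ndarray) -> np.ndarray:
    """Normalize each column to sum to 1; an all-zero column stays zero."""
    x = np.asarray(std_matrix, dtype=float)
    if np.any(x < 0):
        raise ValueError("proportions require a nonnegative matrix")
    sums = x.sum(axis=0)
    y = np.zeros_like(x)
    ok = sums > 0
    y[:, ok] = x[:, ok] / sums[ok]
    return y


def entropy(y_column: np.ndarray, n: int) -> float:
    """Information entropy of one proportion column, scaled by k = 1/ln(n).

    The 0*ln(0) terms are taken as 0 (continuity limit).  An all-zero
    column (no information) is assigned entropy 1.
    """
    if n < 2:
        raise ValueError("entropy scaling k = 1/ln(n) needs n >= 2")
    y = np.asarray(y_column, dtype=float)
    if np.any(y < 0):
        raise ValueError("proportions must be nonnegative")
    if y.sum() == 0:
        return 1.0
    k = 1.0 / np.log(n)
    pos = y > 0
    e = -k * float(np.sum(y[pos] * np.log(y[pos])))
    # guard tiny float overshoot above 1 for near-uniform columns
    return float(min(max(e, 0.0), 1.0))


def weights_from_entropy(e: np.ndarray) -> np.ndarray:
    """Weights proportional to the difference coefficients g_j = 1 - e_j."""
    e = np.asarray(e, dtype=float)
    g = 1.0 - e
    total = g.sum()
    if total <= 0:
        raise ValueError("no discriminating indicator: all entropies equal 1")
    return g / total


def capacity_scores(std_matrix: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Composite score per region: weighted sum of standardized indicators."""
    x = np.asarray(std_matrix, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape[1] != w.shape[0]:
        raise ValueError(
            f"dimension mismatch: {x.shape[1]} columns vs {w.shape[0]} weights"
        )
    return x @ w


def score_panel(panel: IndicatorPanel) -> CapacityResult:
    """Run the full entropy-weight pipeline on one panel.

    Standardize, normalize columns to proportions, compute per-indicator
    entropy and weights, and combine into per-region capacity scores.
    """
    std = standardize_minmax(panel)
    y = column_proportions(std)
    n = panel.n_regions
    e = np.array([entropy(y[:, j], n) for j in range(panel.n_indicators)])
    w = weights_from_entropy(e)
    scores = capacity_scores(std, w)
    return CapacityResult(
        weights=w,
        entropies=e,
        diff_coeffs=1.0 - e,
        scores=scores,
        standardized=std,
        region_ids=panel.region_ids,
        indicator_ids=panel.indicator_ids,
        year=panel.year,
    )
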