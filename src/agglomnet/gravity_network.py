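"""Gravity-model interaction matrices and mean-threshold binarization.

The modified gravity model scores the directed pull of region ``e`` on
region ``f`` from population, GDP, composite capacity, the per-capita-GDP
gap, and geographic distance.  Thresholding each row of the resulting
matrix at its mean yields a directed binary spatial-correlation network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BINARIZE_RULES = ("row_mean", "col_mean", "grand_mean")


@dataclass
class GravityMatrix:
    """Real-valued directed interaction matrix with its capacity-share factor.

    ``lam[e, f]`` is region e's share of the combined capacity of e and f,
    so ``lam + lam.T`` is 1 on every off-diagonal cell.
    """

    values: np.ndarray
    lam: np.ndarray
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        n = len(self.region_ids)
        if self.values.shape != (n, n):
            raise ValueError("gravity matrix shape does not match region count")
        if np.any(self.values < 0):
            raise ValueError("gravity values must be nonnegative")


@dataclass
class SpatialNetwork:
    """Directed binary adjacency over labelled regions (no self-ties)."""

    adjacency: np.ndarray
    region_ids: list[str]
    year: int | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        self.region_ids = list(self.region_ids)
        self.validate()
        self.adjacency = self.adjacency.astype(int)

    @property
    def n(self) -> int:
        return len(self.region_ids)

    def validate(self) -> None:
        a = self.adjacency
        n = len(self.region_ids)
        if a.shape != (n, n):
            raise ValueError("adjacency shape does not match region count")
        if len(set(self.region_ids)) != n:
            raise ValueError("duplicate region ids")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-ties are not allowed")


def _check_distance(D: np.ndarray, n: int) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match region count")
    off = ~np.eye(n, dtype=bool)
    if np.any(D[off] <= 0):
        raise ValueError("off-diagonal distances must be strictly positive")
    return D


def traditional_gravity(
    P: np.ndarray, G: np.ndarray, D: np.ndarray, lam: float = 1.0
) -> np.ndarray:
    """Classic inverse-square gravity: lam * Pe*Ge*Pf*Gf / D**2.

    Symmetric; provided for comparison with the modified model only.
    """
    P = np.asarray(P, dtype=float)
    G = np.asarray(G, dtype=float)
    n = P.shape[0]
    if np.any(P <= 0) or np.any(G <= 0):
        raise ValueError("population and GDP must be strictly positive")
    D = _check_distance(D, n)
    mass = P * G
    X = lam * np.outer(mass, mass)
    off = ~np.eye(n, dtype=bool)
    out = np.zeros((n, n))
    out[off] = X[off] / D[off] ** 2
    return out


def modified_gravity(
    P: np.ndarray,
    G: np.ndarray,
    g: np.ndarray,
    N: np.ndarray,
    D: np.ndarray,
    gap_floor_scale: float = 1e-9,
) -> GravityMatrix:
    """Capacity-share gravity with per-capita-GDP economic distance.

    X[e, f] = N_e/(N_e+N_f) * (P_e N_e G_e)^(1/3) * (P_f N_f G_f)^(1/3)
              * |g_e - g_f| / D[e, f]

    The per-capita-GDP gap is floored at ``gap_floor_scale * mean(g)`` so
    that exactly equal per-capita GDPs (possible in synthetic data) do not
    silently annihilate a cell.
    """
    P, G, g, N = (np.asarray(v, dtype=float) for v in (P, G, g, N))
    n = P.shape[0]
    for name, v in (("population", P), ("GDP", G), ("per-capita GDP", g), ("capacity", N)):
        if v.shape != (n,):
            raise ValueError(f"{name} vector has wrong length")
        if np.any(v <= 0):
            raise ValueError(f"{name} must be strictly positive")
    D = _check_distance(D, n)

    lam = N[:, None] / (N[:, None] + N[None, :])
    np.fill_diagonal(lam, 0.0)
    mass = np.cbrt(P * N * G)
    gap = np.abs(g[:, None] - g[None, :])
    floor = gap_floor_scale * float(g.mean())
    gap = np.maximum(gap, floor)

    X = np.zeros((n, n))
    off = ~np.eye(n, dtype=bool)
    masses = np.outer(mass, mass)
    X[off] = lam[off] * masses[off] * gap[off] / D[off]
    region_ids = [f"r{i}" for i in range(n)]
    return GravityMatrix(values=X, lam=lam, region_ids=region_ids)


def binarize(
    X: GravityMatrix | np.ndarray,
    rule: str = "row_mean",
    region_ids: list[str] | None = None,
    year: int | None = None,
) -> SpatialNetwork:
    """Threshold a gravity matrix at the chosen mean critical point.

    A cell becomes a directed tie when it is greater than or equal to the
    critical value of its row (default), column, or the whole matrix.
    Means are taken over off-diagonal cells; the structural zero diagonal
    is excluded.  Zero cells never become ties, so an all-zero matrix
    yields an empty network.
    """
    if isinstance(X, GravityMatrix):
        values = X.values
        ids = region_ids or X.region_ids
    else:
        values = np.asarray(X, dtype=float)
        ids = region_ids or [f"r{i}" for i in range(values.shape[0])]
    if rule not in BINARIZE_RULES:
        raise ValueError(f"unknown binarization rule {rule!r}; choose from {BINARIZE_RULES}")
    if np.any(values < 0):
        raise ValueError("gravity matrix must be nonnegative")
    n = values.shape[0]
    off = ~np.eye(n, dtype=bool)

    if rule == "row_mean":
        crit = (values.sum(axis=1) / (n - 1))[:, None] * np.ones((1, n))
    elif rule == "col_mean":
        crit = (values.sum(axis=0) / (n - 1))[None, :] * np.ones((n, 1))
    else:  # grand_mean
        crit = np.full((n, n), values[off].mean())

    adj = ((values >= crit) & (values > 0) & off).astype(int)
    return SpatialNetwork(adjacency=adj, region_ids=ids, year=year)
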