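"""Readers/writers for the delimited-text artifacts and run configuration.

All matrices are stored as labelled CSV (header row and index column of
region ids); edge lists as TSV; reports as JSON.  Regions are ordered by
first appearance in the panel file and every matrix shares that order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .entropy_scoring import IndicatorPanel
from .gravity_network import SpatialNetwork


@dataclass
class RegionTable:
    """Per-region metadata: population P, GDP G, per-capita GDP g."""

    region_ids: list[str]
    region_names: list[str]
    population: np.ndarray
    gdp: np.ndarray
    gdp_per_capita: np.ndarray
    x_coord: np.ndarray | None = None
    y_coord: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=float)
        self.gdp = np.asarray(self.gdp, dtype=float)
        self.gdp_per_capita = np.asarray(self.gdp_per_capita, dtype=float)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.region_ids)

    def validate(self) -> None:
        n = len(self.region_ids)
        if len(set(self.region_ids)) != n:
            raise ValueError("duplicate region ids")
        for name, v in (
            ("population", self.population),
            ("gdp", self.gdp),
            ("gdp_per_capita", self.gdp_per_capita),
        ):
            if v.shape != (n,):
                raise ValueError(f"{name} has wrong length")
            if np.any(v <= 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive and finite")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "region_name": self.region_names,
            "population": self.population,
            "gdp": self.gdp,
            "gdp_per_capita": self.gdp_per_capita,
        }
        if self.x_coord is not None:
            data["x_coord"] = self.x_coord
            data["y_coord"] = self.y_coord
        df = pd.DataFrame(data, index=pd.Index(self.region_ids, name="region_id"))
        return df


@dataclass
class DistanceMatrix:
    """Symmetric geographic distance matrix with zero diagonal."""

    values: np.ndarray
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.region_ids)
        v = self.values
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match region count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 0):
            raise ValueError("distance matrix diagonal must be zero")
        off = ~np.eye(n, dtype=bool)
        if np.any(v[off] <= 0):
            raise ValueError("off-diagonal distances must be strictly positive")


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    years: list[int] | None = None
    binarize_rule: str = "row_mean"
    concor_depth: int = 2
    concor_tolerance: float = 0.2
    role_margin: float = 1.5
    qap_permutations: int = 8000
    seed: int = 0
    weight_mode: str = "per_year"  # or "pooled"
    log_covariates: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.qap_permutations < 1:
            raise ValueError("qap_permutations must be >= 1")
        if self.concor_depth < 1:
            raise ValueError("concor_depth must be >= 1")
        if self.weight_mode not in ("per_year", "pooled"):
            raise ValueError("weight_mode must be 'per_year' or 'pooled'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------- readers

def _read_labelled_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing + %.17g writing give bit-exact matrix round-trips
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return df


def read_indicator_panel(path: str | Path, year: int | None = None) -> IndicatorPanel:
    """Read a region x indicator CSV (region_id index column + header)."""
    df = _read_labelled_csv(path)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no indicator columns found")
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate region rows {dupes}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna()][0]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return IndicatorPanel(
        values=values,
        region_ids=list(df.index),
        indicator_ids=list(df.columns),
        year=year,
    )


def read_region_table(path: str | Path) -> RegionTable:
    df = _read_labelled_csv(path)
    required = {"population", "gdp", "gdp_per_capita"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    names = (
        df["region_name"].astype(str).tolist()
        if "region_name" in df.columns
        else list(df.index)
    )
    has_xy = "x_coord" in df.columns and "y_coord" in df.columns
    return RegionTable(
        region_ids=list(df.index),
        region_names=names,
        population=df["population"].to_numpy(dtype=float),
        gdp=df["gdp"].to_numpy(dtype=float),
        gdp_per_capita=df["gdp_per_capita"].to_numpy(dtype=float),
        x_coord=df["x_coord"].to_numpy(dtype=float) if has_xy else None,
        y_coord=df["y_coord"].to_numpy(dtype=float) if has_xy else None,
    )


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = _read_labelled_csv(path)
    if list(df.index) != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column labels differ")
    return DistanceMatrix(values=df.to_numpy(dtype=float), region_ids=list(df.index))


def read_adjacency(path: str | Path, year: int | None = None) -> SpatialNetwork:
    df = _read_labelled_csv(path)
    if list(df.index) != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column labels differ")
    return SpatialNetwork(
        adjacency=df.to_numpy(dtype=int), region_ids=list(df.index), year=year
    )


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Region x factor CSV of covariate node values."""
    return _read_labelled_csv(path)


# ---------------------------------------------------------------- writers

def write_matrix(values: np.ndarray, region_ids: list[str], path: str | Path) -> None:
    # %.17g round-trips IEEE doubles exactly through text
    pd.DataFrame(values, index=region_ids, columns=region_ids).to_csv(
        path, float_format="%.17g"
    )


def write_adjacency(net: SpatialNetwork, path: str | Path) -> None:
    write_matrix(net.adjacency, net.region_ids, path)


def write_distance_matrix(dist: DistanceMatrix, path: str | Path) -> None:
    write_matrix(dist.values, dist.region_ids, path)


def write_edge_list(net: SpatialNetwork, path: str | Path, weights: np.ndarray | None = None) -> None:
    """One 'source TAB target TAB weight' line per directed tie."""
    with open(path, "w") as fh:
        for i, src in enumerate(net.region_ids):
            for j, dst in enumerate(net.region_ids):
                if net.adjacency[i, j]:
                    w = weights[i, j] if weights is not None else 1
                    fh.write(f"{src}\t{dst}\t{w}\n")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_report(results: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, cls=_NumpyEncoder)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
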