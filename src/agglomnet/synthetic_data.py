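"""Synthetic study inputs: regions, indicator panels, distances, covariates.

The generator plants an east-to-west capacity gradient on a plane:
latent capacity, population and GDP all rise with the eastward coordinate,
indicators are noisy multiples of latent capacity, and distances are
Euclidean.  Covariates can be tied to latent capacity with a controllable
strength, and block structure can be planted in the gravity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy_scoring import IndicatorPanel, score_panel
from .gravity_network import SpatialNetwork, binarize, modified_gravity
from .io_config import (
    DistanceMatrix,
    RegionTable,
    write_distance_matrix,
    write_matrix,
)
from .qap_analysis import QAP_FACTORS

DEFAULT_YEARS = tuple(range(2004, 2019))


@dataclass
class SyntheticSpec:
    n_regions: int = 31
    n_indicators: int = 10
    years: tuple[int, ...] = DEFAULT_YEARS
    gradient_strength: float = 1.0
    noise_sd: float = 0.3
    block_plant: tuple[int, ...] | None = None  # e.g. (8, 7, 7, 9)
    block_boost: float = 100.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 4:
            raise ValueError("need at least 4 regions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.block_plant is not None and sum(self.block_plant) != self.n_regions:
            raise ValueError(
                f"planted block sizes {self.block_plant} do not sum to "
                f"{self.n_regions} regions"
            )
        bad = set(self.covariate_effects) - set(QAP_FACTORS)
        if bad:
            raise ValueError(f"unknown covariate factors: {sorted(bad)}")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    regions: RegionTable
    panels: dict[int, IndicatorPanel]
    distances: DistanceMatrix
    covariates: pd.DataFrame
    latent_capacity: np.ndarray
    block_labels: np.ndarray | None = None  # 1-based planted block per region

    def to_dir(self, path: str | Path) -> None:
        """Write all artifacts as the CSV dialects the readers consume."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        self.regions.to_frame().to_csv(out / "regions.csv")
        write_distance_matrix(self.distances, out / "distances.csv")
        self.covariates.to_csv(out / "covariates.csv")
        for year, panel in self.panels.items():
            df = pd.DataFrame(
                panel.values,
                index=pd.Index(panel.region_ids, name="region_id"),
                columns=panel.indicator_ids,
            )
            df.to_csv(out / f"panel_{year}.csv")


def _mix(signal: np.ndarray, noise: np.ndarray, strength: float) -> np.ndarray:
    """Standardized mixture with correlation ~strength to the signal."""
    zs = (signal - signal.mean()) / (signal.std() or 1.0)
    zn = (noise - noise.mean()) / (noise.std() or 1.0)
    rho = float(np.clip(strength, 0.0, 1.0))
    return rho * zs + np.sqrt(1.0 - rho**2) * zn


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a full synthetic dataset, reproducible from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_regions, spec.n_indicators

    x = rng.uniform(0.0, 1.0, n)  # eastward coordinate
    y = rng.uniform(0.0, 1.0, n)
    log_capacity = spec.gradient_strength * x + spec.noise_sd * rng.standard_normal(n)
    capacity = np.exp(log_capacity)

    population = np.exp(15.0 + 0.8 * x + 0.3 * rng.standard_normal(n))
    gdp = np.exp(16.5 + 1.2 * x + 0.4 * rng.standard_normal(n))
    gdp_pc = gdp / population

    region_ids = [f"R{i+1:02d}" for i in range(n)]
    regions = RegionTable(
        region_ids=region_ids,
        region_names=[f"Region {i+1}" for i in range(n)],
        population=population,
        gdp=gdp,
        gdp_per_capita=gdp_pc,
        x_coord=x,
        y_coord=y,
    )

    coords = np.column_stack([x, y]) * 1000.0  # km-ish scale
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, 0.0)
    distances = DistanceMatrix(values=dist, region_ids=region_ids)

    loadings = np.exp(0.5 * rng.standard_normal(m))
    indicator_ids = [f"ind{j+1:02d}" for j in range(m)]
    panels: dict[int, IndicatorPanel] = {}
    for k, year in enumerate(spec.years):
        trend = 1.0 + 0.04 * k
        noise = np.exp(spec.noise_sd * rng.standard_normal((n, m)))
        values = trend * capacity[:, None] * loadings[None, :] * noise
        panels[year] = IndicatorPanel(
            values=values,
            region_ids=region_ids,
            indicator_ids=indicator_ids,
            year=year,
        )

    covariates = _make_covariates(spec, rng, regions, np.log(gdp_pc), region_ids)

    block_labels = None
    if spec.block_plant is not None:
        block_labels = np.concatenate(
            [np.full(s, b + 1, dtype=int) for b, s in enumerate(spec.block_plant)]
        )

    return SyntheticDataset(
        spec=spec,
        regions=regions,
        panels=panels,
        distances=distances,
        covariates=covariates,
        latent_capacity=capacity,
        block_labels=block_labels,
    )


def _make_covariates(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    regions: RegionTable,
    signal: np.ndarray,
    region_ids: list[str],
) -> pd.DataFrame:
    """Six positive covariates with configurable link to the network driver.

    The gravity network's strongest dyadic driver is the per-capita-GDP
    gap, so requested effects mix the covariate with log per-capita GDP.
    PGDP and Pop default to the generated region economics; the rest
    default to independent noise unless an effect strength is requested.
    """
    cols: dict[str, np.ndarray] = {}
    scales = {"PGDP": 10.0, "Pop": 15.0, "Urb": 4.0, "Stu": 12.0, "Wag": 10.5, "Exp": 13.0}
    for factor in QAP_FACTORS:
        if factor in spec.covariate_effects:
            z = _mix(signal, rng.standard_normal(len(region_ids)),
                     spec.covariate_effects[factor])
            cols[factor] = np.exp(scales[factor] * 0.1 + 0.5 * z)
        elif factor == "PGDP":
            cols[factor] = regions.gdp_per_capita
        elif factor == "Pop":
            cols[factor] = regions.population
        else:
            cols[factor] = np.exp(
                scales[factor] * 0.1 + 0.5 * rng.standard_normal(len(region_ids))
            )
    return pd.DataFrame(cols, index=pd.Index(region_ids, name="region_id"))


def plant_network_effect(
    spec: SyntheticSpec, factor: str, strength: float
) -> pd.DataFrame:
    """Covariate table where only ``factor`` is tied to the network driver.

    The named factor's node values mix log per-capita GDP (the gravity
    network's dominant dyadic driver) and noise at the requested
    strength; every other factor is independent noise, giving a clean
    planted-vs-null contrast for QAP power and calibration checks.
    """
    if factor not in QAP_FACTORS:
        raise ValueError(f"unknown factor {factor!r}; choose from {QAP_FACTORS}")
    ds = generate(spec)
    rng = np.random.default_rng(spec.seed + 10_000)
    n = spec.n_regions
    signal = np.log(ds.regions.gdp_per_capita)
    cols = {}
    for name in QAP_FACTORS:
        s = strength if name == factor else 0.0
        z = _mix(signal, rng.standard_normal(n), s)
        cols[name] = np.exp(0.5 * z)
    return pd.DataFrame(cols, index=pd.Index(ds.regions.region_ids, name="region_id"))


def capacity_vector(dataset: SyntheticDataset, year: int | None = None) -> np.ndarray:
    """Entropy-weight capacity scores for one year, floored away from zero."""
    years = sorted(dataset.panels)
    panel = dataset.panels[year if year is not None else years[-1]]
    scores = score_panel(panel).scores
    return np.maximum(scores, 1e-6)


def generate_planted_network(
    spec: SyntheticSpec, year: int | None = None
) -> tuple[SpatialNetwork, np.ndarray]:
    """Build the gravity network with planted intra-block boost.

    Multiplies intra-block gravity cells by ``spec.block_boost`` before
    row-mean binarization, so the planted blocks dominate each row's
    critical point.  The plant is hierarchical: cells between consecutive
    block pairs get the square root of the boost, matching the divisive
    two-way structure a correlation blockmodel recovers.  Returns the
    network and the 1-based planted labels.
    """
    if spec.block_plant is None:
        raise ValueError("spec.block_plant must be set to plant a network")
    ds = generate(spec)
    N = capacity_vector(ds, year)
    gm = modified_gravity(
        ds.regions.population,
        ds.regions.gdp,
        ds.regions.gdp_per_capita,
        N,
        ds.distances.values,
    )
    X = gm.values.copy()
    labels = ds.block_labels
    same = labels[:, None] == labels[None, :]
    super_labels = (labels - 1) // 2  # consecutive blocks pair into super-groups
    same_super = super_labels[:, None] == super_labels[None, :]
    X[same_super] *= np.sqrt(spec.block_boost)
    X[same] *= spec.block_boost / np.sqrt(spec.block_boost)
    np.fill_diagonal(X, 0.0)
    net = binarize(X, rule="row_mean", region_ids=ds.regions.region_ids)
    return net, labels
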