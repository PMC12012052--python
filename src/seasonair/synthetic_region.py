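"""Synthetic study region with planted, recorded parameters.

Generates everything the downstream pipeline consumes — four seasonal
concentration rasters per pollutant, a road mask, a land-cover grid, and a
sector table with population, degree of urbanisation, deprivation decile,
accessibility score and car ownership — from one declarative
:class:`RegionSpec`, so every analysis stage has a ground truth to recover.

Concentration model (before noise)::

    conc(cell, season) = f_s * bg_winter + g_s * inc_winter * exp(-d / L)

where ``d`` is the distance (cells) to the nearest road cell and ``L`` the
decay scale. Winter has ``f = g = 1``; spring and autumn scale both terms by
a per-season factor (so their ratio to winter is that factor everywhere);
for summer ``f`` and ``g`` are solved so that the cellwise summer/winter
ratio equals ``planted_ratio_road`` exactly on road cells and
``planted_ratio_background`` in the far field. Winter background exceeds the
summer background by construction, matching the winter-dominated seasonality
of both pollutants.

Urban deprivation enters NO2 as an additive term
``slope * (10 - decile)`` on the non-road cells of urban sectors, scaled per
season by the background profile so it leaves summer/winter ratios intact.

Randomness: one master seed; each stochastic component draws from its own
``default_rng([seed, k])`` substream (k = 1 field noise, 2 sector merges,
3 deprivation jitter, 4 population, 5 accessibility scores, 6 car-ownership
noise), so fields and sectors are individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import (
    POLLUTANTS,
    SEASONS,
    GridMeta,
    SeasonalField,
    SectorFrame,
)

#: smallest concentration the generator will emit (ug/m3)
CONCENTRATION_FLOOR = 0.1

LANDCOVER_CLASSES = (
    "urban_fabric",
    "road_rail",
    "industry",
    "arable",
    "pasture",
    "forest",
)


def default_road_cells(grid_shape: tuple[int, int]) -> frozenset[tuple[int, int]]:
    """Two crossing road lines: one horizontal, one vertical."""
    rows, cols = grid_shape
    r0, c0 = rows // 3, cols // 3
    cells = {(r0, c) for c in range(cols)} | {(r, c0) for r in range(rows)}
    return frozenset(cells)


@dataclass(frozen=True)
class RegionSpec:
    """Declarative description of a synthetic study region.

    Concentration defaults are loosely anchored to Belgian winter levels
    (NO2 backgrounds around 20 ug/m3 with road increments of ~15 at source;
    PM2.5 around 14 with a ~3 road increment) and to observed summer/winter
    ratios: near 0.78 on road cells vs ~0.46 in the NO2 background, and a
    much flatter 0.56 vs 0.51 contrast for PM2.5.
    """

    grid_shape: tuple[int, int] = (60, 80)
    cell_size: float = 10.0
    road_cells: frozenset[tuple[int, int]] | None = None
    n_sectors: int = 48
    background_winter: dict = dfield(
        default_factory=lambda: {"NO2": 20.0, "PM25": 14.0}
    )
    road_increment_winter: dict = dfield(
        default_factory=lambda: {"NO2": 15.0, "PM25": 3.0}
    )
    season_factors: dict = dfield(
        default_factory=lambda: {"spring": 0.75, "autumn": 0.70}
    )
    decay_scale: float = 3.0
    planted_ratio_road: dict = dfield(
        default_factory=lambda: {"NO2": 0.78, "PM25": 0.56}
    )
    planted_ratio_background: dict = dfield(
        default_factory=lambda: {"NO2": 0.46, "PM25": 0.51}
    )
    deprivation_no2_slope: float = 0.8
    mobiscore_changepoint: float = 8.0
    cars_plateau: float = 1.1
    cars_post_slope: float = -0.4
    cars_noise_sd: float = 0.05
    noise_sd: float = 0.5
    population_mean: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.road_cells is None:
            object.__setattr__(self, "road_cells", default_road_cells(self.grid_shape))
        if not self.road_cells:
            raise ValueError("road_cells must not be empty")
        for r, c in self.road_cells:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"road cell ({r}, {c}) outside the {rows}x{cols} grid")
        if self.n_sectors < 2:
            raise ValueError("n_sectors must be >= 2")
        if self.n_sectors > rows * cols:
            raise ValueError("n_sectors exceeds the number of grid cells")
        if self.decay_scale <= 0:
            raise ValueError("decay_scale must be > 0")
        for p in POLLUTANTS:
            if self.planted_ratio_road[p] <= self.planted_ratio_background[p]:
                raise ValueError(
                    f"{p}: planted road ratio must exceed the background ratio"
                )
            if self.planted_ratio_background[p] >= 1.0:
                raise ValueError(
                    f"{p}: background summer/winter ratio must be < 1 "
                    "(winter background exceeds summer background)"
                )
            if self.background_winter[p] <= 0 or self.road_increment_winter[p] <= 0:
                raise ValueError(f"{p}: concentration parameters must be > 0")
            # summer road increment implied by the planted ratios must be positive
            if self._summer_coeffs(p)[1] <= 0:
                raise ValueError(
                    f"{p}: planted ratios imply a non-positive summer road increment"
                )
        if self.noise_sd < 0 or self.cars_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def _summer_coeffs(self, pollutant: str) -> tuple[float, float]:
        """(f_summer, g_summer): background and increment multipliers for summer."""
        bg = self.background_winter[pollutant]
        inc = self.road_increment_winter[pollutant]
        r_bg = self.planted_ratio_background[pollutant]
        r_road = self.planted_ratio_road[pollutant]
        f = r_bg
        g = (r_road * (bg + inc) - r_bg * bg) / inc
        return f, g

    def season_coeffs(self, pollutant: str, season: str) -> tuple[float, float]:
        """(f_s, g_s): multipliers of winter background and road increment."""
        if season == "winter":
            return 1.0, 1.0
        if season == "summer":
            return self._summer_coeffs(pollutant)
        f = self.season_factors[season]
        return f, f

    @property
    def meta(self) -> GridMeta:
        rows, cols = self.grid_shape
        return GridMeta(
            rows=rows, cols=cols,
            x_origin=0.0, y_origin=rows * self.cell_size,
            cell_size=self.cell_size,
        )


# ---------------------------------------------------------------------------
# deterministic spatial scaffolding shared by fields and sectors
# ---------------------------------------------------------------------------

def road_mask(spec: RegionSpec) -> np.ndarray:
    rows, cols = spec.grid_shape
    mask = np.zeros((rows, cols), dtype=bool)
    for r, c in spec.road_cells:
        mask[r, c] = True
    return mask


def distance_cells(spec: RegionSpec) -> np.ndarray:
    """Distance (cell units) from each cell center to the nearest road cell."""
    return ndimage.distance_transform_edt(~road_mask(spec))


def _tile_partition(spec: RegionSpec) -> np.ndarray:
    """Rectangular tiling perturbed by random merges; returns a sector-id grid."""
    rows, cols = spec.grid_shape
    n = spec.n_sectors
    a = max(1, min(rows, round(np.sqrt(n * rows / cols))))
    b = int(np.ceil(n / a))
    if b > cols:
        b = cols
        a = int(np.ceil(n / b))
    if a > rows:  # rows*cols >= n is guaranteed, so this split always exists
        a = rows
        b = int(np.ceil(n / a))
    row_bands = np.array_split(np.arange(rows), a)
    col_bands = np.array_split(np.arange(cols), b)
    tile = np.empty((rows, cols), dtype=int)
    for i, rb in enumerate(row_bands):
        for j, cb in enumerate(col_bands):
            tile[np.ix_(rb, cb)] = i * b + j

    # union-find over tiles; merge random adjacent tiles down to n sectors
    rng = np.random.default_rng([spec.seed, 2])
    parent = list(range(a * b))

    def find(t: int) -> int:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    n_groups = a * b
    while n_groups > n:
        i = int(rng.integers(a))
        j = int(rng.integers(b))
        neighbours = []
        if i > 0:
            neighbours.append((i - 1) * b + j)
        if i < a - 1:
            neighbours.append((i + 1) * b + j)
        if j > 0:
            neighbours.append(i * b + j - 1)
        if j < b - 1:
            neighbours.append(i * b + j + 1)
        other = neighbours[int(rng.integers(len(neighbours)))]
        ra, rb_ = find(i * b + j), find(other)
        if ra != rb_:
            parent[rb_] = ra
            n_groups -= 1

    grouped = np.array([find(t) for t in range(a * b)])[tile]
    # relabel 0..n-1 in order of first appearance (row-major) for determinism
    _, first = np.unique(grouped, return_index=True)
    order = grouped.ravel()[np.sort(first)]
    remap = {int(g): i for i, g in enumerate(order)}
    return np.vectorize(remap.get)(grouped)


def _sector_structure(spec: RegionSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Sector ids with mean road distance, DEGURBA class and deprivation decile.

    Deterministic given the spec (substreams [seed, 2] and [seed, 3]).
    """
    labels = _tile_partition(spec)
    dist = distance_cells(spec)
    d_max = dist.max() if dist.max() > 0 else 1.0
    n = spec.n_sectors
    mean_dist = np.array([dist[labels == s].mean() for s in range(n)]) / d_max

    # DEGURBA by road-distance tertile: 1 = city (closest), 3 = rural
    order = np.argsort(mean_dist, kind="stable")
    degurba = np.empty(n, dtype=int)
    thirds = np.array_split(order, 3)
    for k, idx in enumerate(thirds):
        degurba[idx] = k + 1

    # latent deprivation score; ranked into global deciles (1 = most deprived).
    # Urban sectors: deprived sectors sit closest to roads; rural sectors:
    # the least deprived sit closest (hence exposed to higher NO2).
    rng = np.random.default_rng([spec.seed, 3])
    latent = np.where(
        degurba == 1, mean_dist, np.where(degurba == 3, 1.0 - mean_dist, 0.5)
    )
    latent = latent + rng.normal(0.0, 1e-3, size=n)
    rank = np.empty(n, dtype=int)
    rank[np.argsort(latent, kind="stable")] = np.arange(n)
    decile = 1 + (rank * 10) // n

    return pd.DataFrame(
        {
            "sector_id": np.arange(n),
            "mean_dist_norm": mean_dist,
            "degurba": degurba,
            "bimd_decile": decile,
        }
    ), labels


def landcover_grid(spec: RegionSpec) -> tuple[np.ndarray, dict[int, str]]:
    """Per-cell land-cover class on a reduced 6-class palette."""
    struct, labels = _sector_structure(spec)
    dist = distance_cells(spec)
    lc = np.empty(spec.grid_shape, dtype=int)
    names = {i: name for i, name in enumerate(LANDCOVER_CLASSES)}
    inv = {name: i for i, name in names.items()}
    sector_mod = labels % 3
    lc[:] = inv["forest"]
    lc[sector_mod == 0] = inv["arable"]
    lc[sector_mod == 1] = inv["pasture"]
    lc[(dist > 2) & (dist <= 4) & (labels % 5 == 0)] = inv["industry"]
    lc[dist <= 2] = inv["urban_fabric"]
    lc[dist == 0] = inv["road_rail"]
    return lc, names


def _deprivation_term(spec: RegionSpec, season_f: float) -> np.ndarray:
    """Additive NO2 deprivation surface for one season (zero off urban sectors)."""
    struct, labels = _sector_structure(spec)
    dec = struct.set_index("sector_id")["bimd_decile"]
    deg = struct.set_index("sector_id")["degurba"]
    add_per_sector = np.where(
        deg.to_numpy() == 1,
        spec.deprivation_no2_slope * (10 - dec.to_numpy()),
        0.0,
    )
    surface = add_per_sector[labels] * season_f
    surface[road_mask(spec)] = 0.0  # nobody resides on road/rail land
    return surface


def generate_fields(
    spec: RegionSpec, noise: bool = True
) -> dict[tuple[str, str], SeasonalField]:
    """All pollutant x season concentration surfaces for the region.

    ``noise=False`` returns the deterministic (pre-noise) surfaces that the
    recorded truth is computed from.
    """
    dist = distance_cells(spec)
    decay = np.exp(-dist / spec.decay_scale)
    rng = np.random.default_rng([spec.seed, 1])
    meta = spec.meta
    fields: dict[tuple[str, str], SeasonalField] = {}
    for pollutant in POLLUTANTS:
        bg = spec.background_winter[pollutant]
        inc = spec.road_increment_winter[pollutant]
        for season in SEASONS:
            f, g = spec.season_coeffs(pollutant, season)
            values = f * bg + g * inc * decay
            if pollutant == "NO2" and spec.deprivation_no2_slope != 0.0:
                values = values + _deprivation_term(spec, f)
            if noise:
                values = values + spec.noise_sd * rng.standard_normal(values.shape)
            values = np.clip(values, CONCENTRATION_FLOOR, None)
            fields[(pollutant, season)] = SeasonalField(
                pollutant=pollutant, season=season, values=values, meta=meta
            )
    return fields


def generate_sectors(spec: RegionSpec) -> SectorFrame:
    """Partition the grid into sectors and attach all per-sector attributes."""
    struct, labels = _sector_structure(spec)
    n = spec.n_sectors
    lc, lc_names = landcover_grid(spec)

    rng_pop = np.random.default_rng([spec.seed, 4])
    sigma = 0.35
    population = np.maximum(
        1,
        np.round(
            rng_pop.lognormal(np.log(spec.population_mean) - sigma**2 / 2, sigma, size=n)
        ).astype(int),
    )

    rng_mob = np.random.default_rng([spec.seed, 5])
    u = rng_mob.uniform(size=n)
    mobiscore = np.clip(
        10.0 * u + 2.0 * (0.5 - struct["mean_dist_norm"].to_numpy()), 0.0, 10.0
    )

    rng_cars = np.random.default_rng([spec.seed, 6])
    cars = np.where(
        mobiscore < spec.mobiscore_changepoint,
        spec.cars_plateau,
        spec.cars_plateau + spec.cars_post_slope * (mobiscore - spec.mobiscore_changepoint),
    )
    if spec.cars_noise_sd > 0:
        cars = cars + rng_cars.normal(0.0, spec.cars_noise_sd, size=n)
    cars = np.clip(cars, 0.0, None)

    # modal land-cover class over member cells
    landcover = []
    for s in range(n):
        classes, counts = np.unique(lc[labels == s], return_counts=True)
        landcover.append(lc_names[int(classes[np.argmax(counts)])])

    attributes = pd.DataFrame(
        {
            "sector_id": struct["sector_id"],
            "population": population,
            "landcover": landcover,
            "degurba": struct["degurba"],
            "bimd_decile": struct["bimd_decile"],
            "mobiscore": mobiscore,
            "cars_per_household": cars,
        }
    )
    rr, cc = np.indices(spec.grid_shape)
    membership = pd.DataFrame(
        {"sector_id": labels.ravel(), "row": rr.ravel(), "col": cc.ravel()}
    ).sort_values(["sector_id", "row", "col"], ignore_index=True)
    return SectorFrame(attributes=attributes, membership=membership)


def cars_rule(spec: RegionSpec, mobiscore: float) -> float:
    """Noise-free car-ownership rule: plateau, then linear decline past the changepoint."""
    if mobiscore < spec.mobiscore_changepoint:
        return spec.cars_plateau
    return spec.cars_plateau + spec.cars_post_slope * (
        mobiscore - spec.mobiscore_changepoint
    )


@dataclass
class SyntheticTruth:
    """Planted and derived ground truth recorded alongside a generated region."""

    seed: int
    sector_means: dict  # pollutant -> season -> list of per-sector noise-free means
    stratum_ratios: dict  # kind -> label -> noise-free summer/winter ratio
    planted_ratio_road: dict
    planted_ratio_background: dict
    changepoint: float
    cars_plateau: float
    cars_post_slope: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def generate_truth(spec: RegionSpec) -> SyntheticTruth:
    """Compute the recoverable ground truth from the noise-free surfaces."""
    fields = generate_fields(spec, noise=False)
    struct, labels = _sector_structure(spec)
    lc, lc_names = landcover_grid(spec)
    sector_means: dict = {}
    for (pollutant, season), fld in fields.items():
        sector_means.setdefault(pollutant, {})[season] = [
            float(fld.values[labels == s].mean()) for s in range(spec.n_sectors)
        ]
    stratum_ratios: dict = {"landcover": {}, "degurba": {}}
    for pollutant in POLLUTANTS:
        su = fields[(pollutant, "summer")].values
        wi = fields[(pollutant, "winter")].values
        lc_r = {}
        for code, name in lc_names.items():
            m = lc == code
            if m.any():
                lc_r[name] = float(su[m].mean() / wi[m].mean())
        stratum_ratios["landcover"][pollutant] = lc_r
        deg = struct.set_index("sector_id")["degurba"].to_numpy()[labels]
        stratum_ratios["degurba"][pollutant] = {
            str(k): float(su[deg == k].mean() / wi[deg == k].mean()) for k in (1, 2, 3)
        }
    return SyntheticTruth(
        seed=spec.seed,
        sector_means=sector_means,
        stratum_ratios=stratum_ratios,
        planted_ratio_road=dict(spec.planted_ratio_road),
        planted_ratio_background=dict(spec.planted_ratio_background),
        changepoint=spec.mobiscore_changepoint,
        cars_plateau=spec.cars_plateau,
        cars_post_slope=spec.cars_post_slope,
    )


@dataclass
class RegionData:
    """A fully generated synthetic region."""

    spec: RegionSpec
    fields: dict
    sectors: SectorFrame
    truth: SyntheticTruth
    road_mask: np.ndarray
    landcover: np.ndarray
    landcover_names: dict


def generate_region(spec: RegionSpec) -> RegionData:
    """Generate fields, sectors and recorded truth in one call."""
    lc, names = landcover_grid(spec)
    return RegionData(
        spec=spec,
        fields=generate_fields(spec),
        sectors=generate_sectors(spec),
        truth=generate_truth(spec),
        road_mask=road_mask(spec),
        landcover=lc,
        landcover_names=names,
    )
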