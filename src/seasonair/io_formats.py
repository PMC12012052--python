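"""File formats and in-memory containers for gridded fields and sector tables.

Grid convention (used everywhere in this package): raster row 0 is the north
edge; the center of cell (r, c) sits at
``(x_origin + (c + 0.5) * cell_size,  y_origin - (r + 0.5) * cell_size)``
with ``y_origin`` the north edge of the grid.

Rasters are exchanged as ESRI ASCII grids (text, self-describing header) or
single-band float32 TIFF with a JSON sidecar (``<path>.aux.json``) carrying the
grid metadata. Sector attributes travel as CSV, sector polygons as GeoJSON, and
cell membership as an explicit (sector_id, row, col) CSV — linkage by table,
not by on-the-fly polygon overlay.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel used on disk for missing cells; large negative, never a concentration
DEFAULT_NODATA = -9999.0

SEASONS = ("winter", "spring", "summer", "autumn")
POLLUTANTS = ("NO2", "PM25")


@dataclass(frozen=True)
class GridMeta:
    """Raster geometry: shape, origin (NW corner), cell size and nodata sentinel."""

    rows: int
    cols: int
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 1.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError(f"grid shape must be positive, got {self.rows}x{self.cols}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.nodata >= 0:
            raise ValueError("nodata sentinel must be negative so it is never a concentration")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_origin + (col + 0.5) * self.cell_size,
            self.y_origin - (row + 0.5) * self.cell_size,
        )


@dataclass
class SeasonalField:
    """One pollutant x season gridded concentration surface (ug/m3).

    ``values`` is a 2-D float array; missing cells are NaN in memory and the
    nodata sentinel on disk.
    """

    pollutant: str
    season: str
    values: np.ndarray
    meta: GridMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("field values must be a 2-D array")
        if self.values.shape != (self.meta.rows, self.meta.cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid meta "
                f"({self.meta.rows}, {self.meta.cols})"
            )
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}; expected one of {SEASONS}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-missing) cells."""
        return np.isfinite(self.values)


def _check_finite(values: np.ndarray, path: str | Path) -> None:
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"{path}: non-finite value other than nodata at cell ({r}, {c})")


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, values: np.ndarray, meta: GridMeta) -> None:
    """Write an ESRI ASCII grid; values formatted with 6 significant digits."""
    values = np.asarray(values, dtype=float)
    path = Path(path)
    y_ll = meta.y_origin - meta.rows * meta.cell_size
    out = np.where(np.isfinite(values), values, meta.nodata)
    with path.open("w") as fh:
        fh.write(f"ncols {meta.cols}\n")
        fh.write(f"nrows {meta.rows}\n")
        fh.write(f"xllcorner {meta.x_origin!r}\n")
        fh.write(f"yllcorner {y_ll!r}\n")
        fh.write(f"cellsize {meta.cell_size!r}\n")
        fh.write(f"NODATA_value {meta.nodata!r}\n")
        for row in out:
            fh.write(" ".join(f"{v:.6g}" for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridMeta]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                if len(parts) != 2:
                    raise ValueError(f"{path}: malformed header line {line!r}")
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for required in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if required not in header:
            raise ValueError(f"{path}: missing required header field {required!r}")
    rows, cols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    try:
        values = np.array([[float(v) for v in ln.split()] for ln in data_lines], dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed data row ({exc})") from exc
    if values.shape != (rows, cols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header ({rows}, {cols})"
        )
    meta = GridMeta(
        rows=rows,
        cols=cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + rows * header["cellsize"],
        cell_size=header["cellsize"],
        nodata=nodata,
    )
    values = np.where(values == nodata, np.nan, values)
    _check_finite(np.where(np.isnan(values), 0.0, values), path)
    return values, meta


# ---------------------------------------------------------------------------
# TIFF (single band float32) + JSON sidecar for grid metadata
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".aux.json")


def write_tiff(path: str | Path, values: np.ndarray, meta: GridMeta) -> None:
    import tifffile

    path = Path(path)
    out = np.where(np.isfinite(values), values, meta.nodata).astype(np.float32)
    tifffile.imwrite(path, out)
    _sidecar(path).write_text(json.dumps({
        "rows": meta.rows, "cols": meta.cols,
        "x_origin": meta.x_origin, "y_origin": meta.y_origin,
        "cell_size": meta.cell_size, "nodata": meta.nodata,
    }, indent=1))


def read_tiff(path: str | Path) -> tuple[np.ndarray, GridMeta]:
    import tifffile

    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {values.shape}")
    side = _sidecar(path)
    if side.exists():
        m = json.loads(side.read_text())
        meta = GridMeta(**m)
    else:
        meta = GridMeta(rows=values.shape[0], cols=values.shape[1])
    values = np.where(values == meta.nodata, np.nan, values)
    _check_finite(np.where(np.isnan(values), 0.0, values), path)
    return values, meta


# ---------------------------------------------------------------------------
# SeasonalField round trip
# ---------------------------------------------------------------------------

def write_field(path: str | Path, fld: SeasonalField) -> None:
    """Write a seasonal field; format chosen by extension (.asc/.txt or .tif)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        write_tiff(path, fld.values, fld.meta)
    else:
        write_ascii_grid(path, fld.values, fld.meta)


def read_field(path: str | Path, pollutant: str, season: str) -> SeasonalField:
    """Read a raster into a SeasonalField; auto-detects ASCII grid vs TIFF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff") or path.read_bytes()[:4] in (b"II*\x00", b"MM\x00*"):
        values, meta = read_tiff(path)
    else:
        values, meta = read_ascii_grid(path)
    return SeasonalField(pollutant=pollutant, season=season, values=values, meta=meta)


# ---------------------------------------------------------------------------
# Sector attribute table and cell membership
# ---------------------------------------------------------------------------

SECTOR_REQUIRED = ("sector_id", "population", "landcover", "degurba")
SECTOR_OPTIONAL = ("bimd_decile", "mobiscore", "cars_per_household")


@dataclass
class SectorFrame:
    """Per-sector attributes plus cell membership.

    ``attributes``: one row per sector (sector_id, population, landcover,
    degurba, and optionally bimd_decile, mobiscore, cars_per_household).
    ``membership``: (sector_id, row, col), every cell in exactly one sector.
    """

    attributes: pd.DataFrame
    membership: pd.DataFrame
    geometry: dict[int, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_sectors(self.attributes, self.membership)

    @property
    def sector_ids(self) -> np.ndarray:
        return self.attributes["sector_id"].to_numpy()

    def cells_of(self, sector_id: int) -> np.ndarray:
        m = self.membership
        return m.loc[m["sector_id"] == sector_id, ["row", "col"]].to_numpy()

    def label_grid(self, meta: GridMeta) -> np.ndarray:
        """Sector-id raster; -1 where no sector claims the cell."""
        grid = np.full((meta.rows, meta.cols), -1, dtype=int)
        grid[self.membership["row"], self.membership["col"]] = self.membership["sector_id"]
        return grid


def validate_sectors(attributes: pd.DataFrame, membership: pd.DataFrame) -> None:
    for col in SECTOR_REQUIRED:
        if col not in attributes.columns:
            raise ValueError(f"sector table missing required column {col!r}")
    ids = attributes["sector_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique().tolist())
        raise ValueError(f"duplicate sector ids: {dupes}")
    if (attributes["population"] < 0).any():
        raise ValueError("negative population")
    if (attributes["population"] == 0).any():
        n0 = int((attributes["population"] == 0).sum())
        logger.warning(
            "%d sector(s) with population 0; they are excluded from "
            "population-weighted operations", n0,
        )
    bad_deg = ~attributes["degurba"].isin([1, 2, 3])
    if bad_deg.any():
        raise ValueError(
            f"degurba must be in {{1,2,3}}; offending sectors "
            f"{attributes.loc[bad_deg, 'sector_id'].tolist()}"
        )
    if "bimd_decile" in attributes.columns:
        dec = attributes["bimd_decile"].dropna()
        if (~dec.isin(range(1, 11))).any():
            raise ValueError("bimd_decile must be in 1..10 or missing")
    unknown = set(membership["sector_id"]) - set(ids)
    if unknown:
        raise ValueError(f"membership references unknown sector ids: {sorted(unknown)}")
    cells = membership[["row", "col"]]
    if cells.duplicated().any():
        raise ValueError("a cell is assigned to more than one sector")


def write_sectors(attr_path: str | Path, membership_path: str | Path, sectors: SectorFrame) -> None:
    sectors.attributes.to_csv(attr_path, index=False)
    sectors.membership.to_csv(membership_path, index=False)


def read_sectors(attr_path: str | Path, membership_path: str | Path) -> SectorFrame:
    """Read and validate the sector attribute and membership CSVs."""
    attributes = pd.read_csv(attr_path)
    membership = pd.read_csv(membership_path)
    return SectorFrame(attributes=attributes, membership=membership)


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def sectors_to_geojson(path: str | Path, sectors: SectorFrame, meta: GridMeta) -> None:
    """Write sector polygons (union of member cell squares) as GeoJSON."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    features = []
    for _, row in sectors.attributes.iterrows():
        sid = int(row["sector_id"])
        cells = sectors.cells_of(sid)
        boxes = [
            box(
                meta.x_origin + c * meta.cell_size,
                meta.y_origin - (r + 1) * meta.cell_size,
                meta.x_origin + (c + 1) * meta.cell_size,
                meta.y_origin - r * meta.cell_size,
            )
            for r, c in cells
        ]
        geom = unary_union(boxes)
        props = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        features.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def rasterize_geojson(path: str | Path, meta: GridMeta) -> pd.DataFrame:
    """Build a membership table from GeoJSON polygons by cell-center containment.

    Helper for real-data use where membership is not supplied as a table.
    """
    from shapely.geometry import shape, Point

    gj = json.loads(Path(path).read_text())
    rows = []
    geoms = [(f["properties"]["sector_id"], shape(f["geometry"])) for f in gj["features"]]
    for r in range(meta.rows):
        for c in range(meta.cols):
            x, y = meta.cell_center(r, c)
            pt = Point(x, y)
            for sid, geom in geoms:
                if geom.contains(pt):
                    rows.append((int(sid), r, c))
                    break
    return pd.DataFrame(rows, columns=["sector_id", "row", "col"])


def check_common_grid(fields: list[SeasonalField]) -> GridMeta:
    """All fields must share one grid; returns it or raises."""
    if not fields:
        raise ValueError("no fields supplied")
    meta = fields[0].meta
    for f in fields[1:]:
        if (f.meta.rows, f.meta.cols) != (meta.rows, meta.cols):
            raise ValueError(
                f"grid shape mismatch: {f.pollutant}/{f.season} is "
                f"{(f.meta.rows, f.meta.cols)}, expected {(meta.rows, meta.cols)}"
            )
    return meta
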