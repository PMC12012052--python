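"""End-to-end orchestration: one config in, a directory of report tables out.

Stages (each logged, any failure aborts naming the stage): load or simulate
the region; zonal exposure aggregation; summer/winter ratios (overall, per
land-cover class, per DEGURBA class, per sector); distance-to-road profiles
with percent-decline summaries; seasonal contribution shares; preventable
fractions with Monte Carlo intervals; deprivation disparity curves and the
accessibility/car-ownership turning point. A JSON manifest echoing the
config, seeds and package version makes any run reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .disparities import TurningPointDetector, curves_to_frame, deprivation_curves
from .exposure import annual_means, build_exposure_table, seasonal_shares
from .hia import ExposureResponse, pf_to_frame, pf_with_uncertainty
from .io_formats import (
    POLLUTANTS,
    SEASONS,
    SectorFrame,
    check_common_grid,
    read_field,
    read_sectors,
)
from .seasonal_analysis import (
    distance_profile,
    distance_transform,
    overall_ratio,
    percent_decline,
    ratios_to_frame,
    sector_ratio,
    stratified_ratio,
)
from .synthetic_region import RegionSpec, generate_region

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; exactly one input mode set."""

    synthetic: dict | None = None  # RegionSpec keyword overrides
    inputs: dict | None = None  # field_paths, sector CSVs, road-mask raster
    exposure_response: dict = field(default_factory=dict)  # per-pollutant overrides
    loess_span: float = 0.75
    loess_degree: int = 1
    turning_point_span: float = 0.15
    n_boot: int = 1000
    n_iter: int = 10_000
    seed: int = 0
    counterfactual: str = "guideline"
    shares_weighted: bool = True
    path_distance_cut: float = 0.05

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of synthetic / inputs must be configured")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d)

    def exposure_response_for(self, pollutant: str) -> ExposureResponse:
        if pollutant in self.exposure_response:
            o = self.exposure_response[pollutant]
            return ExposureResponse(pollutant=pollutant, **o)
        return ExposureResponse.default(pollutant)


def _load_inputs(cfg: RunConfig):
    """Stage: read fields, sectors and road mask from configured paths."""
    inp = cfg.inputs
    fields = {}
    for pollutant in POLLUTANTS:
        for season in SEASONS:
            key = f"{pollutant}_{season}"
            if key not in inp["field_paths"]:
                raise ValueError(f"stage load: missing field for season {season!r} ({pollutant})")
            fields[(pollutant, season)] = read_field(
                inp["field_paths"][key], pollutant, season
            )
    sectors = read_sectors(inp["sector_attributes"], inp["sector_membership"])
    mask_field = read_field(inp["road_mask"], "NO2", "winter")
    rmask = np.nan_to_num(mask_field.values) > 0.5
    landcover = None
    if inp.get("landcover"):
        lc_field = read_field(inp["landcover"], "NO2", "winter")
        landcover = np.nan_to_num(lc_field.values, nan=-1).astype(int)
    return fields, sectors, rmask, landcover, None


def run(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write the output bundle; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "seasonair",
        "version": __version__,
        "config": _config_echo(cfg),
        "seed": cfg.seed,
        "counterfactual_mode": cfg.counterfactual,
        "stages": [],
    }

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    # -- load / simulate -----------------------------------------------------
    stage("load")
    lc_names = None
    if cfg.synthetic is not None:
        spec = RegionSpec(seed=cfg.seed, **cfg.synthetic)
        region = generate_region(spec)
        fields, sectors = region.fields, region.sectors
        rmask, landcover = region.road_mask, region.landcover
        lc_names = region.landcover_names
        region.truth.to_json(outdir / "truth.json")
    else:
        fields, sectors, rmask, landcover, lc_names = _load_inputs(cfg)
    meta = check_common_grid(list(fields.values()))

    # -- exposure ------------------------------------------------------------
    stage("aggregate")
    exposure = build_exposure_table(list(fields.values()), sectors)
    exposure.to_csv(outdir / "exposure.csv", index=False)
    logger.info("exposure table: %d rows", len(exposure))

    # -- ratios --------------------------------------------------------------
    stage("ratios")
    ratio_rows = []
    sector_ratios = {}
    for pollutant in POLLUTANTS:
        su = fields[(pollutant, "summer")]
        wi = fields[(pollutant, "winter")]
        ratio_rows.append(overall_ratio(su, wi, n_boot=cfg.n_boot, seed=cfg.seed))
        if landcover is not None:
            ratio_rows.extend(
                stratified_ratio(
                    su, wi, landcover, kind="landcover", labels=lc_names,
                    n_boot=cfg.n_boot, seed=cfg.seed,
                )
            )
        deg_grid = _sector_attr_grid(sectors, meta, "degurba")
        ratio_rows.extend(
            stratified_ratio(
                su, wi, deg_grid, kind="degurba",
                n_boot=cfg.n_boot, seed=cfg.seed,
            )
        )
        sector_ratios[pollutant] = sector_ratio(exposure, pollutant)
    ratios_to_frame(ratio_rows).to_csv(outdir / "ratios.csv", index=False)
    pd.DataFrame(
        {p: s for p, s in sector_ratios.items()}
    ).rename(columns={p: f"ratio_{p}" for p in POLLUTANTS}).to_csv(
        outdir / "sector_ratios.csv"
    )

    # -- distance profiles ---------------------------------------------------
    stage("distance_profiles")
    dist = distance_transform(rmask, meta)
    profile_rows, decline_rows = [], []
    for pollutant in POLLUTANTS:
        for season in ("summer", "winter"):
            prof = distance_profile(
                fields[(pollutant, season)], dist,
                span=cfg.loess_span, degree=cfg.loess_degree, seed=cfg.seed,
            )
            for x, f_, lo, hi in zip(
                prof.loess.eval_x, prof.loess.fitted,
                prof.loess.ci_low, prof.loess.ci_high,
            ):
                profile_rows.append((pollutant, season, x, f_, lo, hi))
            c0, c_cut = np.interp(
                [0.0, cfg.path_distance_cut], prof.loess.eval_x, prof.loess.fitted
            )
            decline_rows.append(
                (pollutant, season, c0, c_cut, percent_decline(c0, c_cut))
            )
    pd.DataFrame(
        profile_rows,
        columns=["pollutant", "season", "distance", "fit", "ci_low", "ci_high"],
    ).to_csv(outdir / "distance_profiles.csv", index=False)
    pd.DataFrame(
        decline_rows,
        columns=["pollutant", "season", "conc_origin", "conc_at_cut", "percent_decline"],
    ).to_csv(outdir / "percent_declines.csv", index=False)

    # -- seasonal shares -----------------------------------------------------
    stage("seasonal_shares")
    share_rows = []
    for pollutant in POLLUTANTS:
        sh = seasonal_shares(exposure, sectors, pollutant, weighted=cfg.shares_weighted)
        for season in SEASONS:
            share_rows.append((pollutant, season, sh.shares[season], sh.weighted))
    pd.DataFrame(
        share_rows, columns=["pollutant", "season", "share", "population_weighted"]
    ).to_csv(outdir / "seasonal_shares.csv", index=False)

    # -- health impact -------------------------------------------------------
    stage("hia")
    pf_frames = []
    for pollutant in POLLUTANTS:
        er = cfg.exposure_response_for(pollutant)
        national, per_sector = pf_with_uncertainty(
            exposure, sectors, er,
            n_iter=cfg.n_iter, seed=cfg.seed, counterfactual=cfg.counterfactual,
        )
        pf_frames.append(pf_to_frame(national, per_sector))
    pd.concat(pf_frames, ignore_index=True).to_csv(outdir / "pf.csv", index=False)

    # -- disparities ---------------------------------------------------------
    stage("disparities")
    metrics = pd.DataFrame({"sector_id": sectors.sector_ids})
    for pollutant in POLLUTANTS:
        ann = annual_means(exposure, pollutant)
        metrics[f"annual_{pollutant}"] = ann.reindex(metrics["sector_id"]).to_numpy()
        metrics[f"ratio_{pollutant}"] = (
            sector_ratios[pollutant].reindex(metrics["sector_id"]).to_numpy()
        )
    curves = deprivation_curves(
        metrics, sectors.attributes, span=cfg.loess_span, degree=cfg.loess_degree
    )
    curves_to_frame(curves).to_csv(outdir / "disparity_curves.csv", index=False)

    tp_result = {"detected": False}
    attrs = sectors.attributes
    if {"mobiscore", "cars_per_household"}.issubset(attrs.columns):
        ok = attrs[["mobiscore", "cars_per_household"]].dropna()
        if len(ok) >= 30:
            det = TurningPointDetector(span=cfg.turning_point_span).fit(
                ok["mobiscore"].to_numpy(), ok["cars_per_household"].to_numpy()
            )
            tp_result = {
                "detected": bool(det.detected_),
                "x_star": None if np.isnan(det.x_star_) else float(det.x_star_),
                "pre_slope": None if np.isnan(det.pre_slope_) else float(det.pre_slope_),
                "post_slope": None if np.isnan(det.post_slope_) else float(det.post_slope_),
                "method": "loess-derivative-threshold",
                "span": cfg.turning_point_span,
            }
    (outdir / "turning_point.json").write_text(json.dumps(tp_result, indent=1))

    stage("manifest")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    # frozensets in a synthetic spec are not JSON-serialisable
    if d.get("synthetic") and "road_cells" in d["synthetic"]:
        d["synthetic"]["road_cells"] = sorted(map(list, d["synthetic"]["road_cells"]))
    return d


def _sector_attr_grid(sectors: SectorFrame, meta, column: str) -> np.ndarray:
    """Broadcast a per-sector attribute to a cell grid (-1 off-sector)."""
    labels = sectors.label_grid(meta)
    attr = sectors.attributes.set_index("sector_id")[column]
    out = np.full(labels.shape, -1, dtype=int)
    inside = labels >= 0
    out[inside] = attr.reindex(labels[inside]).to_numpy()
    return out
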