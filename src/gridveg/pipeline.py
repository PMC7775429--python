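"""End-to-end orchestration: world/in -> features -> screen -> selection -> report.

``run_evaluation`` executes the whole evaluation for one region and returns a
:class:`ReportBundle`; with an output directory it also writes the table
artifacts (suitability table sorted by percent significant pixels, stepwise
selection frequencies, shadow-feature importances, top-3 standardized
anomaly series) plus a JSON manifest with seeds, catalog size and pixel
counts.  All randomness derives from one master seed, so identical configs
produce byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import anomalies as an
from . import selection as sel
from . import snow as sn
from . import stats as st
from .cubes import ClassRaster, ClimateCube, VEGETATED_CLASSES, VEGETATION_CLASSES, regrid_nearest
from .io import read_cube
from .simulate import ProductSpec, TruthRecord, World, WorldConfig, make_world

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of an evaluation run, with the standard defaults."""

    region: str = "synthetic"
    mode: str = "synthetic"                  # synthetic | real
    world: WorldConfig = field(default_factory=WorldConfig)
    cube_paths: dict | None = None           # real mode: (product, variable) -> path
    peak_months: tuple[int, ...] = (7, 8)
    methods: tuple[str, ...] = ("pearson",)
    fdr_q: float = 0.05
    pixel_alpha: float = 0.05
    suitability_pixel_pct: float = 50.0
    bootstrap_reps: int = 2500
    bootstrap_level: float = 0.95
    stepwise_k: int = 3
    stepwise_reps: int = 100
    boruta_max_runs: int = 500
    boruta_alpha: float = 0.05
    boruta_reps: int = 500
    rf_config: sel.RFConfig = field(default_factory=sel.RFConfig)
    seed: int = 0
    with_snow_features: bool = True
    per_class: bool = False

    def __post_init__(self) -> None:
        for lvl in (self.fdr_q, self.pixel_alpha, self.boruta_alpha):
            if not 0 < lvl < 1:
                raise ValueError("levels must be in (0, 1)")
        if min(self.stepwise_reps, self.boruta_reps) < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class ReportBundle:
    region: str
    ndvi: an.NdviAnomalySeries
    features: list[an.FeatureSeries]
    records: dict[str, list[st.CorrelationRecord]]     # per method
    stepwise: list[sel.SelectionFrequency]
    boruta: list[sel.BorutaOutcome]
    autocorrelation: dict
    per_class: dict[str, list[st.CorrelationRecord]]
    manifest: dict


def prepare_inputs(world: World, cfg: RunConfig):
    """NDVI peak-anomaly series plus all monthly cubes on the NDVI grid."""
    years = list(range(world.config.start_year,
                       world.config.start_year + world.config.years))
    veg_mask = world.classes.mask_for(VEGETATED_CLASSES)
    ndvi_monthly = an.monthly_max_composite(world.ndvi)
    ndvi_series = an.peak_anomaly(ndvi_monthly, cfg.peak_months, years,
                                  region=cfg.region, pixel_mask=veg_mask)
    monthly: dict[tuple[str, str], ClimateCube] = {}
    products: list[tuple[str, list[str]]] = []
    for spec in world.config.product_specs:
        products.append((spec.name, list(spec.variables)))
        for var in spec.variables:
            cube = world.climate[(spec.name, var)]
            monthly[(spec.name, var)] = regrid_nearest(cube, world.config.ndvi_grid)
    if cfg.with_snow_features and world.snow_daily is not None:
        metrics = sn.snow_monthly_metrics(world.snow_daily)
        products.append(("modis_snow", list(metrics.keys())))
        for var, cube in metrics.items():
            monthly[("modis_snow", var)] = regrid_nearest(cube, world.config.ndvi_grid)
    catalog = an.build_feature_catalog(products)
    features = an.compute_features(monthly, catalog, years, pixel_mask=veg_mask)
    return ndvi_series, features, veg_mask


def _fmt_of(path: str) -> str:
    return "netcdf" if path.endswith((".nc", ".nc4", ".cdf")) else "geotiff_stack"


def load_world(cube_paths: dict, region: str = "region") -> World:
    """Assemble a :class:`World` from on-disk cubes (real-data mode).

    ``cube_paths`` maps ``"ndvi"`` to the sub-monthly NDVI cube,
    ``"climate"`` to a dict of ``"product:variable" -> path`` monthly cubes,
    and optionally ``"snow"`` (daily NDSI cube) and ``"classes"`` (a
    single-slice cube of vegetation-class indices).  Formats are inferred
    from the extension.  Without a class raster every pixel is treated as
    vegetated.  The returned world carries no ground truth.
    """
    ndvi = read_cube(cube_paths["ndvi"], _fmt_of(cube_paths["ndvi"]))
    climate: dict[tuple[str, str], ClimateCube] = {}
    by_product: dict[str, list[str]] = {}
    for key, path in cube_paths.get("climate", {}).items():
        product, var = key.split(":", 1)
        climate[(product, var)] = read_cube(path, _fmt_of(path))
        by_product.setdefault(product, []).append(var)
    snow = None
    if cube_paths.get("snow"):
        snow = read_cube(cube_paths["snow"], _fmt_of(cube_paths["snow"]))
    if cube_paths.get("classes"):
        ccube = read_cube(cube_paths["classes"], _fmt_of(cube_paths["classes"]))
        classes = ClassRaster(ccube.grid, ccube.values[0].astype(int))
    else:
        classes = ClassRaster(ndvi.grid, np.full(
            ndvi.grid.shape, VEGETATION_CLASSES.index("dwarf_shrub_steppe")))
    years = sorted(set(int(y) for y in ndvi.time.years))
    cfg = WorldConfig(
        years=len(years), start_year=years[0], ndvi_grid=ndvi.grid,
        product_specs=tuple(ProductSpec(p, tuple(v)) for p, v in by_product.items()),
        planted_driver=next(iter(climate), ("", "")) + ("hydrological_year",)
        if climate else ("", "", "hydrological_year"),
        with_snow=snow is not None, region=region,
    )
    truth = TruthRecord(
        driver_feature_id="", effect_size=np.nan, realized_r=np.nan,
        driver_signal=np.full(len(years), np.nan),
        decoupled_mask=np.zeros(ndvi.grid.shape, bool),
        analyzed_mask=classes.mask_for(VEGETATED_CLASSES),
        noise_params={},
    )
    return World(cfg, ndvi, climate, snow, classes, truth)


def feature_matrix(
    features: list[an.FeatureSeries], years: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Stack area anomalies into (n_years, n_features) over common years."""
    cols, ids = [], []
    for f in features:
        sel_years = np.isin(f.years, years)
        if sel_years.sum() != len(years):
            raise ValueError(f"feature {f.feature_id} missing years")
        cols.append(f.anomaly[sel_years])
        ids.append(f.feature_id)
    return np.column_stack(cols), ids


def run_evaluation(cfg: RunConfig, out_dir: str | None = None) -> ReportBundle:
    """Execute the full evaluation; optionally write all table artifacts."""
    ss = np.random.SeedSequence(cfg.seed)
    s_stats, s_step, s_bor = ss.spawn(3)
    if cfg.mode == "synthetic":
        world = make_world(cfg.world)
    elif cfg.mode == "real":
        if not cfg.cube_paths:
            raise ValueError("real mode requires cube_paths")
        world = load_world(cfg.cube_paths, region=cfg.region)
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")
    ndvi_series, features, veg_mask = prepare_inputs(world, cfg)

    acheck = st.autocorrelation_check(ndvi_series)
    records: dict[str, list[st.CorrelationRecord]] = {}
    for method in cfg.methods:
        records[method] = st.evaluate_features(
            features, ndvi_series, method=method, fdr_q=cfg.fdr_q,
            pixel_alpha=cfg.pixel_alpha,
            pixel_pct_threshold=cfg.suitability_pixel_pct,
            n_boot=cfg.bootstrap_reps,
            seed=np.random.default_rng(s_stats),
        )

    common_years = ndvi_series.years
    usable = [f for f in features if np.isin(common_years, f.years).all()]
    X, ids = feature_matrix(usable, common_years)
    stepwise = sel.stepwise_cv_selection(
        X, ndvi_series.anomaly, ids, k=cfg.stepwise_k, reps=cfg.stepwise_reps,
        seed=np.random.default_rng(s_step))
    boruta = sel.boruta_repeat(
        X, ndvi_series.anomaly, ids, reps=cfg.boruta_reps,
        seed=int(s_bor.generate_state(1)[0] % (2**31 - 1)),
        max_runs=cfg.boruta_max_runs, alpha=cfg.boruta_alpha,
        rf_config=cfg.rf_config)

    per_class: dict[str, list[st.CorrelationRecord]] = {}
    if cfg.per_class:
        per_class = st.per_class_analysis(
            features, ndvi_series, world.classes,
            fdr_q=cfg.fdr_q, pixel_alpha=cfg.pixel_alpha,
            pixel_pct_threshold=cfg.suitability_pixel_pct,
            n_boot=cfg.bootstrap_reps, seed=np.random.default_rng(s_stats))

    dropped = {f.feature_id: list(f.dropped_years) for f in features if f.dropped_years}
    manifest = {
        "region": cfg.region, "seed": cfg.seed, "world_seed": cfg.world.seed,
        "catalog_size": len(features), "n_years": int(ndvi_series.n_years),
        "n_analyzed_pixels": int(ndvi_series.pixel_anomaly.shape[1]),
        "methods": list(cfg.methods), "fdr_q": cfg.fdr_q,
        "pixel_alpha": cfg.pixel_alpha,
        "bootstrap_reps": cfg.bootstrap_reps,
        "stepwise": {"k": cfg.stepwise_k, "reps": cfg.stepwise_reps},
        "boruta": {"max_runs": cfg.boruta_max_runs, "alpha": cfg.boruta_alpha,
                   "reps": cfg.boruta_reps},
        "dropped_years": dropped,
        "planted_driver": world.truth.driver_feature_id or None,
        "realized_driver_r": (world.truth.realized_r
                              if np.isfinite(world.truth.realized_r) else None),
        "autocorrelation_pass": acheck["passed"],
    }
    bundle = ReportBundle(cfg.region, ndvi_series, features, records,
                          stepwise, boruta, acheck, per_class, manifest)
    if out_dir is not None:
        write_report(bundle, out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------

def records_frame(records: list[st.CorrelationRecord]) -> pd.DataFrame:
    """Suitability table with both display-rounded and raw columns."""
    rows = []
    for r in records:
        rows.append({
            "feature": r.feature_id, "method": r.method,
            "p": round(r.p, 4), "r": round(r.r, 2),
            "ci_low": round(r.ci_low, 2), "ci_high": round(r.ci_high, 2),
            "pct_significant_pixels": int(round(r.pct_significant_pixels)),
            "fdr_significant": r.fdr_significant,
            "highly_suitable": r.highly_suitable,
            "p_raw": r.p, "r_raw": r.r,
            "ci_low_raw": r.ci_low, "ci_high_raw": r.ci_high,
            "pct_raw": r.pct_significant_pixels,
            "n_years": r.n_years, "n_pixels": r.n_pixels,
        })
    return pd.DataFrame(rows)


def top_features_frame(
    bundle: ReportBundle, method: str = "pearson", k: int = 3
) -> pd.DataFrame:
    """Standardized anomaly series of the k highest-|r| features plus NDVI."""
    recs = sorted(bundle.records[method], key=lambda r: (-abs(r.r), r.feature_id))[:k]
    by_id = {f.feature_id: f for f in bundle.features}
    data = {"year": bundle.ndvi.years,
            "ndvi": an.standardize(bundle.ndvi).anomaly}
    for r in recs:
        f = an.standardize(by_id[r.feature_id])
        col = np.full(bundle.ndvi.n_years, np.nan)
        col[np.isin(bundle.ndvi.years, f.years)] = f.anomaly
        data[r.feature_id] = col
    return pd.DataFrame(data)


def _to_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def correlation_rasters(
    bundle: ReportBundle, method: str = "pearson", k: int = 3,
    pixel_alpha: float = 0.05,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-pixel r and p maps (NaN outside analyzed pixels) for the k
    highest-|r| features of a method."""
    recs = sorted(bundle.records[method], key=lambda r: (-abs(r.r), r.feature_id))[:k]
    by_id = {f.feature_id: f for f in bundle.features}
    out = {}
    for rec in recs:
        feat = by_id[rec.feature_id]
        px = st.per_pixel_analysis(feat, bundle.ndvi, alpha=pixel_alpha)
        shape = bundle.ndvi.pixel_mask.shape
        rmap = np.full(shape, np.nan)
        pmap = np.full(shape, np.nan)
        rows, cols = np.nonzero(bundle.ndvi.pixel_mask)
        rmap[rows[px.analyzed_columns], cols[px.analyzed_columns]] = px.r
        pmap[rows[px.analyzed_columns], cols[px.analyzed_columns]] = px.p
        out[rec.feature_id] = (rmap, pmap)
    return out


def write_correlation_rasters(bundle: ReportBundle, out_dir: str,
                              method: str = "pearson", k: int = 3) -> None:
    """Write the top-k features' r/p maps as a multi-band TIFF stack with a
    YAML sidecar describing the bands (two bands per feature: r then p)."""
    import tifffile
    import yaml

    maps = correlation_rasters(bundle, method=method, k=k)
    if not maps:
        return
    stack, bands = [], []
    for fid, (rmap, pmap) in maps.items():
        stack.extend([rmap, pmap])
        bands.extend([{"feature": fid, "layer": "r"}, {"feature": fid, "layer": "p"}])
    path = os.path.join(out_dir, f"correlation_maps_{method}.tif")
    tifffile.imwrite(path, np.array(stack, dtype=np.float64),
                     photometric="minisblack")
    with open(path + ".yaml", "w") as fh:
        yaml.safe_dump({"bands": bands, "region": bundle.region}, fh)


def write_report(bundle: ReportBundle, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for method, recs in bundle.records.items():
        _to_csv(records_frame(recs), os.path.join(out_dir, f"suitability_{method}.csv"))
    _to_csv(pd.DataFrame([
        {"feature": s.feature_id, "times_selected_best": s.times_selected_best,
         "total_folds": s.total_folds, "selection_pct": s.selection_pct}
        for s in bundle.stepwise]), os.path.join(out_dir, "stepwise_selection.csv"))
    _to_csv(pd.DataFrame([
        {"feature": b.feature_id, "mean_importance": b.mean_importance,
         "confirmed_pct": b.confirmed_pct}
        for b in bundle.boruta]), os.path.join(out_dir, "boruta_importance.csv"))
    for method in bundle.records:
        _to_csv(top_features_frame(bundle, method),
                os.path.join(out_dir, f"top_features_{method}.csv"))
    for cls, recs in bundle.per_class.items():
        _to_csv(records_frame(recs), os.path.join(out_dir, f"suitability_class_{cls}.csv"))
    for method in bundle.records:
        write_correlation_rasters(bundle, out_dir, method=method)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)


def plot_top_features(bundle: ReportBundle, path: str, method: str = "pearson") -> None:
    """Bar/line figure of standardized top-feature anomalies vs NDVI."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = top_features_frame(bundle, method)
    fig, ax = plt.subplots(figsize=(8, 4))
    width = 0.8 / max(1, len(df.columns) - 2)
    for i, col in enumerate(c for c in df.columns if c not in ("year", "ndvi")):
        ax.bar(df["year"] + (i - 1) * width, df[col], width=width, label=col)
    ax.plot(df["year"], df["ndvi"], color="darkgreen", marker="o", label="NDVI")
    ax.set_xlabel("year")
    ax.set_ylabel("standardized anomaly")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_methods(bundle: ReportBundle) -> dict:
    """Jaccard overlap of the highly-suitable sets of both methods."""
    if len(bundle.records) < 2:
        raise ValueError("need two methods to compare")
    sets = {m: {r.feature_id for r in recs if r.highly_suitable}
            for m, recs in bundle.records.items()}
    (m1, s1), (m2, s2) = list(sets.items())[:2]
    union = s1 | s2
    jaccard = len(s1 & s2) / len(union) if union else 1.0
    disagreements = sorted(s1 ^ s2)
    return {"methods": (m1, m2), "jaccard": jaccard,
            "disagreements": disagreements,
            "highly_suitable": {m1: sorted(s1), m2: sorted(s2)}}
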