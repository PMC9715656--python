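"""End-to-end orchestration of the analysis on a (synthetic) scene.

``run_all`` executes simulate -> preprocess -> annual metrics -> classify
-> hydromet -> trends -> irrigation -> correlations -> land cover and
returns every intermediate product plus a machine-readable summary of the
headline statistics.  Given the same configuration and seed the summary is
byte-identical between runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annual, classify, correlations, hydromet, irrigation
from . import landcover as lc
from . import trends as tr
from .config import MONTHS_PER_YEAR, GeneratorConfig
from .preprocess import SmoothingConfig, reconstruct_cube
from .resample import block_average, nearest_upsample
from .synthetic import Scene, generate_scene


@dataclass
class PipelineConfig:
    """Thresholds and switches of the full analysis (all explicit)."""

    generator: GeneratorConfig = None
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    alpha: float = 0.05
    veg_threshold: float = 0.25
    agri_crop_frac: float = 20.0
    natural_crop_frac: float = 40.0
    r_high_threshold: float = 0.6
    intensity_threshold: float = 50.0
    elevation_binwidth_m: float = 50.0
    crop_prob_as_printed: bool = False
    newly_cultivated_as_printed: bool = False

    def __post_init__(self) -> None:
        if self.generator is None:
            raise ValueError("PipelineConfig requires a GeneratorConfig")


@dataclass
class PipelineResult:
    scene: Scene
    reconstruction: object
    veg: annual.AnnualVegGrowth
    crop_frac: np.ndarray
    masks: classify.VegClassMasks
    met_annual: dict
    ai2_monthly_cell: np.ndarray
    twsa_annual: hydromet.AnnualTwsa
    trend: tr.TrendMaps
    basin_shares: object
    met_corr: correlations.CorrelationMaps
    irrigation_fields: dict
    initial_intensity: np.ndarray
    twsa_corr: dict
    landcover_stats: lc.ChangeStatistics
    transition: object
    summary: dict


def _country_mean(arr: np.ndarray, mask: np.ndarray | None = None
                  ) -> np.ndarray:
    """Mean over the spatial axes per year, optionally restricted to a mask."""
    if mask is None:
        return np.nanmean(arr, axis=(0, 1))
    if not mask.any():
        return np.full(arr.shape[-1], np.nan)
    return np.nanmean(arr[mask], axis=0)


def run_all(cfg: PipelineConfig) -> PipelineResult:
    gen = cfg.generator
    scene = generate_scene(gen)

    # (1) NDVI reconstruction
    recon = reconstruct_cube(scene.cube, cfg.smoothing)

    # (2) annual vegetation growth
    snow = annual.max_snow_composites(scene.ancillary.snow_flags,
                                      n_years=gen.n_years)
    veg = annual.annual_cube(recon.smoothed, snow, gen.years)

    # (3) land-use classification
    crop_frac = block_average(scene.ancillary.crop_frac_fine,
                              gen.crop_fine_factor)
    vegetated = classify.classify_vegetated(veg.ndvi_max,
                                            threshold=cfg.veg_threshold)
    masks = classify.classify_agri_natural(
        crop_frac, vegetated, agri_threshold=cfg.agri_crop_frac,
        natural_threshold=cfg.natural_crop_frac)
    masks.newly_cultivated = masks.agricultural & classify.flag_newly_cultivated(
        veg.ndvi_max, gen.years, as_printed=cfg.newly_cultivated_as_printed)

    # (4) hydromet aggregates
    met = scene.met
    tp_ann = hydromet.aggregate_water_year(met.tp, "mean")
    t2m_ann = hydromet.aggregate_water_year(met.t2m, "mean")
    pev_ann = hydromet.aggregate_water_year(met.pev, "mean")
    ai_ann = hydromet.aridity_index(tp_ann, pev_ann)
    ai2 = hydromet.two_month_ai(met.tp, met.pev)
    met_annual = {"tp": tp_ann, "t2m": t2m_ann, "ai": ai_ann}
    twsa_annual = hydromet.annualize_twsa(scene.ancillary.twsa)

    # (5) vegetation growth trends
    trend = tr.trend_map(veg.ndvi_mean_star, alpha=cfg.alpha)
    established_agri = masks.agricultural & ~masks.newly_cultivated
    basin_shares = tr.basin_trend_shares(trend, scene.truth.basin_id,
                                         established_agri)

    # (6) natural vegetation vs meteorology + elevation bins
    met_corr = correlations.pixelwise_met_correlation(
        veg.ndvi_mean_star, met_annual, gen.met_block, mask=masks.natural)
    elev_bins = correlations.bin_by(trend.slope[masks.natural],
                                    scene.ancillary.dem[masks.natural],
                                    binwidth=cfg.elevation_binwidth_m)

    # (7) irrigation intensity
    monthly_max = irrigation.monthly_max_ndvi(recon.smoothed)
    ai2_pix = nearest_upsample(ai2, gen.met_block)
    irr = irrigation.irrigation_fields(monthly_max, crop_frac, ai2_pix,
                                       as_printed=cfg.crop_prob_as_printed)
    init_int = irrigation.initial_intensity(irr["irr_int_ann_4q"], gen.years)

    # (8) country-wide annual correlations
    veg_series = {
        "veg": _country_mean(veg.ndvi_mean_star),
        "vegAgr": _country_mean(veg.ndvi_mean_star, masks.agricultural),
        "vegNat": _country_mean(veg.ndvi_mean_star, masks.natural),
    }
    met_series = {k: np.nanmean(v, axis=(0, 1)) for k, v in met_annual.items()}
    valid_cols = ~np.all(np.isnan(twsa_annual.annual), axis=0)
    twsa_country = np.full(twsa_annual.annual.shape[1], np.nan)
    twsa_country[valid_cols] = np.nanmean(
        twsa_annual.annual[:, valid_cols], axis=0)
    common = ~np.isnan(twsa_country)
    iran_table, iran_z = correlations.iranwide_annual_correlation(
        veg_series, met_series, twsa_country, reference=common)

    # (9) agricultural vegetation vs basin TWSA
    ai_pix = nearest_upsample(ai_ann.mean(axis=-1), gen.met_block)
    twsa_corr = correlations.twsa_vegetation_correlation(
        veg.ndvi_mean_star, twsa_annual, scene.truth.basin_id,
        established_agri, intensity=init_int, aridity=ai_pix,
        r_threshold=cfg.r_high_threshold,
        intensity_threshold=cfg.intensity_threshold)

    # (10) land cover change accounting
    lc_series = scene.ancillary.landcover
    lc_stats = lc.change_statistics(lc_series)
    transition = lc.transition_matrix(lc_series.maps[0], lc_series.maps[-1],
                                      class_names=lc_series.class_names,
                                      pixel_area_km2=lc_series.pixel_area_km2)
    met_country_monthly = {
        "tp": np.nanmean(met.tp, axis=(0, 1)),
        "t2m": np.nanmean(met.t2m, axis=(0, 1)),
        "ai": np.nanmean(
            met.tp / np.maximum(np.abs(met.pev), 1e-9), axis=(0, 1)),
    }
    lc_met = lc.netrate_met_correlation(lc_stats.net_rate_km2,
                                        met_country_monthly)

    # headline summary (deterministic content given config + seed)
    sig = trend.significant & established_agri
    n_sig = int(sig.sum())
    n_pos = int((sig & (trend.slope > 0)).sum())
    n_neg = int((sig & (trend.slope < 0)).sum())
    area = lc_series.pixel_area_km2
    warming_slope, _ = tr.theil_sen(np.nanmean(t2m_ann, axis=(0, 1)))
    top = lc.top_transitions(transition, k=5)
    summary = {
        "config": {"seed": gen.seed, "grid_size": gen.grid_size,
                   "n_years": gen.n_years, "alpha": cfg.alpha},
        "areas_km2": {
            "vegetated": round(float(masks.vegetated.sum() * area), 4),
            "agricultural": round(float(masks.agricultural.sum() * area), 4),
            "natural": round(float(masks.natural.sum() * area), 4),
            "newly_cultivated": round(
                float(masks.newly_cultivated.sum() * area), 4),
        },
        "agri_trends": {
            "n_significant": n_sig,
            "significant_positive_km2": round(n_pos * area, 4),
            "significant_negative_km2": round(n_neg * area, 4),
            "share_positive_pct": round(100.0 * n_pos / n_sig, 2)
            if n_sig else 0.0,
        },
        "warming_trend_k_per_yr": round(float(warming_slope), 6),
        "iranwide_correlations": {
            "%s_vs_%s" % (r.veg_class, r.parameter): round(float(r.r), 4)
            for r in iran_table.itertuples()
        },
        "twsa": {
            "excluded_years": [int(y) for y in twsa_annual.excluded_years],
            "max_basin_share_high_positive_pct": round(float(
                twsa_corr["basin_shares"]["share_high_positive_pct"].max()), 2),
        },
        "irrigation": {
            "mean_initial_intensity_irrigated": round(float(
                np.nanmean(init_int[scene.truth.irrigated
                                    & established_agri])), 2)
            if (scene.truth.irrigated & established_agri).any() else None,
        },
        "top_transitions": [
            {"from": r.from_class, "to": r.to_class,
             "area_km2": round(float(r.area_km2), 4)}
            for r in top.itertuples()
        ],
    }

    result = PipelineResult(
        scene=scene, reconstruction=recon, veg=veg, crop_frac=crop_frac,
        masks=masks, met_annual=met_annual, ai2_monthly_cell=ai2,
        twsa_annual=twsa_annual, trend=trend, basin_shares=basin_shares,
        met_corr=met_corr, irrigation_fields=irr, initial_intensity=init_int,
        twsa_corr=twsa_corr, landcover_stats=lc_stats, transition=transition,
        summary=summary)
    result.elevation_bins = elev_bins
    result.iranwide_table = iran_table
    result.iranwide_z = iran_z
    result.landcover_met_correlation = lc_met
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> Path:
    """Write the summary, manifest and CSV tables; returns the summary path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary_path = outdir / "summary.json"
    summary_path.write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    manifest = {"seed": result.scene.config.seed,
                "config": result.scene.config.to_manifest()}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    result.basin_shares.to_csv(outdir / "basin_trend_shares.csv", index=False)
    result.iranwide_table.to_csv(outdir / "iranwide_correlations.csv",
                                 index=False)
    result.twsa_corr["basin_shares"].to_csv(
        outdir / "twsa_basin_shares.csv", index=False)
    result.landcover_stats.net_rate_km2.to_csv(outdir / "lc_net_rates.csv")
    result.transition.to_csv(outdir / "lc_transition_matrix.csv")
    result.landcover_met_correlation.to_csv(
        outdir / "lc_met_correlation.csv", index=False)
    result.elevation_bins.to_csv(outdir / "trend_by_elevation.csv",
                                 index=False)
    return summary_path
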