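"""Experiment orchestration: estimator comparison, scale transfer, totals.

The central design point is *scale transfer*: calibration models are fitted
once, at the plot-native 44-m support, and then applied unchanged to metric
grids computed at every analysis resolution.  Differences between the
resulting model-based means quantify the aggregation bias of nonlinear
prediction, relative to the 44-m baseline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import BiomassModel, calibrate_strata, fit_power_model
from .estimators import (
    EstimateResult,
    InsufficientSampleError,
    combine_mb,
    empirical_coverage,
    estimate_db,
    estimate_mb,
    estimate_sae,
    fit_sae_working_model,
    sae_inputs_for_scope,
    SAE_PREDICTORS,
)
from .landscape import Landscape, LandscapeConfig, generate_landscape, sample_nfi_plots
from .metrics import MetricGrid, add_plot_metrics, stamp_labels, window_metrics

__all__ = [
    "ExperimentSpec",
    "relative_change",
    "upscale_totals",
    "run_full_experiment",
    "coverage_experiment",
    "mb_scale_replicates",
    "build_metric_grids",
]

COMPARISON_COLUMNS = [
    "method", "scope_type", "scope_id", "scale_m", "mean", "se", "epsilon",
    "rel_se_pct", "ci_low", "ci_high", "n", "N", "area_ha", "total_mg",
    "rel_change_vs_baseline_pct", "flag",
]


@dataclass
class ExperimentSpec:
    """What to run: resolutions, baseline, scopes, confidence, replication."""

    resolutions_m: tuple[float, ...] = (10.0, 25.0, 44.0, 100.0)
    baseline_m: float = 44.0
    confidence: float = 0.95
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_m not in self.resolutions_m:
            raise ValueError(
                f"baseline {self.baseline_m} m must be one of the resolutions "
                f"{self.resolutions_m}"
            )


def relative_change(estimate: float, baseline: float) -> float:
    """Percent change of an estimate over the baseline: 100 (x - x0) / x0."""
    if baseline == 0:
        raise ValueError("baseline estimate is zero; relative change undefined")
    return 100.0 * (estimate - baseline) / baseline


def upscale_totals(
    result: EstimateResult,
    scope_area_ha: float,
    mode: str = "mean_x_area",
    prediction_values: np.ndarray | None = None,
    cell_area_ha: float | None = None,
) -> float:
    """Total stock in Mg for a scope.

    ``mean_x_area`` (DB, SAE): mean times the scope area.  ``pixel_sum``
    (MB): sum of per-window biomass weights, prediction * window area.
    """
    if scope_area_ha <= 0:
        raise ValueError("scope area must be positive")
    if mode == "mean_x_area":
        return result.mean * scope_area_ha
    if mode == "pixel_sum":
        if prediction_values is None or cell_area_ha is None:
            raise ValueError("pixel_sum needs prediction values and a cell area")
        vals = np.asarray(prediction_values, dtype=float)
        return float(np.nansum(vals) * cell_area_ha)
    raise ValueError(f"unknown upscaling mode {mode!r}")


# -------------------------------------------------------------------------
def build_metric_grids(
    landscape: Landscape, resolutions_m: tuple[float, ...]
) -> dict[float, MetricGrid]:
    """Window metrics at every resolution, with stratum/domain labels stamped."""
    grids = {}
    for r in resolutions_m:
        mg = window_metrics(landscape.chm, r)
        stamp_labels(mg, landscape.strata, landscape.domains)
        grids[r] = mg
    return grids


def _scope_masks(mg: MetricGrid) -> list[tuple[str, str, np.ndarray]]:
    """(scope_type, scope_id, window mask) for strata, domains and crossings."""
    strata = mg.label("stratum")
    domains = mg.label("domain")
    out = []
    s_codes = sorted(int(c) for c in np.unique(strata) if c != mg.labels["stratum"].nodata)
    d_codes = sorted(int(c) for c in np.unique(domains) if c != mg.labels["domain"].nodata)
    for s in s_codes:
        out.append(("stratum", str(s), strata == s))
    for d in d_codes:
        out.append(("domain", str(d), domains == d))
    for s in s_codes:
        sm = strata == s
        for d in d_codes:
            mask = sm & (domains == d)
            if mask.any():
                out.append(("stratum_x_domain", f"{s}|{d}", mask))
    return out


def _plot_scope_mask(plots: pd.DataFrame, scope_type: str, scope_id: str) -> pd.Series:
    if scope_type == "stratum":
        return plots["stratum"] == int(scope_id)
    if scope_type == "domain":
        return plots["domain"] == int(scope_id)
    s, d = scope_id.split("|")
    return (plots["stratum"] == int(s)) & (plots["domain"] == int(d))


def _fine_scope_area_ha(landscape: Landscape, scope_type: str, scope_id: str) -> float:
    strata = landscape.strata.values
    domains = landscape.domains.values
    if scope_type == "stratum":
        mask = strata == int(scope_id)
    elif scope_type == "domain":
        mask = domains == int(scope_id)
    else:
        s, d = scope_id.split("|")
        mask = (strata == int(s)) & (domains == int(d))
    return float(mask.sum()) * landscape.chm.cell_area_ha


def _mb_for_scope(
    mg: MetricGrid,
    mask: np.ndarray,
    models: dict[int, BiomassModel],
    confidence: float,
    **scope_kwargs,
) -> EstimateResult:
    """MB estimate for one scope: per-stratum parts combined by unit count."""
    strata = mg.label("stratum")
    codes = sorted(int(c) for c in np.unique(strata[mask]))
    parts = []
    for code in codes:
        m = models.get(code)
        if m is None:
            raise KeyError(f"no biomass model for stratum {code}")
        sub = mask & (strata == code)
        h1 = mg.metric(m.predictors[0])[sub]
        h2 = mg.metric(m.predictors[1])[sub] if len(m.predictors) == 2 else None
        parts.append(estimate_mb(h1, m, h2, confidence=confidence))
    if len(parts) == 1:
        res = parts[0]
        for k, v in scope_kwargs.items():
            setattr(res, k, v)
        return res
    return combine_mb(parts, confidence=confidence, **scope_kwargs)


def _mb_prediction_values(
    mg: MetricGrid, mask: np.ndarray, models: dict[int, BiomassModel]
) -> np.ndarray:
    strata = mg.label("stratum")
    out = np.zeros(int(mask.sum()))
    flat_idx = np.cumsum(mask.ravel()) - 1
    for code in sorted(int(c) for c in np.unique(strata[mask])):
        m = models[code]
        sub = mask & (strata == code)
        h1 = mg.metric(m.predictors[0])[sub]
        h2 = mg.metric(m.predictors[1])[sub] if len(m.predictors) == 2 else None
        out[flat_idx.reshape(mask.shape)[sub]] = m.predict(h1, h2)
    return out


def run_full_experiment(
    spec: ExperimentSpec,
    landscape: Landscape,
    plots: pd.DataFrame,
    models: dict[int, BiomassModel],
    metric_grids: dict[float, MetricGrid] | None = None,
) -> pd.DataFrame:
    """DB and SAE per scope plus MB per scope x resolution, with totals and
    relative changes against the baseline resolution.

    ``plots`` must already carry the metric columns (see
    :func:`chmbiomass.metrics.add_plot_metrics`).  Scopes with fewer than two
    plots yield flagged DB/SAE rows rather than silent drops.
    """
    if metric_grids is None:
        metric_grids = build_metric_grids(landscape, spec.resolutions_m)
    baseline = metric_grids[spec.baseline_m]
    scopes = _scope_masks(baseline)

    beta, beta_cov, residuals = fit_sae_working_model(plots)
    rows: list[dict] = []

    def emit(res: EstimateResult, rel_change=None) -> None:
        d = dataclasses.asdict(res)
        d["rel_change_vs_baseline_pct"] = rel_change
        rows.append(d)

    for scope_type, scope_id, base_mask in scopes:
        area_ha = _fine_scope_area_ha(landscape, scope_type, scope_id)
        sel = _plot_scope_mask(plots, scope_type, scope_id)
        sub = plots[sel]
        kw = dict(scope_type=scope_type, scope_id=scope_id, area_ha=area_ha)

        # design-based
        try:
            db = estimate_db(sub["agbd_mg_ha"].to_numpy(), spec.confidence, **kw)
            db.total_mg = upscale_totals(db, area_ha, "mean_x_area")
        except InsufficientSampleError:
            db = EstimateResult(method="DB", n=len(sub), flag="insufficient", **kw)
        emit(db)

        # small-area
        sae = estimate_sae(
            sae_inputs_for_scope(
                baseline, base_mask, beta, beta_cov, residuals, sub.index
            ),
            spec.confidence,
            **kw,
        )
        if not sae.flag:
            sae.total_mg = upscale_totals(sae, area_ha, "mean_x_area")
        emit(sae)

        # model-based at every resolution, baseline last for the reference mean
        mb_results: dict[float, EstimateResult] = {}
        for r in spec.resolutions_m:
            mg = metric_grids[r]
            mask_r = _resolution_scope_mask(mg, scope_type, scope_id)
            if not mask_r.any():
                emit(EstimateResult(method="MB", scale_m=r, flag="insufficient", **kw))
                continue
            mb = _mb_for_scope(mg, mask_r, models, spec.confidence, scale_m=r, **kw)
            preds = _mb_prediction_values(mg, mask_r, models)
            mb.total_mg = upscale_totals(
                mb, area_ha, "pixel_sum",
                prediction_values=preds, cell_area_ha=mg.cell_area_ha,
            )
            mb_results[r] = mb
        base_mb = mb_results.get(spec.baseline_m)
        for r in spec.resolutions_m:
            if r not in mb_results:
                continue
            rel = (
                relative_change(mb_results[r].mean, base_mb.mean)
                if base_mb is not None and base_mb.mean > 0
                else None
            )
            emit(mb_results[r], rel)

    df = pd.DataFrame(rows)
    return df[COMPARISON_COLUMNS]


def _resolution_scope_mask(mg: MetricGrid, scope_type: str, scope_id: str) -> np.ndarray:
    strata = mg.label("stratum")
    domains = mg.label("domain")
    if scope_type == "stratum":
        return strata == int(scope_id)
    if scope_type == "domain":
        return domains == int(scope_id)
    s, d = scope_id.split("|")
    return (strata == int(s)) & (domains == int(d))


# -------------------------------------------------------------------------
def coverage_experiment(
    config: LandscapeConfig,
    n_replicates: int = 200,
    seed: int = 0,
    methods: tuple[str, ...] = ("DB", "SAE"),
    baseline_m: float = 44.0,
    confidence: float = 0.95,
    min_plots: int = 5,
) -> pd.DataFrame:
    """Empirical CI coverage of DB and SAE per stratum scope.

    One landscape is generated from ``config``; each replicate redraws the
    systematic sample (random grid offset) and the plot measurement noise,
    so coverage is evaluated against the landscape's fixed true means.  The
    DB target is the true stratum mean over fine cells; the SAE target is the
    true mean over the fine cells of the scope's baseline windows (the
    population the estimator actually addresses).
    """
    land = generate_landscape(config)
    rng = np.random.default_rng(seed)

    mg = window_metrics(land.chm, baseline_m)
    stamp_labels(mg, land.strata, land.domains)
    strata_lab = mg.label("stratum")
    nod = mg.labels["stratum"].nodata
    scope_codes = sorted(int(c) for c in np.unique(strata_lab) if c != nod)

    # window-population truth per stratum scope (for SAE)
    k = int(round(baseline_m / land.chm.cell_size))
    from .metrics import _blocks

    truth_win = _blocks(land.truth.true_biomass.values, k).mean(axis=2)
    truth_win = truth_win[: strata_lab.shape[0], : strata_lab.shape[1]]
    sae_truth = {
        c: float(truth_win[strata_lab == c].mean()) for c in scope_codes
    }
    db_truth = {c: land.truth.true_mean("stratum", c) for c in scope_codes}

    cis: dict[tuple[str, int], list[tuple[float, float]]] = {
        (m, c): [] for m in methods for c in scope_codes
    }
    for _ in range(n_replicates):
        plots = sample_nfi_plots(
            land.chm, land.strata, land.domains, land.truth,
            spacing_m=config.plot_spacing_m, radius_m=config.plot_radius_m,
            cover_min=config.cover_min, cover_height_m=config.cover_height_m,
            noise_cv=config.plot_noise_cv, rng=rng,
        )
        if len(plots) < max(min_plots, len(SAE_PREDICTORS) + 3):
            continue
        if "SAE" in methods:
            plots = add_plot_metrics(plots, land.chm, config.plot_radius_m)
            beta, beta_cov, resid = fit_sae_working_model(plots)
        for c in scope_codes:
            sub = plots[plots["stratum"] == c]
            if "DB" in methods and len(sub) >= 2:
                db = estimate_db(sub["agbd_mg_ha"].to_numpy(), confidence)
                cis[("DB", c)].append((db.ci_low, db.ci_high))
            if "SAE" in methods and len(sub) >= 2:
                sae = estimate_sae(
                    sae_inputs_for_scope(
                        mg, strata_lab == c, beta, beta_cov, resid, sub.index
                    ),
                    confidence,
                )
                cis[("SAE", c)].append((sae.ci_low, sae.ci_high))

    records = []
    for (m, c), lst in cis.items():
        if not lst:
            continue
        truth = db_truth[c] if m == "DB" else sae_truth[c]
        cov, cov_se = empirical_coverage(lst, truth)
        records.append(
            {
                "method": m, "scope_type": "stratum", "scope_id": str(c),
                "n_replicates": len(lst), "coverage": cov, "coverage_se": cov_se,
                "true_mean": truth,
            }
        )
    return pd.DataFrame.from_records(records)


def mb_scale_replicates(
    config: LandscapeConfig,
    resolutions_m: tuple[float, ...] = (10.0, 44.0, 100.0),
    n_replicates: int = 50,
    seed: int = 0,
    predictors: tuple[str, ...] = ("h_mean",),
    min_plots: int = 10,
) -> pd.DataFrame:
    """MB mean per resolution over replicate landscapes.

    Each replicate generates a fresh landscape, samples plots, fits the power
    model at the plot support (the 44-m-equivalent baseline) and applies the
    same fitted model to window metrics at every resolution — the scale
    transfer that exposes aggregation bias of nonlinear models.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = dataclasses.replace(config, seed=seed + rep)
        land = generate_landscape(cfg)
        rng = np.random.default_rng(10_000_019 + seed + rep)
        plots = sample_nfi_plots(
            land.chm, land.strata, land.domains, land.truth,
            spacing_m=cfg.plot_spacing_m, radius_m=cfg.plot_radius_m,
            cover_min=cfg.cover_min, cover_height_m=cfg.cover_height_m,
            noise_cv=cfg.plot_noise_cv, rng=rng,
        )
        if len(plots) < min_plots:
            continue
        plots = add_plot_metrics(plots, land.chm, cfg.plot_radius_m)
        needed = tuple(predictors)
        model = fit_power_model(plots, needed, stratum=-1, min_plots=min_plots)
        for r in resolutions_m:
            mg = window_metrics(land.chm, r, metrics=needed)
            h1 = mg.metric(needed[0]).ravel()
            h2 = mg.metric(needed[1]).ravel() if len(needed) == 2 else None
            res = estimate_mb(h1, model, h2)
            rows.append(
                {
                    "replicate": rep, "scale_m": r, "mb_mean": res.mean,
                    "fitted_b": float(model.params[1]), "n_plots": len(plots),
                }
            )
    return pd.DataFrame(rows)


# -- manifests ------------------------------------------------------------
def run_manifest(config: LandscapeConfig, spec: ExperimentSpec) -> dict:
    """A JSON-able record sufficient to re-run the experiment bit-identically."""
    cfg = dataclasses.asdict(config)
    sp = dataclasses.asdict(spec)
    blob = json.dumps({"landscape": cfg, "experiment": sp}, sort_keys=True, default=list)
    return {
        "landscape": cfg,
        "experiment": sp,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "package_version": __version__,
        "numpy_version": np.__version__,
    }
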