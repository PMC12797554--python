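"""Canopy metrics over circular plot footprints and square grid windows.

Metric definitions (identical for plots and windows):

* ``h10`` … ``h99`` — height percentiles of the cells at or above the 2-m
  vegetation threshold, linear interpolation between order statistics.  If no
  cell reaches 2 m every percentile is 0.
* ``h_mean`` — arithmetic mean height over *all* cells in the support (so the
  metric aggregates linearly across nested windows).
* ``fc`` — fraction of cells at or above 2 m (canopy cover predictor).
* ``fc4`` — fraction of cells at or above 4 m (plot-inclusion filter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import _footprint_mask
from .raster import RasterGrid

__all__ = [
    "PERCENTILES",
    "METRIC_NAMES",
    "MetricSet",
    "MetricGrid",
    "plot_metrics",
    "window_metrics",
    "stamp_labels",
    "add_plot_metrics",
]

PERCENTILES = (10, 20, 25, 30, 40, 50, 99)
HEIGHT_METRICS = tuple(f"h{p}" for p in PERCENTILES) + ("h_mean",)
METRIC_NAMES = HEIGHT_METRICS + ("fc", "fc4")

COVER_THRESHOLD_M = 2.0
COVER4_THRESHOLD_M = 4.0


@dataclass
class MetricSet:
    """Canopy metrics for a single support (plot footprint or window)."""

    values: dict[str, float]
    n_cells: int

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


@dataclass
class MetricGrid:
    """Co-registered per-metric rasters at one analysis resolution."""

    resolution_m: float
    grids: dict[str, RasterGrid]
    labels: dict[str, RasterGrid] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.grids.values()))
        return first.values.shape

    @property
    def cell_area_ha(self) -> float:
        return self.resolution_m**2 / 10_000.0

    def metric(self, name: str) -> np.ndarray:
        return self.grids[name].values

    def label(self, name: str) -> np.ndarray:
        if name not in self.labels:
            raise KeyError(f"labels '{name}' not stamped on this grid")
        return self.labels[name].values


def _metrics_from_heights(h: np.ndarray) -> dict[str, float]:
    h = np.asarray(h, dtype=float)
    veg = h[h >= COVER_THRESHOLD_M]
    out: dict[str, float] = {}
    if veg.size:
        qs = np.percentile(veg, PERCENTILES)
        for p, q in zip(PERCENTILES, qs):
            out[f"h{p}"] = float(q)
    else:
        for p in PERCENTILES:
            out[f"h{p}"] = 0.0
    out["h_mean"] = float(h.mean())
    out["fc"] = float(np.mean(h >= COVER_THRESHOLD_M))
    out["fc4"] = float(np.mean(h >= COVER4_THRESHOLD_M))
    return out


def plot_metrics(chm: RasterGrid, center: tuple[float, float], radius_m: float) -> MetricSet:
    """Metrics over fine cells whose centres fall inside the circular footprint."""
    cx, cy = center
    x0, y0 = chm.origin
    if (
        cx - radius_m < x0
        or cx + radius_m > x0 + chm.width_m
        or cy - radius_m < y0
        or cy + radius_m > y0 + chm.height_m
    ):
        raise ValueError(
            f"plot footprint at ({cx}, {cy}) r={radius_m} m extends off the raster"
        )
    rs, cs, mask = _footprint_mask(chm, cx, cy, radius_m)
    h = chm.values[rs, cs][mask]
    return MetricSet(_metrics_from_heights(h), n_cells=int(h.size))


def _blocks(values: np.ndarray, k: int) -> np.ndarray:
    """Reshape (R*k, C*k) -> (R, C, k*k), dropping partial edge windows."""
    nr, nc = values.shape
    R, C = nr // k, nc // k
    v = values[: R * k, : C * k]
    return v.reshape(R, k, C, k).swapaxes(1, 2).reshape(R, C, k * k)


def window_metrics(
    chm: RasterGrid,
    resolution_m: float,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> MetricGrid:
    """Tile the CHM with square windows of side ``resolution_m`` and compute metrics.

    The window side must be a whole multiple of the fine cell size; partial
    windows at the north/east edges are dropped.
    """
    cell = chm.cell_size
    k_f = resolution_m / cell
    k = int(round(k_f))
    if abs(k_f - k) > 1e-9 or k < 1:
        raise ValueError(
            f"resolution {resolution_m} m is not representable on the "
            f"{cell}-m fine grid"
        )
    blocks = _blocks(chm.values.astype(float), k)
    R, C = blocks.shape[:2]

    out: dict[str, RasterGrid] = {}

    def grid(arr: np.ndarray) -> RasterGrid:
        return RasterGrid(chm.origin, resolution_m, arr)

    wanted_percentiles = [p for p in PERCENTILES if f"h{p}" in metrics]
    if wanted_percentiles:
        veg = np.where(blocks >= COVER_THRESHOLD_M, blocks, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            qs = np.nanpercentile(veg, wanted_percentiles, axis=2)
        qs = np.nan_to_num(qs, nan=0.0)
        for i, p in enumerate(wanted_percentiles):
            out[f"h{p}"] = grid(qs[i])
    if "h_mean" in metrics:
        out["h_mean"] = grid(blocks.mean(axis=2))
    if "fc" in metrics:
        out["fc"] = grid((blocks >= COVER_THRESHOLD_M).mean(axis=2))
    if "fc4" in metrics:
        out["fc4"] = grid((blocks >= COVER4_THRESHOLD_M).mean(axis=2))
    return MetricGrid(resolution_m, out)


def _majority_labels(labels: np.ndarray, k: int, nodata: int) -> np.ndarray:
    """Majority label per k x k window; ties broken by the smallest code."""
    blocks = _blocks(labels, k)
    codes = np.unique(labels)
    codes = np.sort(codes[codes != nodata])
    counts = np.stack([(blocks == c).sum(axis=2) for c in codes])
    best = np.argmax(counts, axis=0)  # argmax takes the first (smallest) code on ties
    out = codes[best].astype(np.int16)
    out[counts.max(axis=0) == 0] = nodata
    return out


def stamp_labels(
    metric_grid: MetricGrid, strata: RasterGrid, domains: RasterGrid
) -> MetricGrid:
    """Attach majority stratum/domain labels to every window of a metric grid."""
    first = next(iter(metric_grid.grids.values()))
    k = int(round(metric_grid.resolution_m / strata.cell_size))
    strata.require_same_grid(domains, "domain raster")
    for name, lab in (("stratum", strata), ("domain", domains)):
        nod = int(lab.nodata) if lab.nodata is not None else -1
        maj = _majority_labels(lab.values, k, nod)[: first.n_rows, : first.n_cols]
        metric_grid.labels[name] = RasterGrid(
            first.origin, metric_grid.resolution_m, maj, nodata=nod
        )
    return metric_grid


def add_plot_metrics(
    plots: pd.DataFrame, chm: RasterGrid, radius_m: float
) -> pd.DataFrame:
    """Append the metric columns (h10 … fc4) to a plot table."""
    records = []
    for row in plots.itertuples(index=False):
        try:
            ms = plot_metrics(chm, (row.x, row.y), radius_m)
        except ValueError as exc:
            raise ValueError(f"plot {row.plot_id}: {exc}") from exc
        records.append(ms.as_dict())
    metrics_df = pd.DataFrame(records, index=plots.index, columns=list(METRIC_NAMES))
    return pd.concat([plots, metrics_df], axis=1)
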