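"""Design-based, model-based and small-area estimators of mean biomass.

Three inference engines share one result type:

* DB — the sample mean with the simple-random-sampling variance ``s2/n``
  (conservative for systematic samples) and Student-t intervals.
* MB — the mean of model predictions over every population unit (grid
  window), with a delta-method standard error driven entirely by the fitted
  parameter covariance.  The quadratic double sum over units factorises as
  ``(sum Z)' Sigma (sum Z)``, which is what is implemented; the explicit
  O(N^2) form is kept in the test suite as an oracle.
* SAE — a two-phase (exhaustive first phase) regression estimator: a working
  linear model fitted on the full plot set, applied to the exhaustive
  auxiliary mean of the small area, plus a local mean-residual correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import BiomassModel
from .metrics import MetricGrid
from .raster import RasterGrid

__all__ = [
    "EstimateResult",
    "SaeInputs",
    "InsufficientSampleError",
    "estimate_db",
    "predict_map",
    "estimate_mb",
    "combine_mb",
    "estimate_sae",
    "fit_sae_working_model",
    "sae_inputs_for_scope",
    "empirical_coverage",
]

SAE_PREDICTORS = ("h99", "h_mean", "fc")


class InsufficientSampleError(ValueError):
    """Fewer plots than the estimator requires."""


@dataclass
class EstimateResult:
    """A (method, scope, scale) estimate of mean biomass with uncertainty."""

    method: str                      # "DB" | "MB" | "SAE"
    scope_type: str = ""
    scope_id: str = ""
    scale_m: float | None = None     # MB only
    mean: float = float("nan")
    se: float = float("nan")
    epsilon: float = float("nan")    # CI half-width = t * se
    rel_se_pct: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n: int | None = None             # plots
    N: int | None = None             # population units
    area_ha: float | None = None
    total_mg: float | None = None
    flag: str = ""                   # "", "insufficient", "no_variance"

    def finalize(self, t_crit: float) -> "EstimateResult":
        """Fill epsilon / relative SE / CI from mean, se and a t critical value."""
        self.epsilon = t_crit * self.se
        self.ci_low = self.mean - self.epsilon
        self.ci_high = self.mean + self.epsilon
        if self.mean > 0:
            self.rel_se_pct = 100.0 * self.epsilon / self.mean
        return self

    def covers(self, true_mean: float) -> bool:
        return self.ci_low <= true_mean <= self.ci_high


def _t_crit(df: int, confidence: float) -> float:
    return float(sps.t.ppf(0.5 + confidence / 2.0, df))


# -- design-based ---------------------------------------------------------
def estimate_db(
    y: np.ndarray, confidence: float = 0.95, **scope_kwargs
) -> EstimateResult:
    """Sample mean with SRS variance and a Student-t confidence interval."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise InsufficientSampleError(
            f"design-based estimate needs n >= 2 plots, got {n}"
        )
    mean = float(y.mean())
    s2 = float(((y - mean) ** 2).sum() / (n - 1))
    se = math.sqrt(s2 / n)
    res = EstimateResult(method="DB", mean=mean, se=se, n=n, **scope_kwargs)
    return res.finalize(_t_crit(n - 1, confidence))


# -- model-based ----------------------------------------------------------
def predict_map(
    metric_grid: MetricGrid,
    models: dict[int, BiomassModel],
    nodata: float = np.nan,
) -> RasterGrid:
    """Per-window biomass prediction using each window's stratum model.

    Windows whose first predictor is 0 predict 0; windows with a nodata
    stratum label propagate nodata.
    """
    strata = metric_grid.label("stratum")
    first = next(iter(metric_grid.grids.values()))
    lab_nodata = metric_grid.labels["stratum"].nodata
    codes = np.unique(strata)
    codes = codes[codes != lab_nodata] if lab_nodata is not None else codes
    missing = [int(c) for c in codes if int(c) not in models]
    if missing:
        raise KeyError(f"no biomass model for stratum codes {missing}")
    pred = np.full(strata.shape, nodata, dtype=float)
    for code in codes:
        m = models[int(code)]
        mask = strata == code
        h1 = metric_grid.metric(m.predictors[0])[mask]
        h2 = metric_grid.metric(m.predictors[1])[mask] if len(m.predictors) == 2 else None
        pred[mask] = m.predict(h1, h2)
    return RasterGrid(first.origin, metric_grid.resolution_m, pred, nodata=nodata)


def estimate_mb(
    h1: np.ndarray,
    model: BiomassModel,
    h2: np.ndarray | None = None,
    confidence: float = 0.95,
    **scope_kwargs,
) -> EstimateResult:
    """Model-based mean over N population units with a delta-method SE.

    ``SE = sqrt((1/N^2) (sum_i Z_i)' Sigma (sum_j Z_j))`` where Z_i is the
    gradient of the prediction at unit i w.r.t. the model parameters.
    """
    if model.cov is None or not np.all(np.isfinite(model.cov)):
        raise ValueError("model parameter covariance is missing or non-finite")
    h1 = np.asarray(h1, dtype=float)
    N = h1.size
    if N < 1:
        raise InsufficientSampleError("model-based estimate needs N >= 1 units")
    pred = model.predict(h1, h2)
    Zsum = model.gradients(h1, h2).sum(axis=0)
    var = float(Zsum @ model.cov @ Zsum) / (N * N)
    res = EstimateResult(
        method="MB",
        mean=float(pred.mean()),
        se=math.sqrt(max(var, 0.0)),
        N=N,
        **scope_kwargs,
    )
    df = max(N - 1, 1)
    return res.finalize(_t_crit(df, confidence))


def combine_mb(
    parts: list[EstimateResult], confidence: float = 0.95, **scope_kwargs
) -> EstimateResult:
    """Combine per-stratum MB estimates into one scope estimate.

    The scope mean is the unit-count-weighted mean; the variance assumes
    independent parameter estimates across strata (models are fitted on
    disjoint plot sets): ``Var = sum w_s^2 Var_s``.
    """
    if not parts:
        raise InsufficientSampleError("no stratum parts to combine")
    Ns = np.array([p.N for p in parts], dtype=float)
    w = Ns / Ns.sum()
    mean = float(np.sum(w * np.array([p.mean for p in parts])))
    var = float(np.sum(w**2 * np.array([p.se for p in parts]) ** 2))
    N = int(Ns.sum())
    res = EstimateResult(
        method="MB", mean=mean, se=math.sqrt(var), N=N, **scope_kwargs
    )
    return res.finalize(_t_crit(max(N - 1, 1), confidence))


# -- small-area -----------------------------------------------------------
@dataclass
class SaeInputs:
    """Everything the two-phase small-area estimator needs for one scope."""

    x_bar: np.ndarray                 # exhaustive auxiliary mean, incl. leading 1
    beta: np.ndarray                  # working-model coefficients (full sample)
    beta_cov: np.ndarray              # coefficient covariance
    residuals: np.ndarray             # working-model residuals of the scope's plots
    x_bar_cov: np.ndarray | None = None  # zero when the first phase is exhaustive

    def __post_init__(self) -> None:
        self.x_bar = np.asarray(self.x_bar, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.beta_cov = np.asarray(self.beta_cov, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.x_bar.size != self.beta.size:
            raise ValueError("x_bar and beta must have equal length")

    @property
    def n_2g(self) -> int:
        return self.residuals.size


def estimate_sae(
    inputs: SaeInputs, confidence: float = 0.95, **scope_kwargs
) -> EstimateResult:
    """Two-phase small-area estimate for one scope.

    mean = x_bar' beta + mean(residuals in scope); the variance sums a
    coefficient-covariance term, an auxiliary-mean term (zero under an
    exhaustive first phase) and the residual term ``s2_e / n_2G``.
    """
    n = inputs.n_2g
    synthetic = float(inputs.x_bar @ inputs.beta)
    if n == 0:
        res = EstimateResult(
            method="SAE", mean=synthetic, n=0, flag="no_variance", **scope_kwargs
        )
        return res
    mean = synthetic + float(inputs.residuals.mean())
    if n == 1:
        return EstimateResult(
            method="SAE", mean=mean, n=1, flag="no_variance", **scope_kwargs
        )
    var = float(inputs.x_bar @ inputs.beta_cov @ inputs.x_bar)
    if inputs.x_bar_cov is not None:
        var += float(inputs.beta @ inputs.x_bar_cov @ inputs.beta)
    s2e = float(np.var(inputs.residuals, ddof=1))
    var += s2e / n
    res = EstimateResult(
        method="SAE", mean=mean, se=math.sqrt(var), n=n, **scope_kwargs
    )
    return res.finalize(_t_crit(n - 1, confidence))


def fit_sae_working_model(
    plots: pd.DataFrame, predictors: tuple[str, ...] = SAE_PREDICTORS
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """OLS working model on the full second-phase plot set.

    Returns ``(beta, beta_cov, residuals)`` with residuals indexed like the
    plot table so scope subsets can be selected later.
    """
    n = len(plots)
    p = len(predictors) + 1
    if n < p + 2:
        raise InsufficientSampleError(
            f"working model needs at least {p + 2} plots, got {n}"
        )
    X = np.column_stack(
        [np.ones(n)] + [plots[c].to_numpy(dtype=float) for c in predictors]
    )
    y = plots["agbd_mg_ha"].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"rank-deficient working-model design (rank {rank} < {p})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - p)
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta, cov, pd.Series(resid, index=plots.index)


def sae_inputs_for_scope(
    metric_grid: MetricGrid,
    scope_mask: np.ndarray,
    beta: np.ndarray,
    beta_cov: np.ndarray,
    residuals: pd.Series,
    scope_plot_index: pd.Index,
    predictors: tuple[str, ...] = SAE_PREDICTORS,
) -> SaeInputs:
    """Assemble SAE inputs: exhaustive auxiliary means over the scope's windows
    plus the residuals of the plots falling in the scope."""
    if not scope_mask.any():
        raise ValueError("scope has no population units")
    x_bar = np.concatenate(
        [[1.0], [metric_grid.metric(c)[scope_mask].mean() for c in predictors]]
    )
    return SaeInputs(
        x_bar=x_bar,
        beta=beta,
        beta_cov=beta_cov,
        residuals=residuals.loc[scope_plot_index].to_numpy(),
    )


# -- empirical CI coverage ------------------------------------------------
def empirical_coverage(
    replicate_cis: list[tuple[float, float]], true_mean: float
) -> tuple[float, float]:
    """Proportion of replicate CIs containing the true mean, with binomial SE."""
    n = len(replicate_cis)
    if n < 1:
        raise ValueError("need at least one replicate")
    hits = sum(1 for lo, hi in replicate_cis if lo <= true_mean <= hi)
    p = hits / n
    return p, math.sqrt(p * (1 - p) / n)
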