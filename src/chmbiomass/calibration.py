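"""Per-stratum power-law biomass calibration.

Model form: ``AGBD = a * h1**b * h2**c`` with ``h1`` a height metric and
``h2`` (optional) a cover fraction.  Fits are plain nonlinear least squares
started from the log-log linearisation, with the parameter covariance taken
as ``s2 * (J'J)^-1`` at the solution.

Plots with ``h1 == 0`` (or ``h2 == 0`` for two-predictor models) are excluded
from fitting — the power model is undefined at zero under the log start — and
prediction at such supports is defined as 0 Mg/ha.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "BiomassModel",
    "FitError",
    "fit_power_model",
    "select_predictors",
    "vif",
    "fit_statistics",
    "save_models",
    "load_models",
]

HEIGHT_CANDIDATES = ("h10", "h20", "h25", "h30", "h40", "h50", "h99", "h_mean")
COVER_CANDIDATES = ("fc",)

VIF_LIMIT = 10.0
MIN_PLOTS = 10
MAX_ITER = 200


class FitError(RuntimeError):
    """Nonlinear fit failed (non-convergence or singular normal matrix)."""


@dataclass
class BiomassModel:
    """A fitted (or fixed) power-law calibration for one stratum."""

    stratum: int
    predictors: tuple[str, ...]  # ("h50", "fc") or ("h50",)
    params: np.ndarray           # (a, b[, c])
    cov: np.ndarray              # parameter covariance, k x k
    n_plots: int = 0
    rmse: float = float("nan")
    rmse_pct: float = float("nan")
    bias_pct: float = float("nan")
    adj_r2: float = float("nan")

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        k = len(self.predictors) + 1
        if self.params.size != k:
            raise ValueError(f"expected {k} parameters, got {self.params.size}")
        if self.cov.shape != (k, k):
            raise ValueError(f"covariance must be {k}x{k}")
        if self.params[0] <= 0:
            raise ValueError("coefficient a must be positive")

    @property
    def k_params(self) -> int:
        return self.params.size

    def predict(self, h1: np.ndarray, h2: np.ndarray | None = None) -> np.ndarray:
        """Predicted AGBD; supports with h1 == 0 (or h2 == 0) predict 0."""
        h1 = np.asarray(h1, dtype=float)
        a, b = self.params[0], self.params[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            pred = a * np.power(h1, b)
            if len(self.predictors) == 2:
                if h2 is None:
                    raise ValueError("model has two predictors; h2 required")
                h2 = np.asarray(h2, dtype=float)
                pred = pred * np.power(h2, self.params[2])
                pred = np.where((h1 <= 0) | (h2 <= 0), 0.0, pred)
            else:
                pred = np.where(h1 <= 0, 0.0, pred)
        return pred

    def gradients(self, h1: np.ndarray, h2: np.ndarray | None = None) -> np.ndarray:
        """Per-support gradient of the prediction w.r.t. (a, b[, c]).

        Shape ``(n, k)``.  Supports predicting 0 contribute a zero gradient.
        """
        h1 = np.asarray(h1, dtype=float)
        f = self.predict(h1, h2)
        a = self.params[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            cols = [np.where(f > 0, f / a, 0.0), np.where(f > 0, f * np.log(h1), 0.0)]
            if len(self.predictors) == 2:
                cols.append(np.where(f > 0, f * np.log(np.asarray(h2, float)), 0.0))
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "predictors": list(self.predictors),
            "params": self.params.tolist(),
            "cov": self.cov.ravel().tolist(),
            "n": self.n_plots,
            "rmse": self.rmse,
            "rmse_pct": self.rmse_pct,
            "bias_pct": self.bias_pct,
            "adj_r2": self.adj_r2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiomassModel":
        k = len(d["params"])
        return cls(
            stratum=int(d["stratum"]),
            predictors=tuple(d["predictors"]),
            params=np.array(d["params"]),
            cov=np.array(d["cov"]).reshape(k, k),
            n_plots=int(d.get("n", 0)),
            rmse=float(d.get("rmse", float("nan"))),
            rmse_pct=float(d.get("rmse_pct", float("nan"))),
            bias_pct=float(d.get("bias_pct", float("nan"))),
            adj_r2=float(d.get("adj_r2", float("nan"))),
        )


# -------------------------------------------------------------------------
def fit_statistics(
    observed: np.ndarray, predicted: np.ndarray, k_params: int
) -> dict[str, float]:
    """RMSE, RMSE%, bias% and adjusted pseudo-R2 of a calibration.

    bias% is signed so that positive values mean overprediction
    (predicted > observed).
    """
    y = np.asarray(observed, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    if y.shape != yh.shape:
        raise ValueError("observed and predicted must have equal length")
    n = y.size
    if n <= k_params:
        raise ValueError(f"need n > k_params, got n={n}, k={k_params}")
    ybar = y.mean()
    if ybar == 0:
        raise ValueError("mean of observed values is zero; relative statistics undefined")
    resid = y - yh
    sse = float(resid @ resid)
    rmse = float(np.sqrt(sse / n))
    sst = float(((y - ybar) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k_params - 1)
    return {
        "rmse": rmse,
        "rmse_pct": 100.0 * rmse / ybar,
        "bias_pct": 100.0 * float((yh - y).sum()) / (n * ybar),
        "adj_r2": adj,
    }


def vif(columns: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column of a design matrix.

    ``VIF_k = 1 / (1 - R2_k)`` where ``R2_k`` comes from regressing column k
    on the remaining columns (with intercept).  Perfectly collinear columns
    report ``+inf``.
    """
    X = np.asarray(columns, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D design with at least 2 columns")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    out = np.empty(X.shape[1])
    for k in range(X.shape[1]):
        y = X[:, k]
        if np.allclose(y, y[0]):
            raise ValueError(f"column {k} is constant; VIF undefined")
        others = np.delete(X, k, axis=1)
        A = np.column_stack([np.ones(X.shape[0]), others])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / sst
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _fit_data(
    plots: pd.DataFrame, predictors: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    y = plots["agbd_mg_ha"].to_numpy(dtype=float)
    h1 = plots[predictors[0]].to_numpy(dtype=float)
    h2 = plots[predictors[1]].to_numpy(dtype=float) if len(predictors) == 2 else None
    keep = h1 > 0  # power model undefined at zero predictors; response may be any real
    if h2 is not None:
        keep &= h2 > 0
    return y[keep], h1[keep], (h2[keep] if h2 is not None else None)


def fit_power_model(
    plots: pd.DataFrame,
    predictors: tuple[str, ...],
    stratum: int | None = None,
    min_plots: int = MIN_PLOTS,
) -> BiomassModel:
    """Nonlinear least-squares fit of ``a * h1**b [* h2**c]`` for one stratum.

    Start values come from OLS on the log-log linearisation; the covariance is
    ``s2 (J'J)^-1`` with J the Jacobian at the solution.
    """
    if stratum is None:
        strat_vals = plots["stratum"].unique()
        stratum = int(strat_vals[0]) if len(strat_vals) == 1 else -1
    y, h1, h2 = _fit_data(plots, predictors)
    n = y.size
    if n < min_plots:
        raise FitError(
            f"stratum {stratum}: only {n} usable plots (need >= {min_plots})"
        )

    # log-log OLS start, computed on the positive-response subset
    pos = y > 0
    if pos.sum() < 3:
        raise FitError(f"stratum {stratum}: fewer than 3 positive responses")
    logs = [np.ones(int(pos.sum())), np.log(h1[pos])]
    if h2 is not None:
        logs.append(np.log(h2[pos]))
    L = np.column_stack(logs)
    start, *_ = np.linalg.lstsq(L, np.log(y[pos]), rcond=None)
    x0 = np.concatenate([[np.exp(start[0])], start[1:]])

    def model(theta: np.ndarray) -> np.ndarray:
        f = theta[0] * np.power(h1, theta[1])
        if h2 is not None:
            f = f * np.power(h2, theta[2])
        return f

    def resid(theta: np.ndarray) -> np.ndarray:
        return model(theta) - y

    def jac(theta: np.ndarray) -> np.ndarray:
        f = model(theta)
        cols = [f / theta[0], f * np.log(h1)]
        if h2 is not None:
            cols.append(f * np.log(h2))
        return np.column_stack(cols)

    sol = optimize.least_squares(
        resid, x0, jac=jac, method="lm", max_nfev=MAX_ITER * (x0.size + 1)
    )
    if not sol.success:
        raise FitError(
            f"stratum {stratum}: nonlinear fit did not converge from start {x0} "
            f"({sol.message})"
        )
    theta = sol.x
    J = jac(theta)
    k = theta.size
    JtJ = J.T @ J
    try:
        JtJ_inv = np.linalg.inv(JtJ)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"stratum {stratum}: singular J'J at the solution") from exc
    s2 = float(sol.fun @ sol.fun) / (n - k)
    cov = s2 * JtJ_inv
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry

    stats = fit_statistics(y, model(theta), k)
    return BiomassModel(
        stratum=stratum,
        predictors=predictors,
        params=theta,
        cov=cov,
        n_plots=n,
        **stats,
    )


def select_predictors(
    plots: pd.DataFrame,
    candidate_heights: tuple[str, ...] = HEIGHT_CANDIDATES,
    candidate_covers: tuple[str, ...] = COVER_CANDIDATES,
    stratum: int | None = None,
    vif_limit: float = VIF_LIMIT,
    min_plots: int = MIN_PLOTS,
) -> tuple[str, ...]:
    """Exhaustive two-predictor search with a VIF screen.

    Every (height, cover) pair whose log-log design passes ``VIF <= limit``
    is fitted with the nonlinear model; the winner is the pair with the lowest
    RMSE.  If no pair survives (or none fits), the best single height
    predictor is returned instead.
    """
    if len(candidate_heights) + len(candidate_covers) < 1:
        raise ValueError("need at least one candidate predictor")
    best: tuple[float, tuple[str, ...]] | None = None
    for h, c in itertools.product(candidate_heights, candidate_covers):
        y, h1, h2 = _fit_data(plots, (h, c))
        if y.size < max(min_plots, 3):
            continue
        try:
            v = vif(np.column_stack([np.log(h1), np.log(h2)]))
        except ValueError:
            continue
        if np.any(v > vif_limit):
            continue
        try:
            m = fit_power_model(plots, (h, c), stratum=stratum, min_plots=min_plots)
        except FitError:
            continue
        if best is None or m.rmse < best[0]:
            best = (m.rmse, (h, c))
    if best is not None:
        return best[1]
    for h in candidate_heights:
        try:
            m = fit_power_model(plots, (h,), stratum=stratum, min_plots=min_plots)
        except FitError:
            continue
        if best is None or m.rmse < best[0]:
            best = (m.rmse, (h,))
    if best is None:
        raise FitError(
            f"stratum {stratum}: no fittable predictor combination "
            f"(usable plots below the minimum of {min_plots}?)"
        )
    return best[1]


def calibrate_strata(
    plots: pd.DataFrame,
    candidate_heights: tuple[str, ...] = HEIGHT_CANDIDATES,
    candidate_covers: tuple[str, ...] = COVER_CANDIDATES,
    min_plots: int = MIN_PLOTS,
) -> dict[int, BiomassModel]:
    """Select predictors and fit one model per stratum present in the table."""
    models: dict[int, BiomassModel] = {}
    for code, grp in plots.groupby("stratum"):
        code = int(code)
        preds = select_predictors(
            grp, candidate_heights, candidate_covers, stratum=code, min_plots=min_plots
        )
        models[code] = fit_power_model(grp, preds, stratum=code, min_plots=min_plots)
    return models


# -- persistence ----------------------------------------------------------
def save_models(models: dict[int, BiomassModel], path: str | Path) -> Path:
    path = Path(path)
    payload = [models[k].to_dict() for k in sorted(models)]
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_models(path: str | Path) -> dict[int, BiomassModel]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for d in payload:
        m = BiomassModel.from_dict(d)
        out[m.stratum] = m
    return out
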