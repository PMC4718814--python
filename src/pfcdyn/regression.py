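"""Sliding-window OLS of task variables onto firing and LFP, and the CPD.

The coefficient of partial determination of a factor X_i in a model with
regressor set X is

    CPD(X_i) = [SSE(X_without_i) - SSE(X)] / SSE(X_without_i),

the fraction of residual variance uniquely explained by the factor. For a
single-column factor it equals the squared partial correlation. Fits are
ordinary least squares with classical standard errors; the same design is
solved once and applied to every timebin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .containers import BinnedRates, LFPArray, RegressionResult, SpikeRaster
from .synthetic import zscore


def bin_rates(
    raster: SpikeRaster, bin_width_ms: float = 200.0, step_ms: float = 10.0
) -> BinnedRates:
    """Boxcar firing-rate estimate: spike count in each sliding window
    divided by the window width, in Hz."""
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = raster.window_ms
    centers = np.arange(lo + bin_width_ms / 2.0, hi - bin_width_ms / 2.0 + 1e-9, step_ms)
    starts = centers - bin_width_ms / 2.0
    stops = centers + bin_width_ms / 2.0
    rates = np.empty((raster.n_trials, centers.size))
    for i, spk in enumerate(raster.spikes):
        counts = np.searchsorted(spk, stops) - np.searchsorted(spk, starts)
        rates[i] = counts / (bin_width_ms / 1000.0)
    return BinnedRates(
        rates=rates,
        bin_centers_ms=centers,
        bin_width_ms=bin_width_ms,
        unit_id=raster.unit_id,
        region=raster.region,
        session_id=raster.session_id,
        trial_ids=raster.trial_ids,
    )


@dataclass
class OLSFit:
    """OLS estimates for (possibly) many responses sharing one design.

    ``coef``/``se``/``z`` have shape (n_responses, p); ``sse`` has shape
    (n_responses,). Single-vector input yields n_responses = 1.
    """

    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    sse: np.ndarray
    dof: int


def ols(y: np.ndarray, X: np.ndarray, names=None, allow_rank_deficient: bool = False) -> OLSFit:
    """Ordinary least squares with classical standard errors.

    ``y`` may be a vector (one response) or a (n_trials, n_responses)
    matrix; the design is factored once. Rank-deficient designs raise,
    naming the offending columns when ``names`` is given — unless
    ``allow_rank_deficient``, in which case the minimum-norm solution is
    used (SSE remains well defined; SEs and Z are NaN).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Y = y[:, None] if y.ndim == 1 else y
    if X.shape[0] != Y.shape[0]:
        raise ValueError("rows of X must match length of y")
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        if not allow_rank_deficient:
            # flag columns that add no rank over the columns before them
            ranks = [np.linalg.matrix_rank(X[:, : j + 1]) for j in range(p)]
            bad = [
                (names[j] if names else j)
                for j in range(p)
                if ranks[j] == (ranks[j - 1] if j else 0)
            ]
            raise np.linalg.LinAlgError(
                f"rank deficient design; collinear columns: {bad}"
            )
        beta = np.linalg.pinv(X) @ Y
        resid = Y - X @ beta
        sse = (resid**2).sum(axis=0)
        nan = np.full_like(beta, np.nan)
        return OLSFit(coef=beta.T, se=nan.T, z=nan.T, sse=sse, dof=n - rank)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    sse = (resid**2).sum(axis=0)
    dof = n - p
    sigma2 = sse / dof if dof > 0 else np.full_like(sse, np.nan)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    return OLSFit(coef=beta.T, se=se.T, z=z.T, sse=sse, dof=dof)


def cpd(y: np.ndarray, X_full: np.ndarray, factor_columns) -> np.ndarray:
    """Coefficient of partial determination of one factor.

    ``factor_columns`` indexes the columns of ``X_full`` belonging to the
    factor; the reduced model drops exactly those columns. Returns a value
    per response column of ``y`` (scalar response gives a length-1 array).
    NaN is returned where the reduced model already fits perfectly.
    """
    factor_columns = np.atleast_1d(factor_columns)
    keep = np.setdiff1d(np.arange(X_full.shape[1]), factor_columns)
    sse_full = ols(y, X_full, allow_rank_deficient=True).sse
    sse_red = ols(y, X_full[:, keep], allow_rank_deficient=True).sse
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (sse_red - sse_full) / sse_red
    out = np.where(sse_red == 0, np.nan, out)
    return np.clip(out, 0.0, 1.0)


def decision_design(trials: pd.DataFrame, zscore_values: bool = True):
    """The five-variable decision model: a constant per trial type, the
    left-minus-right value difference, the chosen action (+1 = left), and
    the chosen value.

    Returns ``(X, names, factors)`` where ``factors`` maps the three
    substantive factor names to their column indices. Value regressors are
    z-scored by default so coefficients are comparable across units and
    electrodes. An all-one-type session drops the empty constant with a
    warning.
    """
    eff = (trials["trial_type"] == "effort").to_numpy(float)
    del_ = (trials["trial_type"] == "delay").to_numpy(float)
    dv = (trials["value_left"] - trials["value_right"]).to_numpy(float)
    choice = np.where(trials["chosen_side"] == "L", 1.0, -1.0)
    cv = trials["chosen_value"].to_numpy(float)
    if zscore_values:
        dv, cv = zscore(dv), zscore(cv)
    cols = {"const_effort": eff, "const_delay": del_}
    for name in list(cols):
        if cols[name].sum() == 0:
            warnings.warn(f"no trials of type for {name}; dropping constant", stacklevel=2)
            del cols[name]
    cols.update({"value_diff": dv, "choice": choice, "chosen_value": cv})
    names = list(cols)
    X = np.column_stack(list(cols.values()))
    factors = {
        f: [names.index(f)] for f in ("value_diff", "choice", "chosen_value")
    }
    return X, names, factors


def regression_result(
    Y: np.ndarray, X: np.ndarray, names, factors, bin_centers_ms
) -> RegressionResult:
    """Fit every timebin of ``Y`` (trials x bins) against ``X`` and compute
    per-factor CPD timecourses."""
    fit = ols(Y, X, names)
    cpds = {f: cpd(Y, X, cols) for f, cols in factors.items()}
    return RegressionResult(
        coef=fit.coef,
        z=fit.z,
        sse=fit.sse,
        cpd=cpds,
        factor_names=names,
        bin_centers_ms=np.asarray(bin_centers_ms),
        n_trials=Y.shape[0],
    )


def unit_decision_model(
    rates: BinnedRates, trials: pd.DataFrame, zscore_values: bool = True
) -> RegressionResult:
    """Sliding-window regression of the decision model onto one unit's
    binned firing, with CPD timecourses for value difference, chosen action
    and chosen value."""
    if rates.n_trials != len(trials):
        raise ValueError("rates and trial table are misaligned")
    X, names, factors = decision_design(trials, zscore_values)
    return regression_result(rates.rates, X, names, factors, rates.bin_centers_ms)


def lfp_value_regression(arrays, trials: pd.DataFrame, zscore_values: bool = True):
    """Regress the evoked signal at each timepoint onto chosen and unchosen
    value, per electrode.

    Returns ``(z, mean_z, se_z, time_ms)`` where ``z`` has shape
    (n_electrodes, n_timepoints, 2) holding the Z-scored coefficients of
    chosen then unchosen value, and mean/se aggregate across electrodes.
    """
    if isinstance(arrays, LFPArray):
        arrays = [arrays]
    cv = trials["chosen_value"].to_numpy(float)
    uv = trials["unchosen_value"].to_numpy(float)
    if zscore_values:
        cv, uv = zscore(cv), zscore(uv)
    X = np.column_stack([np.ones(len(trials)), cv, uv])
    zs = []
    for arr in arrays:
        if arr.n_trials != len(trials):
            raise ValueError("LFP array and trial table are misaligned")
        fit = ols(arr.data, X)
        zs.append(fit.z[:, 1:3])
    z = np.stack(zs)
    return z, z.mean(axis=0), z.std(axis=0, ddof=1) / np.sqrt(len(zs)), arrays[0].time_ms


def erp_derivative(
    mean_erp: np.ndarray, time_ms: np.ndarray, smooth_window_ms: float = 80.0
) -> np.ndarray:
    """Local temporal derivative of a waveform (units per ms): centered
    finite differences, boxcar-averaged over ``smooth_window_ms``."""
    dt = np.diff(time_ms)
    if not np.allclose(dt, dt[0]):
        raise ValueError("waveform must be uniformly sampled")
    w = int(round(smooth_window_ms / dt[0]))
    if w < 2:
        raise ValueError("smoothing window shorter than 2 samples")
    deriv = np.gradient(np.asarray(mean_erp, float), time_ms)
    if w % 2:
        return uniform_filter1d(deriv, size=w, mode="nearest")
    # even-length boxcar: average the two half-sample-offset placements so
    # the smoother stays zero-phase
    a = uniform_filter1d(deriv, size=w, mode="nearest", origin=0)
    b = uniform_filter1d(deriv, size=w, mode="nearest", origin=-1)
    return 0.5 * (a + b)


def orthogonalize(x: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual of ``x`` after projecting out span(Z plus an intercept)."""
    x = np.asarray(x, float)
    Z = np.asarray(Z, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    A = np.column_stack([np.ones(len(x)), Z])
    beta, *_ = np.linalg.lstsq(A, x, rcond=None)
    return x - A @ beta


def pc_weight_regression(
    u: np.ndarray, trials: pd.DataFrame, include_rt: bool = False
):
    """Multiple regression of single-trial component weights onto chosen
    value, unchosen value and the error flag (plus intercept).

    With ``include_rt``, reaction time is first orthogonalised with respect
    to those three regressors and appended, so its coefficient reflects RT
    variance beyond the task variables. Returns a DataFrame with columns
    ``coef``, ``se``, ``z`` indexed by regressor name.
    """
    u = np.asarray(u, float)
    if len(u) != len(trials):
        raise ValueError("weights and trial table are misaligned")
    cols = {
        "intercept": np.ones(len(u)),
        "chosen_value": trials["chosen_value"].to_numpy(float),
        "unchosen_value": trials["unchosen_value"].to_numpy(float),
        "error": trials["is_error"].to_numpy(float),
    }
    if cols["error"].std() == 0:
        warnings.warn("no error trials; dropping error regressor", stacklevel=2)
        del cols["error"]
    if include_rt:
        rt = trials["rt_ms"].to_numpy(float)
        task = np.column_stack([v for k, v in cols.items() if k != "intercept"])
        cols["rt"] = orthogonalize(rt, task)
    names = list(cols)
    X = np.column_stack(list(cols.values()))
    fit = ols(u, X, names)
    return pd.DataFrame(
        {"coef": fit.coef[0], "se": fit.se[0], "z": fit.z[0]}, index=names
    )
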