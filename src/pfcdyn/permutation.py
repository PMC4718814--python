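"""Non-parametric population inference.

Population effects (e.g. a unit's CPD minus its pre-choice-baseline mean)
are tested with a sign-flip permutation: under the null the sign of each
unit's effect is exchangeable, so randomly flipping signs and averaging
builds the null distribution of the population mean. Multiple-comparison
thresholds across timebins are estimated empirically by permuting the design
matrix (whole trials, preserving regressor covariance) and taking extrema of
the refit Z statistics over the test window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regression import ols


@dataclass
class PopulationEffect:
    """Per-unit, per-timebin effects relative to a baseline window.

    ``values`` has shape (n_units, n_bins). Typically built with
    :func:`baseline_corrected`, which subtracts each unit's mean effect over
    a pre-choice baseline period (disjoint from the test window).
    """

    values: np.ndarray
    bin_centers_ms: np.ndarray

    @property
    def n_units(self) -> int:
        return self.values.shape[0]


def baseline_corrected(
    per_unit: np.ndarray, bin_centers_ms, baseline_ms=(-500.0, 0.0)
) -> PopulationEffect:
    """Subtract each unit's mean over the baseline window from its
    timecourse (units x bins)."""
    per_unit = np.atleast_2d(np.asarray(per_unit, float))
    bin_centers_ms = np.asarray(bin_centers_ms, float)
    sel = (bin_centers_ms >= baseline_ms[0]) & (bin_centers_ms < baseline_ms[1])
    if not sel.any():
        raise ValueError("baseline window contains no bins")
    base = per_unit[:, sel].mean(axis=1, keepdims=True)
    return PopulationEffect(values=per_unit - base, bin_centers_ms=bin_centers_ms)


def signflip_test(
    effects: PopulationEffect | np.ndarray, n_perm: int = 10000, seed: int = 0
) -> np.ndarray:
    """One-sided sign-flip permutation p-value per timebin.

    p = (#{permuted means >= observed mean} + 1) / (n_perm + 1), so p is
    bounded below by 1/(n_perm + 1) and degenerate all-zero effects give
    p = 1.
    """
    values = effects.values if isinstance(effects, PopulationEffect) else np.atleast_2d(effects)
    n_units, n_bins = values.shape
    if n_units < 2:
        raise ValueError("need at least 2 units")
    rng = np.random.default_rng(seed)
    observed = values.mean(axis=0)
    # canonical row order so the flip assignment (and hence p) does not
    # depend on how the caller happened to order the units
    values = values[np.lexsort(values.T[::-1])]
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_units))
    perm_means = (flips @ values) / n_units
    count = (perm_means >= observed[None, :]).sum(axis=0)
    return (count + 1.0) / (n_perm + 1.0)


def empirical_threshold(
    Y: np.ndarray,
    X: np.ndarray,
    interest_col: int,
    bin_centers_ms,
    window_ms=(250.0, 750.0),
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Empirical multiple-comparison Z thresholds for one regressor.

    Rows (trials) of the design are permuted as a whole ``n_perm`` times;
    each refit yields a Z timecourse for ``interest_col`` on the responses
    ``Y`` (trials x bins). Thresholds are the (1 - alpha) quantile of the
    per-permutation maximum Z over the window, and the alpha quantile of
    the minimum (a negative bound). Returns ``(z_pos, z_neg)``.
    """
    if n_perm * alpha < 1:
        raise ValueError("n_perm too small to estimate the requested quantile")
    bin_centers_ms = np.asarray(bin_centers_ms, float)
    sel = (bin_centers_ms >= window_ms[0]) & (bin_centers_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("window contains no bins")
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    minima = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(X.shape[0])
        fit = ols(Y, X[perm])
        zc = fit.z[:, interest_col][sel]
        maxima[p] = zc.max()
        minima[p] = zc.min()
    return (
        float(np.quantile(maxima, 1.0 - alpha)),
        float(np.quantile(minima, alpha)),
    )


def circ_linear_corr(theta: np.ndarray, x: np.ndarray) -> float:
    """Circular-linear correlation between phases and a linear variable.

    Uses the two-harmonic construction: with r_cx = corr(cos theta, x),
    r_sx = corr(sin theta, x), r_cs = corr(cos theta, sin theta),

        r = sqrt[(r_cx^2 + r_sx^2 - 2 r_cx r_sx r_cs) / (1 - r_cs^2)],

    equivalently the multiple correlation of x on (cos theta, sin theta).
    Non-negative by construction; clipped to [0, 1]. Invariant to phase
    rotation. Raises on zero-variance x.
    """
    theta = np.asarray(theta, float)
    x = np.asarray(x, float)
    if theta.size != x.size or theta.size < 3:
        raise ValueError("theta and x must have equal length >= 3")
    if x.std() == 0:
        raise ValueError("x has zero variance; correlation undefined")
    c, s = np.cos(theta), np.sin(theta)
    r_cx = np.corrcoef(c, x)[0, 1]
    r_sx = np.corrcoef(s, x)[0, 1]
    r_cs = np.corrcoef(c, s)[0, 1]
    num = r_cx**2 + r_sx**2 - 2.0 * r_cx * r_sx * r_cs
    r2 = num / (1.0 - r_cs**2)
    return float(np.sqrt(np.clip(r2, 0.0, 1.0)))
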