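"""Single-trial decomposition of stacked evoked responses.

The central object is the row-stacked matrix X ([electrodes x trials] rows by
timepoints): one row per single-trial waveform, pooled over electrodes and
sessions so a single SVD yields temporal components with a common meaning
everywhere. After removing the cross-row mean timecourse, the leading
components capture cross-trial variability in waveform shape: an
amplitude-like component resembling the mean response, and a latency-like
component resembling its temporal derivative (adding a waveform's derivative
shifts it earlier). The per-row weights of those components are the
single-trial indices of response amplitude and timing used downstream.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .containers import LFPArray, PCADecomposition, StackedMatrix

logger = logging.getLogger(__name__)

#: z threshold of the artifact rule: Gaussian 99th-percentile quantile
#: truncated to two decimals.
ARTIFACT_Z_THRESH = 2.32

#: Default sign conventions: component index -> (sign, anchor time in ms).
DEFAULT_SIGN_ANCHORS = {0: (+1, 190.0), 1: (-1, 530.0)}

DEFAULT_PCA_WINDOW_MS = (-200.0, 1000.0)


def preprocess(raw: LFPArray, target_fs: float, window_ms) -> LFPArray:
    """Anti-alias filter, decimate to ``target_fs`` and crop to ``window_ms``.

    The time axis is regenerated on the decimated grid (start-inclusive,
    end-exclusive). Decimation uses a zero-phase FIR low-pass.
    """
    if target_fs > raw.fs_hz:
        raise ValueError("target_fs must not exceed the recorded sampling rate")
    lo, hi = window_ms
    if lo < raw.time_ms[0] - 1e-9 or hi > raw.time_ms[-1] + 1000.0 / raw.fs_hz + 1e-9:
        raise ValueError("requested window lies outside the recorded span")
    q = raw.fs_hz / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError("fs ratio must be an integer for decimation")
    q = int(round(q))
    data = raw.data
    if q > 1:
        data = sp_signal.decimate(data, q, ftype="fir", axis=1, zero_phase=True)
    new_t = raw.time_ms[0] + np.arange(data.shape[1]) * 1000.0 / target_fs
    keep = (new_t >= lo - 1e-9) & (new_t < hi - 1e-9)
    return LFPArray(
        data=data[:, keep],
        time_ms=new_t[keep],
        fs_hz=target_fs,
        electrode_id=raw.electrode_id,
        region=raw.region,
        session_id=raw.session_id,
        subject_id=raw.subject_id,
        trial_ids=raw.trial_ids,
    )


def stack(arrays, window_ms=DEFAULT_PCA_WINDOW_MS) -> StackedMatrix:
    """Stack per-electrode trials x time arrays into one matrix X.

    Rows are ordered deterministically by (session, electrode, trial); each
    row is recorded in ``row_index``. All arrays must share sampling rate
    and cover the requested window.
    """
    if not arrays:
        raise ValueError("no arrays to stack")
    fs = arrays[0].fs_hz
    lo, hi = window_ms
    order = sorted(
        arrays, key=lambda a: (a.session_id, a.electrode_id)
    )
    blocks, idx = [], []
    t_ref = None
    for arr in order:
        if abs(arr.fs_hz - fs) > 1e-9:
            raise ValueError("all arrays must share the sampling rate")
        keep = (arr.time_ms >= lo - 1e-9) & (arr.time_ms < hi - 1e-9)
        t = arr.time_ms[keep]
        if t_ref is None:
            t_ref = t
        elif t.shape != t_ref.shape or not np.allclose(t, t_ref):
            raise ValueError("arrays do not cover the window on a common grid")
        blocks.append(arr.data[:, keep])
        idx.append(
            pd.DataFrame(
                {
                    "session_id": arr.session_id,
                    "electrode_id": arr.electrode_id,
                    "region": arr.region,
                    "subject_id": -1 if arr.subject_id is None else arr.subject_id,
                    "trial_id": arr.trial_ids,
                }
            )
        )
    row_index = pd.concat(idx, ignore_index=True)
    return StackedMatrix(
        X=np.vstack(blocks), row_index=row_index, time_ms=t_ref, fs_hz=fs
    )


def artifact_mask(stacked: StackedMatrix, z_thresh: float = ARTIFACT_Z_THRESH) -> np.ndarray:
    """Flag rows with outlying within-trial variability.

    The per-row index is the square root of the waveform's standard
    deviation across time; rows whose index lies strictly more than
    ``z_thresh`` standard deviations above the mean index (the Gaussian 99th
    percentile at the default 2.32) are marked True (excluded).
    """
    if stacked.n_rows < 2:
        raise ValueError("need at least 2 rows to form the exclusion index")
    index = np.sqrt(stacked.X.std(axis=1))
    mu, sd = index.mean(), index.std()
    return index > mu + z_thresh * sd


def decompose(
    stacked: StackedMatrix,
    k: int | None = None,
    mask: np.ndarray | None = None,
    sign_anchors=DEFAULT_SIGN_ANCHORS,
    demean: str = "global",
) -> PCADecomposition:
    """SVD of the demeaned stack, with sign conventions applied.

    The per-timepoint mean over all retained rows (the mean timecourse) is
    removed first, so components describe cross-trial variability in
    waveform shape; ``demean="per_electrode"`` removes each (session,
    electrode) block's own mean instead, while ``mean_timecourse`` always
    records the global mean. For each anchored component the component and
    its weights are jointly sign-flipped, if needed, so the component has
    the required sign at the anchor time (snapped to the nearest sample);
    flips are recorded. ``mask`` marks rows to exclude (e.g. from
    :func:`artifact_mask`); ``k`` defaults to the full rank.
    """
    if demean not in ("global", "per_electrode"):
        raise ValueError("demean must be 'global' or 'per_electrode'")
    if mask is None:
        mask = np.zeros(stacked.n_rows, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    keep = ~mask
    X = stacked.X[keep]
    mean_tc = X.mean(axis=0)
    if demean == "global":
        Xd = X - mean_tc
    else:
        idx = stacked.row_index[keep]
        Xd = np.empty_like(X)
        groups = idx.groupby(["session_id", "electrode_id"], sort=False).indices
        for rows in groups.values():
            Xd[rows] = X[rows] - X[rows].mean(axis=0)
    max_k = min(Xd.shape)
    k = max_k if k is None else int(k)
    if k > max_k:
        raise ValueError(f"k={k} exceeds matrix rank bound {max_k}")
    U, s, Vt = np.linalg.svd(Xd, full_matrices=False)
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    total_var = (Xd**2).sum()
    explained = (s**2) / total_var if total_var > 0 else np.zeros(k)

    flips: dict = {}
    for comp, (want_sign, t_anchor) in sign_anchors.items():
        if comp >= k:
            continue
        i = int(np.argmin(np.abs(stacked.time_ms - t_anchor)))
        snapped = stacked.time_ms[i]
        if abs(snapped - t_anchor) > 1e-6:
            logger.info("sign anchor %s ms snapped to sample at %s ms", t_anchor, snapped)
        if s[comp] == 0:
            raise ValueError(f"zero singular value at anchored component {comp}")
        if np.sign(V[i, comp]) != 0 and np.sign(V[i, comp]) != np.sign(want_sign):
            V[:, comp] *= -1
            U[:, comp] *= -1
            flips[comp] = True
        else:
            flips[comp] = False

    return PCADecomposition(
        V=V,
        U=U,
        singular_values=s,
        explained_variance_fraction=explained,
        mean_timecourse=mean_tc,
        time_ms=stacked.time_ms,
        excluded_rows=mask,
        row_index=stacked.row_index[keep].reset_index(drop=True),
        sign_flips=flips,
    )


def reconstruct(
    d: PCADecomposition,
    component: int,
    weight_delta: float,
    base_weights: dict | None = None,
) -> np.ndarray:
    """Waveform implied by the mean timecourse plus ``weight_delta`` of one
    component (optionally on top of fixed weights of other components)."""
    if component >= d.k:
        raise ValueError("component index out of range")
    wave = d.mean_timecourse.copy()
    for c, w in (base_weights or {}).items():
        wave = wave + w * d.V[:, c]
    return wave + weight_delta * d.V[:, component]


def latency_component(
    d: PCADecomposition,
    search_components: int = 3,
    window_ms=(200.0, 1000.0),
    smooth_ms: float = 80.0,
) -> int:
    """Identify the latency-like component by derivative similarity.

    Returns the index (among the leading ``search_components``) whose shape
    correlates most strongly, in absolute value, with the smoothed temporal
    derivative of the mean waveform over ``window_ms``. In recorded-LFP-like
    data this is typically component 2; in the attractor network's summed
    rate it is component 1, so the index is decided from the data rather
    than hard-coded.
    """
    from .regression import erp_derivative

    deriv = erp_derivative(d.mean_timecourse, d.time_ms, smooth_ms)
    sel = (d.time_ms >= window_ms[0]) & (d.time_ms <= window_ms[1])
    best, best_r = 0, -1.0
    for c in range(min(search_components, d.k)):
        r = abs(np.corrcoef(d.V[sel, c], deriv[sel])[0, 1])
        if r > best_r:
            best, best_r = c, r
    return best


def noise_component_indices(d: PCADecomposition, indices=(100, 101)) -> tuple:
    """Indices of the noise-control components: fixed positions (101st and
    102nd, zero-based 100/101) when the decomposition retains that many,
    else the last two retained components (with a warning)."""
    if d.k > max(indices):
        return tuple(indices)
    fallback = (d.k - 2, d.k - 1)
    warnings.warn(
        f"decomposition has only {d.k} components; using {fallback} as noise controls",
        stacklevel=2,
    )
    return fallback


def align_subject_signs(subject_arrays, max_iter: int = 100) -> np.ndarray:
    """Resolve per-subject sign ambiguity of source-reconstructed signals.

    Iteratively flips any subject whose evoked (trial-mean) response
    correlates negatively with the signed grand mean of the other subjects,
    until stable. The result is defined up to one global sign, resolved by
    the convention that the majority sign is +1.
    """
    if len(subject_arrays) < 2:
        raise ValueError("need at least 2 subjects")
    evoked = np.array([a.data.mean(axis=0) for a in subject_arrays])
    n = evoked.shape[0]
    signs = np.ones(n)
    for _ in range(max_iter):
        changed = False
        for i in range(n):
            others = (signs[:, None] * evoked).sum(axis=0) - signs[i] * evoked[i]
            r = np.corrcoef(signs[i] * evoked[i], others)[0, 1]
            if r < 0:
                signs[i] *= -1
                changed = True
        if not changed:
            break
    else:
        raise RuntimeError(
            f"sign alignment did not converge in {max_iter} iterations; "
            f"current signs: {signs.tolist()}"
        )
    if (signs == -1).sum() > n / 2:
        signs = -signs
    return signs


DEFAULT_BANDS_HZ = ((2.0, 4.0), (4.0, 8.0), (8.0, 16.0), (16.0, 32.0))


def phase_power_map(arr: LFPArray, bands_hz=DEFAULT_BANDS_HZ):
    """Per-trial instantaneous phase and power in octave-spaced bands.

    Each band is isolated with a zero-phase 4th-order Butterworth band-pass
    and Hilbert-transformed; returns ``(phase, power)`` arrays of shape
    (trials, bands, time), phase wrapped to (-pi, pi].
    """
    nyq = arr.fs_hz / 2.0
    for lo, hi in bands_hz:
        if hi >= nyq:
            raise ValueError(f"band edge {hi} Hz >= Nyquist {nyq} Hz")
    n_tr, n_t = arr.data.shape
    phase = np.empty((n_tr, len(bands_hz), n_t))
    power = np.empty_like(phase)
    for b, (lo, hi) in enumerate(bands_hz):
        sos = sp_signal.butter(4, [lo, hi], btype="band", fs=arr.fs_hz, output="sos")
        filt = sp_signal.sosfiltfilt(sos, arr.data, axis=1)
        analytic = sp_signal.hilbert(filt, axis=1)
        phase[:, b] = np.angle(analytic)
        power[:, b] = np.abs(analytic) ** 2
    return phase, power
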