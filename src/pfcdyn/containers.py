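"""In-memory containers shared across the pipeline.

Trial metadata lives in a plain :class:`pandas.DataFrame` (see
:data:`TRIAL_COLUMNS` for the canonical schema); continuous and spiking
signals are small dataclasses wrapping numpy arrays plus the recording
metadata the analyses need (sampling rate, time axis, region labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column set of a trial table. ``rt_ms`` is optional and only
#: present in human-style (reaction-time) datasets.
TRIAL_COLUMNS = [
    "trial_id",
    "session_id",
    "trial_type",
    "reward_left",
    "reward_right",
    "cost_left",
    "cost_right",
    "value_left",
    "value_right",
    "chosen_side",
    "chosen_value",
    "unchosen_value",
    "is_error",
]


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table invariants and return the table unchanged.

    Raises ``ValueError`` if value bookkeeping is inconsistent: values must
    equal reward minus cost, chosen/unchosen must be {value_left,
    value_right} in the order implied by ``chosen_side``, and ``is_error``
    must flag exactly the trials where the strictly lower-valued option was
    taken (ties are never errors).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    vl = trials["reward_left"] - trials["cost_left"]
    vr = trials["reward_right"] - trials["cost_right"]
    if not (trials["value_left"].eq(vl).all() and trials["value_right"].eq(vr).all()):
        raise ValueError("value columns do not equal reward - cost")
    left = trials["chosen_side"].eq("L")
    cv = np.where(left, trials["value_left"], trials["value_right"])
    uv = np.where(left, trials["value_right"], trials["value_left"])
    if not (trials["chosen_value"].to_numpy() == cv).all():
        raise ValueError("chosen_value inconsistent with chosen_side")
    if not (trials["unchosen_value"].to_numpy() == uv).all():
        raise ValueError("unchosen_value inconsistent with chosen_side")
    if not (trials["is_error"].to_numpy() == (cv < uv)).all():
        raise ValueError("is_error must mark strictly lower-valued choices")
    return trials


@dataclass
class LFPArray:
    """trials x time continuous signal from one electrode (or one human
    virtual electrode), time-locked to choice onset."""

    data: np.ndarray          # (n_trials, n_timepoints)
    time_ms: np.ndarray       # (n_timepoints,), strictly increasing, uniform
    fs_hz: float
    electrode_id: int = 0
    region: str = ""
    session_id: int = 0
    subject_id: int | None = None
    trial_ids: np.ndarray | None = None  # defaults to 0..n_trials-1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != self.time_ms.size:
            raise ValueError("data must be (n_trials, n_timepoints) matching time_ms")
        dt = np.diff(self.time_ms)
        if dt.size and (dt <= 0).any():
            raise ValueError("time axis must be strictly increasing")
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time axis must be uniformly sampled")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[0])
        else:
            self.trial_ids = np.asarray(self.trial_ids)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class SpikeRaster:
    """Per-trial spike times (ms, relative to choice onset) of one unit."""

    spikes: list                # list of 1-D arrays, one per trial
    window_ms: tuple            # (t_start, t_stop) covered by the raster
    unit_id: int = 0
    region: str = ""
    session_id: int = 0
    electrode_id: int = 0
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        if self.trial_ids is None:
            self.trial_ids = np.arange(len(self.spikes))

    @property
    def n_trials(self) -> int:
        return len(self.spikes)


@dataclass
class StackedMatrix:
    """Row-stacked cross-trial matrix X: one row per (electrode, trial)."""

    X: np.ndarray               # (n_rows, n_timepoints)
    row_index: pd.DataFrame     # columns: session_id, electrode_id, trial_id, region/subject
    time_ms: np.ndarray
    fs_hz: float
    mean_timecourse: np.ndarray | None = None  # set once demeaned (decompose)

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.row_index):
            raise ValueError("row_index length must equal number of rows of X")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass
class PCADecomposition:
    """SVD of the demeaned stacked matrix: X_demeaned = U @ diag(s) @ V.T.

    ``U`` holds one row per *retained* row of the stack (artifact-excluded
    rows are dropped); ``row_index`` maps those rows back to
    (session, electrode, trial). Columns of ``V`` are orthonormal temporal
    components; ``sign_flips`` records anchor-driven sign changes.
    """

    V: np.ndarray               # (n_timepoints, k)
    U: np.ndarray               # (n_retained, k), orthonormal columns
    singular_values: np.ndarray
    explained_variance_fraction: np.ndarray
    mean_timecourse: np.ndarray
    time_ms: np.ndarray
    excluded_rows: np.ndarray   # bool mask over the original stack rows
    row_index: pd.DataFrame     # retained rows only
    sign_flips: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.V.shape[1]

    def weights(self, component: int) -> np.ndarray:
        """Single-trial weights of one component (0-based), scaled by its
        singular value so they are in the units of the input signal."""
        return self.U[:, component] * self.singular_values[component]

    def weight_table(self, components=(0, 1)) -> pd.DataFrame:
        """Tidy per-(electrode, trial) table of component weights."""
        out = self.row_index.reset_index(drop=True).copy()
        for c in components:
            out[f"pc{c + 1}"] = self.weights(c)
        return out


@dataclass
class BinnedRates:
    """Sliding-window firing rates: trials x timebins, in Hz."""

    rates: np.ndarray           # (n_trials, n_bins)
    bin_centers_ms: np.ndarray
    bin_width_ms: float
    unit_id: int = 0
    region: str = ""
    session_id: int = 0
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.rates < 0).any():
            raise ValueError("rates must be non-negative")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.rates.shape[0])

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]


@dataclass
class RegressionResult:
    """Per-timebin OLS output for one response variable (unit or signal).

    ``coef``, ``z`` are (n_bins, n_regressors); ``cpd`` maps factor name ->
    (n_bins,) coefficient of partial determination in [0, 1].
    """

    coef: np.ndarray
    z: np.ndarray
    sse: np.ndarray             # (n_bins,)
    cpd: dict
    factor_names: list
    bin_centers_ms: np.ndarray
    n_trials: int

    @property
    def chance_cpd(self) -> float:
        """Analytic chance level of a single-column CPD, ~ 1/(n - p)."""
        p = len(self.factor_names)
        return 1.0 / max(self.n_trials - p, 1)
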