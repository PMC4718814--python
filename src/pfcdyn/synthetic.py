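"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a two-option cost-benefit task: on each trial two
pictures promise a reward level (1-4) at a cost level (1-4), the cost being
physical effort on half of trials and delay on the other half. Option value
is reward minus cost; choices follow a softmax on the value difference, and
"error" trials are those where the strictly lower-valued option was taken.

Evoked field potentials are built from a template waveform whose single-trial
*amplitude* covaries with the summed value of both options and whose
*latency* shortens with chosen value (and on error trials), plus
region-shared and electrode-local latency latents. Spike rasters carry an
early action-value-difference drive, a late chosen-action drive, and a
mid-trial drive that can be routed either directly through chosen value or
through the shared latency latent (the ``mediation`` dial), which is what the
coupling analyses are designed to detect.

Every random stream is derived from one master seed; ground-truth latents are
always returned alongside the data so recovery tests never re-derive them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import zlib

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import LFPArray, SpikeRaster, validate_trial_table

DEFAULT_FS_HZ = 100.0
DEFAULT_WINDOW_MS = (-500.0, 1000.0)


def stream_rng(seed: int, *tags) -> np.random.Generator:
    """Derive a named child generator from the master seed.

    The stream is keyed by CRC32 of each tag's string form, so e.g.
    ``stream_rng(seed, "lfp", region, electrode)`` is reproducible and
    independent of generation order.
    """
    keys = [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


def time_axis(window_ms=DEFAULT_WINDOW_MS, fs_hz=DEFAULT_FS_HZ) -> np.ndarray:
    """Sample times in ms: start-inclusive, end-exclusive uniform grid."""
    start, stop = window_ms
    n = int(round((stop - start) * fs_hz / 1000.0))
    return start + np.arange(n) * 1000.0 / fs_hz


def _bump(t, peak, width, amp):
    """Gamma-shaped bump peaking at ``peak`` ms, zero for t <= 0."""
    k = (peak / width) ** 2
    x = np.clip(t, 0.0, None) / peak
    with np.errstate(divide="ignore", invalid="ignore"):
        out = amp * np.exp(k * (np.log(np.where(x > 0, x, 1.0)) + 1.0 - x))
    return np.where(x > 0, out, 0.0)


def fast_erp_component(t_ms) -> np.ndarray:
    """Fast biphasic sensory-evoked deflection, essentially complete within
    ~250 ms of stimulus onset."""
    t = np.asarray(t_ms, dtype=float)
    return _bump(t, 100.0, 30.0, 1.0) - _bump(t, 50.0, 18.0, 0.5)


def late_erp_component(t_ms) -> np.ndarray:
    """Slow decision-related component (peak ~430 ms, decaying through the
    late window); this is the part whose single-trial latency varies."""
    t = np.asarray(t_ms, dtype=float)
    return _bump(t, 430.0, 140.0, 1.2)


def default_erp_template(t_ms) -> np.ndarray:
    """Template evoked response g(t): fast biphasic deflection followed by a
    slower late bump. The exact shape is a free choice; no analysis stage
    depends on it."""
    return fast_erp_component(t_ms) + late_erp_component(t_ms)


@dataclass
class ErpModel:
    """Generative model of single-trial evoked responses.

    The waveform has a fast sensory part (fixed timing) and a late
    decision-related part whose latency varies trial by trial, emulating
    the observation that cross-trial variation in the early deflection is
    orthogonal to variation in the late component. Latency (ms) on trial i,
    electrode e in region r:

        tau = -latency_gain * z(chosen value) - latency_error * is_error
              + shared_r (sd sigma_shared) + local_e (sd sigma_local)

    Amplitude scale: 1 + amp_gain * z(value sum) + N(0, sigma_amp), applied
    to the whole waveform. Signal:
    scale * [fast(t) + late(t - tau)] + N(0, sigma_noise) white noise.
    """

    template_fast: object = None       # callable t_ms -> waveform, or array on the grid
    template_late: object = None
    amp_gain: float = 0.1              # amplitude per z-scored value sum
    latency_gain: float = 10.0         # ms earlier per z-scored chosen value
    latency_error: float = 15.0        # ms earlier on error trials
    sigma_shared: float = 20.0         # ms, region-shared latency latent
    sigma_local: float = 8.0           # ms, electrode-local latency latent
    sigma_amp: float = 0.15
    sigma_noise: float = 0.25
    max_shift_ms: float = 150.0
    fs_hz: float = DEFAULT_FS_HZ
    window_ms: tuple = DEFAULT_WINDOW_MS

    def __post_init__(self) -> None:
        for name in ("sigma_shared", "sigma_local", "sigma_amp", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.template_fast is None and self.template_late is None:
            self.template_fast = fast_erp_component
            self.template_late = late_erp_component

    def _eval(self, part, t_ms: np.ndarray) -> np.ndarray:
        """Evaluate one template part at arbitrary times; array templates
        are linearly interpolated with boundary-value padding (no
        wrap-around)."""
        if part is None:
            return np.zeros_like(np.asarray(t_ms, dtype=float))
        if callable(part):
            return part(np.asarray(t_ms, dtype=float))
        grid = time_axis(self.window_ms, self.fs_hz)
        return np.interp(t_ms, grid, np.asarray(part, dtype=float))

    def evaluate_template(self, t_ms: np.ndarray) -> np.ndarray:
        """Full template (fast plus late part) at arbitrary times."""
        return self._eval(self.template_fast, t_ms) + self._eval(self.template_late, t_ms)


def zscore(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def gen_trial_table(
    n_trials: int,
    softmax_temperature: float = 1.0,
    seed: int = 0,
    session_id: int = 0,
) -> pd.DataFrame:
    """Simulate the trial table: interleaved effort/delay trials, reward and
    cost levels uniform on 1-4 per option, softmax choice on value difference.

    P(choose left) = logistic((value_left - value_right) / temperature).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if softmax_temperature <= 0:
        raise ValueError("softmax_temperature must be positive")
    rng = stream_rng(seed, "trials", session_id)
    trial_type = np.where(rng.random(n_trials) < 0.5, "effort", "delay")
    levels = rng.integers(1, 5, size=(n_trials, 4))
    reward_left, reward_right, cost_left, cost_right = levels.T
    value_left = reward_left - cost_left
    value_right = reward_right - cost_right
    p_left = expit((value_left - value_right) / softmax_temperature)
    chose_left = rng.random(n_trials) < p_left
    chosen_value = np.where(chose_left, value_left, value_right)
    unchosen_value = np.where(chose_left, value_right, value_left)
    table = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "session_id": session_id,
            "trial_type": trial_type,
            "reward_left": reward_left,
            "reward_right": reward_right,
            "cost_left": cost_left,
            "cost_right": cost_right,
            "value_left": value_left,
            "value_right": value_right,
            "chosen_side": np.where(chose_left, "L", "R"),
            "chosen_value": chosen_value,
            "unchosen_value": unchosen_value,
            "is_error": chosen_value < unchosen_value,
        }
    )
    return validate_trial_table(table)


def gen_lfp(
    trials: pd.DataFrame,
    model: ErpModel | None = None,
    n_electrodes_per_region: int = 2,
    regions=("DLPFC", "OFC", "ACC"),
    seed: int = 0,
):
    """Generate per-electrode trials x time evoked LFP.

    Returns ``(arrays, truth)`` where ``truth`` is a per-(region, electrode,
    trial) table of the injected latents: ``tau_ms`` (total latency shift,
    positive = later), ``tau_region_ms`` (the part shared by all electrodes
    of the region, including the value/error drive), and ``amp`` (amplitude
    deviation from 1). Electrode ids are unique across regions.
    """
    model = model or ErpModel()
    n = len(trials)
    t = time_axis(model.window_ms, model.fs_hz)
    z_cv = zscore(trials["chosen_value"])
    z_sum = zscore(trials["chosen_value"] + trials["unchosen_value"])
    err = trials["is_error"].to_numpy().astype(float)
    session = int(trials["session_id"].iloc[0]) if "session_id" in trials else 0

    arrays, rows = [], []
    electrode_id = 0
    for region in regions:
        rng_r = stream_rng(seed, "lfp-region", session, region)
        shared = rng_r.normal(0.0, model.sigma_shared, size=n)
        tau_region = -model.latency_gain * z_cv - model.latency_error * err + shared
        for _ in range(n_electrodes_per_region):
            rng_e = stream_rng(seed, "lfp-electrode", session, region, electrode_id)
            tau = tau_region + rng_e.normal(0.0, model.sigma_local, size=n)
            amp = model.amp_gain * z_sum + rng_e.normal(0.0, model.sigma_amp, size=n)
            if np.abs(tau).max() > model.max_shift_ms:
                raise ValueError(
                    "latency shift exceeds max_shift_ms; template would leave the window"
                )
            shifted = model._eval(model.template_fast, t)[None, :] + model._eval(
                model.template_late, t[None, :] - tau[:, None]
            )
            data = (1.0 + amp)[:, None] * shifted
            data += rng_e.normal(0.0, model.sigma_noise, size=data.shape)
            arrays.append(
                LFPArray(
                    data=data,
                    time_ms=t,
                    fs_hz=model.fs_hz,
                    electrode_id=electrode_id,
                    region=region,
                    session_id=session,
                    trial_ids=trials["trial_id"].to_numpy(),
                )
            )
            rows.append(
                pd.DataFrame(
                    {
                        "session_id": session,
                        "region": region,
                        "electrode_id": electrode_id,
                        "trial_id": trials["trial_id"].to_numpy(),
                        "tau_ms": tau,
                        "tau_region_ms": tau_region,
                        "amp": amp,
                    }
                )
            )
            electrode_id += 1
    return arrays, pd.concat(rows, ignore_index=True)


def _gauss_kernel(t_ms: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center) / sd) ** 2)


@dataclass
class SpikeModel:
    """Generative model of per-unit firing rates (Hz), Poisson spiking.

    Units carry an early drive by the left-right action value difference, a
    late drive by the chosen action, and a mid-trial chosen-value drive of
    which a fraction ``mediation`` is routed through the region's latency
    latent (the pathway transmits the value signal unchanged and adds the
    latent's trial-specific fluctuation; faster dynamics = higher rate).
    A per-unit selectivity gain scales every drive — so chosen-value
    selectivity and latent coupling covary across units — and a preferred
    side flips the action-frame drives; both are reported in the unit
    truth table.
    """

    baseline_hz: float = 10.0
    dv_weight_hz: float = 2.0          # Hz per unit of (value_left - value_right)
    choice_weight_hz: float = 5.0      # Hz for chosen_side (+1 = L)
    cv_weight_hz: float = 5.0          # Hz per z of the mid-trial value drive
    latency_coupling_hz: float = 0.0   # extra Hz per z(-tau) regardless of value
    mediation: float = 0.5             # fraction of cv drive routed via the latent
    early_kernel: tuple = (300.0, 100.0)   # (center ms, sd ms)
    late_kernel: tuple = (700.0, 100.0)
    mid_kernel: tuple = (500.0, 150.0)
    gain_sd: float = 0.5               # per-unit selectivity spread
    window_ms: tuple = DEFAULT_WINDOW_MS

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise ValueError("baseline rate must be non-negative")
        if not 0.0 <= self.mediation <= 1.0:
            raise ValueError("mediation must lie in [0, 1]")


def gen_spikes(
    trials: pd.DataFrame,
    model: SpikeModel | None = None,
    latents: pd.DataFrame | None = None,
    n_units: int = 10,
    seed: int = 0,
    region: str = "DLPFC",
):
    """Inhomogeneous-Poisson spike rasters for ``n_units`` units.

    ``latents`` is the ground-truth table from :func:`gen_lfp`; the units
    couple to that region's shared latency latent (``tau_region_ms``). With
    ``latents=None`` the latent drive is zero. Returns ``(rasters,
    unit_truth)`` with the per-unit gains used.
    """
    model = model or SpikeModel()
    n = len(trials)
    dt_ms = 1.0
    edges = np.arange(model.window_ms[0], model.window_ms[1] + dt_ms / 2, dt_ms)
    centers = edges[:-1] + dt_ms / 2.0

    dv = (trials["value_left"] - trials["value_right"]).to_numpy().astype(float)
    choice = np.where(trials["chosen_side"].to_numpy() == "L", 1.0, -1.0)
    z_cv = zscore(trials["chosen_value"])
    if latents is not None:
        sub = latents[latents["region"] == region]
        tau = (
            sub.drop_duplicates("trial_id")
            .set_index("trial_id")["tau_region_ms"]
            .reindex(trials["trial_id"])
            .to_numpy()
        )
        if np.isnan(tau).any():
            raise ValueError("latents do not cover every trial for region " + region)
        z_lat = zscore(-tau)  # + = faster (earlier) dynamics
    else:
        z_lat = np.zeros(n)

    k_early = _gauss_kernel(centers, *model.early_kernel)
    k_late = _gauss_kernel(centers, *model.late_kernel)
    k_mid = _gauss_kernel(centers, *model.mid_kernel)

    # Route a fraction `mediation` of the chosen-value drive through the
    # latent pathway. The pathway carries the chosen-value signal unchanged
    # (so the unit's chosen-value coding strength is independent of the
    # routing) plus the latent's intrinsic trial-specific fluctuation, whose
    # contribution grows linearly with the routed fraction.
    rho = float(np.corrcoef(z_lat, z_cv)[0, 1]) if z_lat.std() > 0 else 0.0
    if abs(rho) > 0.05:
        eps = (z_lat - rho * z_cv) / np.sqrt(1.0 - rho**2)  # unit var, orth. to cv
        nu = np.sqrt(1.0 - rho**2) / abs(rho)  # latent noise-to-signal ratio
        mid_drive = z_cv + model.mediation * nu * eps
    else:
        mid_drive = (1.0 - model.mediation) * z_cv + model.mediation * z_lat

    session = int(trials["session_id"].iloc[0]) if "session_id" in trials else 0
    rasters, unit_rows = [], []
    for u in range(n_units):
        rng = stream_rng(seed, "spikes", session, region, u)
        gain = max(rng.normal(1.0, model.gain_sd), 0.1)
        side = rng.choice([-1.0, 1.0])
        rate = (
            model.baseline_hz
            + gain * side * (
                model.dv_weight_hz * k_early[None, :] * dv[:, None]
                + model.choice_weight_hz * k_late[None, :] * choice[:, None]
            )
            + gain * (
                model.cv_weight_hz * k_mid[None, :] * mid_drive[:, None]
                + model.latency_coupling_hz * k_mid[None, :] * z_lat[:, None]
            )
        )
        rate = np.clip(rate, 0.0, None)
        counts = rng.poisson(rate * dt_ms / 1000.0)
        spikes = []
        for i in range(n):
            idx = np.repeat(np.arange(counts.shape[1]), counts[i])
            times = edges[idx] + rng.random(idx.size) * dt_ms
            spikes.append(np.sort(times))
        rasters.append(
            SpikeRaster(
                spikes=spikes,
                window_ms=model.window_ms,
                unit_id=u,
                region=region,
                session_id=session,
                trial_ids=trials["trial_id"].to_numpy(),
            )
        )
        unit_rows.append(
            {"unit_id": u, "region": region, "session_id": session,
             "gain": gain, "preferred_side": side}
        )
    return rasters, pd.DataFrame(unit_rows)


@dataclass
class RtModel:
    """Reaction-time model for human-style datasets (ms):
    rt = base - value_slope * chosen_value + tau_slope * tau + noise,
    truncated below at ``floor_ms``."""

    base_ms: float = 800.0
    value_slope: float = 50.0
    tau_slope: float = 2.0
    noise_sd: float = 100.0
    floor_ms: float = 50.0


def gen_meg_subjects(
    n_subjects: int = 6,
    trials_per_subject: int = 200,
    model: ErpModel | None = None,
    rt_model: RtModel | None = None,
    seed: int = 0,
    softmax_temperature: float = 1.0,
):
    """Multi-subject MEG-like dataset: one virtual electrode per subject.

    Each subject's signal is multiplied by a random sign in {+1, -1}
    (mimicking the arbitrary source-orientation flip of beamforming); the
    sign is recorded in the truth table. Reaction times follow
    :class:`RtModel` with the subject's latency latent feeding in, so slower
    single-trial dynamics mean slower responses.

    Returns ``(arrays, trials, truth)``; ``trials`` carries a ``subject_id``
    and ``rt_ms`` column, with trial rows in subject-major order matching
    the per-subject arrays.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    model = model or ErpModel(sigma_local=0.0)
    rt_model = rt_model or RtModel()
    arrays, tables, truths = [], [], []
    for s in range(n_subjects):
        trials = gen_trial_table(
            trials_per_subject, softmax_temperature, seed=seed, session_id=s
        )
        arrs, truth = gen_lfp(
            trials, model, n_electrodes_per_region=1, regions=("vmPFC",), seed=seed
        )
        arr = arrs[0]
        rng = stream_rng(seed, "meg-sign", s)
        sign = float(rng.choice([-1.0, 1.0]))
        arr.data = sign * arr.data
        arr.subject_id = s
        arr.electrode_id = s
        tau = truth["tau_ms"].to_numpy()
        rt = (
            rt_model.base_ms
            - rt_model.value_slope * trials["chosen_value"].to_numpy()
            + rt_model.tau_slope * tau
            + rng.normal(0.0, rt_model.noise_sd, size=len(trials))
        )
        trials = trials.assign(subject_id=s, rt_ms=np.maximum(rt, rt_model.floor_ms))
        truth = truth.assign(subject_id=s, sign=sign)
        arrays.append(arr)
        tables.append(trials)
        truths.append(truth)
    return arrays, pd.concat(tables, ignore_index=True), pd.concat(truths, ignore_index=True)
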