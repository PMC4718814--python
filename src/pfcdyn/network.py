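"""Winner-take-all spiking decision network and its analysis harness.

A recurrent network of 2000 conductance-based leaky integrate-and-fire
neurons (1600 excitatory, 400 inhibitory) makes two-alternative value-based
choices. Two selective excitatory pools (240 cells each) receive Poisson
input whose mean rate encodes the value of their option; strengthened
recurrent excitation within each pool (w+ = 1.7) and weakened excitation
between pools (w- = 1 - f(w+ - 1)/(1 - f)) give integration via
reverberation and competition via shared inhibition, so one pool ramps into
a high-rate attractor state — the choice. Physiological constants follow
the classic two-population reverberation model of perceptual choice
(AMPA/NMDA/GABA conductance synapses, NMDA saturation and Mg block); they
are collected in :class:`CellParams` / :class:`SynapseParams` and are
user-editable, but none of the analyses depend on their exact values.

The "LFP" of the model is the summed firing rate of all cells. The analysis
harness reuses the stacked-PCA and regression machinery on that proxy, so
the model's predictions are processed exactly like recorded data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import uniform_filter1d

from .containers import LFPArray
from .pca import decompose, stack
from .regression import cpd, ols, regression_result
from .synthetic import stream_rng

logger = logging.getLogger(__name__)

POOL_A, POOL_B, POOL_NS, POOL_I = 0, 1, 2, 3


@dataclass
class CellParams:
    """Leaky integrate-and-fire constants (per cell class)."""

    c_m_nf: float          # membrane capacitance
    g_leak_ns: float       # leak conductance
    e_leak_mv: float = -70.0
    v_thresh_mv: float = -50.0
    v_reset_mv: float = -55.0
    t_refractory_ms: float = 2.0
    # synaptic conductances onto this cell class (nS)
    g_ext_ampa_ns: float = 2.1
    g_rec_ampa_ns: float = 0.05
    g_nmda_ns: float = 0.165
    g_gaba_ns: float = 1.3


PYRAMIDAL = CellParams(c_m_nf=0.5, g_leak_ns=25.0, t_refractory_ms=2.0,
                       g_ext_ampa_ns=2.1, g_rec_ampa_ns=0.05,
                       g_nmda_ns=0.165, g_gaba_ns=1.3)
INTERNEURON = CellParams(c_m_nf=0.2, g_leak_ns=20.0, t_refractory_ms=1.0,
                         g_ext_ampa_ns=1.62, g_rec_ampa_ns=0.04,
                         g_nmda_ns=0.13, g_gaba_ns=1.0)


@dataclass
class SynapseParams:
    """Kinetics and reversal potentials shared by all cells."""

    e_ampa_mv: float = 0.0
    e_gaba_mv: float = -70.0
    tau_ampa_ms: float = 2.0
    tau_gaba_ms: float = 5.0
    tau_nmda_decay_ms: float = 100.0
    tau_nmda_rise_ms: float = 2.0
    alpha_nmda_per_ms: float = 0.5
    mg_mm: float = 1.0


@dataclass
class NetworkConfig:
    """Network structure, inputs and simulation schedule."""

    n_total: int = 2000
    n_inhibitory: int = 400
    selective_fraction: float = 0.15
    w_plus: float = 1.7
    background_rate_hz: float = 2400.0
    input_mean_range_hz: tuple = (20.0, 60.0)
    input_noise_sd_hz: float = 10.0
    input_resample_ms: float = 50.0
    t_init_ms: float = 500.0
    t_stim_ms: float = 2500.0
    dt_ms: float = 0.02            # fast mode: 0.1
    readout_threshold_hz: float = 25.0
    readout_margin_hz: float = 15.0
    rate_window_ms: float = 50.0
    pyramidal: CellParams = field(default_factory=lambda: PYRAMIDAL)
    interneuron: CellParams = field(default_factory=lambda: INTERNEURON)
    synapse: SynapseParams = field(default_factory=SynapseParams)

    def __post_init__(self) -> None:
        if self.n_inhibitory >= self.n_total:
            raise ValueError("inconsistent cell counts")
        if self.n_selective * 2 > self.n_excitatory:
            raise ValueError("selective pools exceed the excitatory population")
        if not self.w_minus < 1.0 < self.w_plus:
            raise ValueError("weights must satisfy w_minus < 1 < w_plus")

    @property
    def n_excitatory(self) -> int:
        return self.n_total - self.n_inhibitory

    @property
    def n_selective(self) -> int:
        """Cells per selective pool: f * n_excitatory."""
        return int(round(self.selective_fraction * self.n_excitatory))

    @property
    def n_nonselective(self) -> int:
        return self.n_excitatory - 2 * self.n_selective

    @property
    def w_minus(self) -> float:
        """Depressed cross-pool weight, 1 - f(w+ - 1)/(1 - f): chosen so
        total recurrent excitatory drive is balanced at baseline."""
        f = self.selective_fraction
        return 1.0 - f * (self.w_plus - 1.0) / (1.0 - f)

    @property
    def t_total_ms(self) -> float:
        return self.t_init_ms + self.t_stim_ms


@dataclass
class Network:
    """Built network: pool assignment, per-neuron constants and the
    excitatory weight scheme (queryable via :meth:`weight`)."""

    config: NetworkConfig
    pool_id: np.ndarray        # per neuron: 0=A, 1=B, 2=nonselective, 3=inhibitory
    w_exc: np.ndarray          # (4 target pools, 3 source excitatory pools)

    def weight(self, source_pool: int, target_pool: int) -> float:
        """Excitatory connection weight from one pool onto another
        (inhibitory sources always weight 1)."""
        if source_pool == POOL_I:
            return 1.0
        return float(self.w_exc[target_pool, source_pool])

    @property
    def pool_slices(self) -> dict:
        c = self.config
        nA = c.n_selective
        return {
            POOL_A: slice(0, nA),
            POOL_B: slice(nA, 2 * nA),
            POOL_NS: slice(2 * nA, c.n_excitatory),
            POOL_I: slice(c.n_excitatory, c.n_total),
        }


def build(config: NetworkConfig | None = None) -> Network:
    """Assemble the pool layout and block-structured weight scheme.

    Connectivity is all-to-all; because weights depend only on the (source,
    target) pool pair, recurrent drive is computed from per-pool sums of
    synaptic gating rather than an explicit matrix.
    """
    config = config or NetworkConfig()
    c = config
    pool_id = np.concatenate(
        [
            np.full(c.n_selective, POOL_A),
            np.full(c.n_selective, POOL_B),
            np.full(c.n_nonselective, POOL_NS),
            np.full(c.n_inhibitory, POOL_I),
        ]
    ).astype(np.int64)
    wp, wm = c.w_plus, c.w_minus
    w_exc = np.array(
        [
            [wp, wm, wm],   # onto A from (A, B, NS)
            [wm, wp, wm],   # onto B
            [1.0, 1.0, 1.0],  # onto nonselective
            [1.0, 1.0, 1.0],  # onto inhibitory
        ]
    )
    return Network(config=config, pool_id=pool_id, w_exc=w_exc)


def sample_inputs(config: NetworkConfig, seed: int = 0):
    """Draw the trial's input means and the 50 ms piecewise-constant rate
    streams.

    Means mu_A, mu_B are independent U(20, 60) Hz; every resample interval
    the instantaneous rate is redrawn from N(mu, sigma) and rectified at
    zero. Returns ``(mu_a, mu_b, stream_a, stream_b)`` with one stream
    entry per resample segment of the stimulus period.
    """
    rng = stream_rng(seed, "inputs")
    lo, hi = config.input_mean_range_hz
    mu_a, mu_b = rng.uniform(lo, hi, size=2)
    n_seg = int(np.ceil(config.t_stim_ms / config.input_resample_ms))
    stream_a = np.clip(rng.normal(mu_a, config.input_noise_sd_hz, n_seg), 0.0, None)
    stream_b = np.clip(rng.normal(mu_b, config.input_noise_sd_hz, n_seg), 0.0, None)
    return float(mu_a), float(mu_b), stream_a, stream_b


@njit(inline="always")
def _poisson_small(lam, p0):
    """Inverse-CDF Poisson draw for small rates (one uniform, p0 = e^-lam)."""
    u = np.random.random()
    k = 0
    p = p0
    c = p0
    while u > c:
        k += 1
        p *= lam / k
        c += p
        if k > 50:
            break
    return k


@njit(cache=True, fastmath=True)
def _run_trial(
    dt, n_steps, n_ms, stim_start_ms, resample_ms,
    pool_id, nA, nE, N,
    c_m, g_leak, e_leak, v_thresh, v_reset, ref_steps,
    g_ext, g_ampa, g_nmda, g_gaba,
    w_exc,
    e_ampa, e_gaba, tau_ampa, tau_gaba, tau_nmda, tau_rise, alpha, mg,
    bg_rate_hz, stream_a, stream_b, seed,
):
    np.random.seed(seed)
    V = e_leak + (v_thresh - e_leak) * np.random.random(N) * 0.5
    s_ext = np.zeros(N)
    x_nmda = np.zeros(nE)
    s_nmda = np.zeros(nE)
    refr = np.zeros(N, dtype=np.int64)
    counts = np.zeros((4, n_ms), dtype=np.int64)

    d_ampa = np.exp(-dt / tau_ampa)
    d_gaba = np.exp(-dt / tau_gaba)
    d_rise = np.exp(-dt / tau_rise)
    lam_bg = bg_rate_hz * dt * 1e-3
    p0_bg = np.exp(-lam_bg)

    # AMPA/GABA gating decays uniformly, so only the per-pool sums are
    # tracked; NMDA saturates per synapse and keeps per-neuron state.
    S_ampa = np.zeros(3)  # pools A, B, NS
    S_gaba = 0.0
    SA_n = 0.0
    SB_n = 0.0
    SN_n = 0.0

    for step in range(n_steps):
        t_ms = step * dt
        bin_ms = int(t_ms)
        if bin_ms >= n_ms:
            bin_ms = n_ms - 1
        lam_a = lam_bg
        lam_b = lam_bg
        if t_ms >= stim_start_ms:
            seg = int((t_ms - stim_start_ms) / resample_ms)
            if seg >= stream_a.shape[0]:
                seg = stream_a.shape[0] - 1
            lam_a = lam_bg + stream_a[seg] * dt * 1e-3
            lam_b = lam_bg + stream_b[seg] * dt * 1e-3
        p0_a = np.exp(-lam_a)
        p0_b = np.exp(-lam_b)

        # freeze the gating sums at step start so every pool sees the same
        # state regardless of update order (spikes this step only enter the
        # sums used at the next step)
        sa0 = S_ampa[0]
        sa1 = S_ampa[1]
        sa2 = S_ampa[2]
        sg = S_gaba

        # per-pool sections: cell constants and input rates are uniform
        # within a pool, so hoist them out of the inner loop
        for tp in range(4):
            if tp == 0:
                i0, i1, lam, p0 = 0, nA, lam_a, p0_a
            elif tp == 1:
                i0, i1, lam, p0 = nA, 2 * nA, lam_b, p0_b
            elif tp == 2:
                i0, i1, lam, p0 = 2 * nA, nE, lam_bg, p0_bg
            else:
                i0, i1, lam, p0 = nE, N, lam_bg, p0_bg
            wa = w_exc[tp, 0] * sa0 + w_exc[tp, 1] * sa1 + w_exc[tp, 2] * sa2
            wn = w_exc[tp, 0] * SA_n + w_exc[tp, 1] * SB_n + w_exc[tp, 2] * SN_n
            cm_p = c_m[i0]
            gl_p = g_leak[i0]
            gx_p = g_ext[i0]
            ga_wa = g_ampa[i0] * wa
            gn_wn = g_nmda[i0] * wn
            gg_p = g_gaba[i0] * sg
            vth = v_thresh[i0]
            vre = v_reset[i0]
            rst = ref_steps[i0]
            scale = dt * 1e-3 / cm_p
            for i in range(i0, i1):
                # external Poisson drive (background + selective input)
                s_ext[i] = s_ext[i] * d_ampa + _poisson_small(lam, p0)

                if refr[i] > 0:
                    refr[i] -= 1
                    V[i] = vre
                    continue

                v = V[i]
                i_leak = gl_p * (v - e_leak)
                i_ext = gx_p * s_ext[i] * (v - e_ampa)
                i_ampa = ga_wa * (v - e_ampa)
                block = 1.0 + mg * np.exp(-0.062 * v) / 3.57
                i_nmda = gn_wn * (v - e_ampa) / block
                i_gaba = gg_p * (v - e_gaba)
                # conductances in nS, C in nF, V in mV, t in ms -> 1e-3 scale
                v = v - scale * (i_leak + i_ext + i_ampa + i_nmda + i_gaba)
                if v >= vth:
                    V[i] = vre
                    refr[i] = rst
                    counts[tp, bin_ms] += 1
                    if i < nE:
                        if tp < 2:
                            S_ampa[tp] += 1.0
                        else:
                            S_ampa[2] += 1.0
                        x_nmda[i] += 1.0
                    else:
                        S_gaba += 1.0
                else:
                    V[i] = v

        # decay pooled gating; NMDA second-order kinetics per neuron
        S_ampa[0] *= d_ampa
        S_ampa[1] *= d_ampa
        S_ampa[2] *= d_ampa
        S_gaba *= d_gaba
        SA_n = 0.0
        SB_n = 0.0
        SN_n = 0.0
        for j in range(nE):
            s = s_nmda[j] + dt * (
                -s_nmda[j] / tau_nmda + alpha * x_nmda[j] * (1.0 - s_nmda[j])
            )
            s_nmda[j] = s
            x_nmda[j] *= d_rise
            if j < nA:
                SA_n += s
            elif j < 2 * nA:
                SB_n += s
            else:
                SN_n += s

    return counts


@dataclass
class TrialSimResult:
    """One simulated trial: inputs, pool rate traces, choice and LFP proxy.

    ``time_ms`` is relative to stimulus onset (negative = initialisation).
    Pool rates are per-cell averages in Hz over the sliding window;
    ``lfp_proxy`` is the summed rate of all cells.
    """

    mu_a: float
    mu_b: float
    time_ms: np.ndarray
    rate_a: np.ndarray
    rate_b: np.ndarray
    rate_ns: np.ndarray
    rate_i: np.ndarray
    lfp_proxy: np.ndarray
    choice: str | None
    decision_time_ms: float | None
    spike_counts: np.ndarray   # (4 pools, 1 ms bins)

    @property
    def chosen_mu(self) -> float:
        return self.mu_a if self.choice == "A" else self.mu_b

    @property
    def unchosen_mu(self) -> float:
        return self.mu_b if self.choice == "A" else self.mu_a


def pool_rates(counts: np.ndarray, n_cells: int, window_ms: float = 50.0) -> np.ndarray:
    """Per-cell firing rate (Hz) from 1 ms spike counts of a pool, averaged
    over a centered sliding window."""
    w = max(int(round(window_ms)), 1)
    smoothed = uniform_filter1d(counts.astype(float), size=w, mode="nearest")
    return smoothed * 1000.0 / n_cells


def readout(
    rate_a: np.ndarray,
    rate_b: np.ndarray,
    time_ms: np.ndarray,
    threshold_hz: float = 25.0,
    margin_hz: float = 15.0,
):
    """Online choice rule: the first pool whose rate exceeds ``threshold_hz``
    while also exceeding the other pool's rate by ``margin_hz``.

    Evaluated at every sample from stimulus onset; returns
    ``(choice, decision_time_ms)`` with ``(None, None)`` if neither pool
    ever satisfies both conditions.
    """
    valid = time_ms >= 0
    a_win = valid & (rate_a > threshold_hz) & (rate_a - rate_b >= margin_hz)
    b_win = valid & (rate_b > threshold_hz) & (rate_b - rate_a >= margin_hz)
    t_a = time_ms[a_win][0] if a_win.any() else np.inf
    t_b = time_ms[b_win][0] if b_win.any() else np.inf
    if np.isinf(t_a) and np.isinf(t_b):
        return None, None
    return ("A", float(t_a)) if t_a <= t_b else ("B", float(t_b))


def simulate_trial(
    network: Network,
    mu_a: float | None = None,
    mu_b: float | None = None,
    seed: int = 0,
    streams=None,
) -> TrialSimResult:
    """Integrate one 3 s trial (500 ms settling, then 2500 ms of stimulus).

    Explicit ``mu_a``/``mu_b`` override the uniform draw (their 50 ms
    streams are then generated from the same seed); the readout labels the
    choice online but the simulation always runs to the end of the trial.
    """
    c = network.config
    if streams is not None:
        stream_a, stream_b = streams
        mu_a = float(mu_a) if mu_a is not None else float(np.mean(stream_a))
        mu_b = float(mu_b) if mu_b is not None else float(np.mean(stream_b))
    elif mu_a is None or mu_b is None:
        mu_a, mu_b, stream_a, stream_b = sample_inputs(c, seed)
    else:
        rng = stream_rng(seed, "streams")
        n_seg = int(np.ceil(c.t_stim_ms / c.input_resample_ms))
        stream_a = np.clip(rng.normal(mu_a, c.input_noise_sd_hz, n_seg), 0.0, None)
        stream_b = np.clip(rng.normal(mu_b, c.input_noise_sd_hz, n_seg), 0.0, None)

    pools = [c.n_selective, c.n_selective, c.n_nonselective, c.n_inhibitory]
    per_neuron = {}
    for name in ("c_m_nf", "g_leak_ns", "v_thresh_mv", "v_reset_mv",
                 "g_ext_ampa_ns", "g_rec_ampa_ns", "g_nmda_ns", "g_gaba_ns"):
        vals = [getattr(c.pyramidal, name)] * 3 + [getattr(c.interneuron, name)]
        per_neuron[name] = np.repeat(np.array(vals, dtype=float), pools)
    ref_steps = np.repeat(
        np.array(
            [c.pyramidal.t_refractory_ms] * 3 + [c.interneuron.t_refractory_ms]
        ) / c.dt_ms,
        pools,
    ).astype(np.int64)

    n_steps = int(round(c.t_total_ms / c.dt_ms))
    n_ms = int(round(c.t_total_ms))
    syn = c.synapse
    kernel_seed = int(np.random.SeedSequence([int(seed), 0x5EED]).generate_state(1)[0] % (2**31))
    counts = _run_trial(
        c.dt_ms, n_steps, n_ms, c.t_init_ms, c.input_resample_ms,
        network.pool_id, c.n_selective, c.n_excitatory, c.n_total,
        per_neuron["c_m_nf"], per_neuron["g_leak_ns"],
        c.pyramidal.e_leak_mv,
        per_neuron["v_thresh_mv"], per_neuron["v_reset_mv"], ref_steps,
        per_neuron["g_ext_ampa_ns"], per_neuron["g_rec_ampa_ns"],
        per_neuron["g_nmda_ns"], per_neuron["g_gaba_ns"],
        network.w_exc,
        syn.e_ampa_mv, syn.e_gaba_mv, syn.tau_ampa_ms, syn.tau_gaba_ms,
        syn.tau_nmda_decay_ms, syn.tau_nmda_rise_ms, syn.alpha_nmda_per_ms, syn.mg_mm,
        c.background_rate_hz, stream_a, stream_b, kernel_seed,
    )
    if not np.isfinite(counts).all():
        raise FloatingPointError(f"numerical instability at dt={c.dt_ms} ms")

    time_ms = np.arange(n_ms) - c.t_init_ms + 0.5
    rate_a = pool_rates(counts[POOL_A], c.n_selective, c.rate_window_ms)
    rate_b = pool_rates(counts[POOL_B], c.n_selective, c.rate_window_ms)
    rate_ns = pool_rates(counts[POOL_NS], c.n_nonselective, c.rate_window_ms)
    rate_i = pool_rates(counts[POOL_I], c.n_inhibitory, c.rate_window_ms)
    lfp = pool_rates(counts.sum(axis=0), 1, c.rate_window_ms)  # summed Hz
    choice, dtime = readout(
        rate_a, rate_b, time_ms, c.readout_threshold_hz, c.readout_margin_hz
    )
    return TrialSimResult(
        mu_a=float(mu_a), mu_b=float(mu_b), time_ms=time_ms,
        rate_a=rate_a, rate_b=rate_b, rate_ns=rate_ns, rate_i=rate_i,
        lfp_proxy=lfp, choice=choice, decision_time_ms=dtime,
        spike_counts=counts,
    )


def simulate_experiment(
    config: NetworkConfig | None = None, n_trials: int = 400, seed: int = 0
) -> list:
    """Simulate independent trials with uniformly drawn input means.

    Per-trial seeds derive from the master seed, so the dataset is
    reproducible as a whole.
    """
    config = config or NetworkConfig()
    net = build(config)
    trials = []
    for t in range(n_trials):
        trial_seed = int(
            np.random.SeedSequence([int(seed), t]).generate_state(1)[0] % (2**31)
        )
        trials.append(simulate_trial(net, seed=trial_seed))
    n_undecided = sum(1 for tr in trials if tr.choice is None)
    if n_undecided:
        logger.info("%d of %d trials reached no decision", n_undecided, n_trials)
    return trials


def _decided(dataset):
    return [tr for tr in dataset if tr.choice is not None]


def model_design(dataset):
    """Design matrix of the model regressions on decided trials:
    intercept, chose-A (+1/-1), value difference (mu_A - mu_B)/80, and
    chosen value mu_chosen/80."""
    decided = _decided(dataset)
    chose_a = np.array([1.0 if tr.choice == "A" else -1.0 for tr in decided])
    dv = np.array([(tr.mu_a - tr.mu_b) / 80.0 for tr in decided])
    cv = np.array([tr.chosen_mu / 80.0 for tr in decided])
    X = np.column_stack([np.ones(len(decided)), chose_a, dv, cv])
    names = ["intercept", "choice", "value_diff", "chosen_value"]
    factors = {"choice": [1], "value_diff": [2], "chosen_value": [3]}
    return X, names, factors, decided


def binned_pool_rates(dataset, bin_ms: float = 50.0, pool: str = "A") -> tuple:
    """Trials x bins matrix of a pool's rate, averaged in ``bin_ms`` bins."""
    decided = _decided(dataset)
    time_ms = decided[0].time_ms
    edges = np.arange(time_ms[0] - 0.5, time_ms[-1] + 0.6, bin_ms)
    centers = edges[:-1] + bin_ms / 2.0
    attr = {"A": "rate_a", "B": "rate_b", "lfp": "lfp_proxy"}[pool]
    idx = np.clip(np.digitize(time_ms, edges) - 1, 0, centers.size - 1)
    Y = np.empty((len(decided), centers.size))
    for i, tr in enumerate(decided):
        trace = getattr(tr, attr)
        Y[i] = np.bincount(idx, weights=trace, minlength=centers.size) / np.bincount(
            idx, minlength=centers.size
        )
    return Y, centers


def model_regression(dataset, bin_ms: float = 50.0, min_trials: int = 100):
    """Per-timebin regression of the model design onto A-pool rates.

    Undecided trials are excluded (count logged). Returns a
    RegressionResult with CPD timecourses for choice, value difference and
    chosen value.
    """
    decided = _decided(dataset)
    if not decided:
        raise ValueError("all trials undecided; nothing to regress")
    if len(decided) < min_trials:
        logger.warning("only %d decided trials (< %d)", len(decided), min_trials)
    X, names, factors, decided = model_design(dataset)
    Y, centers = binned_pool_rates(dataset, bin_ms, pool="A")
    return regression_result(Y, X, names, factors, centers)


def model_lfp_analysis(
    dataset,
    window_ms=(-200.0, 1500.0),
    k: int = 10,
    bin_ms: float = 50.0,
):
    """PCA of the model's LFP proxy plus the coupling analyses.

    Stacks single-trial summed-rate traces (decided trials), decomposes
    them, identifies the latency-like component by derivative similarity
    (in this network it is typically the first component), orients it so
    that positive weights mean earlier/faster dynamics, regresses its
    weights on the decision variables and decision time, and measures how
    including it as a coregressor changes the per-factor CPDs in A-pool
    firing.

    Returns a dict with the decomposition, latency component index, weight
    regressions, and CPD timecourses with/without the component.
    """
    decided = _decided(dataset)
    time_ms = decided[0].time_ms
    lfp = np.array([tr.lfp_proxy for tr in decided])
    arr = LFPArray(data=lfp, time_ms=time_ms, fs_hz=1000.0, region="model")
    stacked = stack([arr], window_ms=window_ms)
    d = decompose(stacked, k=min(k, len(decided)), sign_anchors={})
    comp = _latency_component_oriented(d)

    w = d.U[:, comp]
    dec_time = np.array([tr.decision_time_ms for tr in decided])
    cv = np.array([tr.chosen_mu / 80.0 for tr in decided])
    uv = np.array([tr.unchosen_mu / 80.0 for tr in decided])
    err = np.array([tr.chosen_mu < tr.unchosen_mu for tr in decided], dtype=float)
    Xw = np.column_stack([np.ones(len(decided)), cv, uv, err])
    names = ["intercept", "chosen_value", "unchosen_value", "error"]
    fit = ols(w, Xw, names)

    X, rnames, factors, _ = model_design(dataset)
    Y, centers = binned_pool_rates(dataset, bin_ms, pool="A")
    X_aug = np.column_stack([X, w])
    cpd_without = {f: cpd(Y, X, cols) for f, cols in factors.items()}
    cpd_with = {f: cpd(Y, X_aug, cols) for f, cols in factors.items()}
    cpd_pc = cpd(Y, X_aug, [X.shape[1]])
    return {
        "decomposition": d,
        "latency_component": comp,
        "weights": w,
        "weight_coef": dict(zip(names, fit.coef[0])),
        "weight_z": dict(zip(names, fit.z[0])),
        "corr_weight_decision_time": float(np.corrcoef(w, dec_time)[0, 1]),
        "cpd_without_pc": cpd_without,
        "cpd_with_pc": cpd_with,
        "cpd_pc": cpd_pc,
        "bin_centers_ms": centers,
    }


def half_rise_latency(X: np.ndarray, time_ms: np.ndarray) -> np.ndarray:
    """Per-trial latency of a rising trace family: first post-stimulus time
    each trace crosses the common half-rise level of the grand mean.

    The threshold is shared across trials (midpoint between the grand
    mean's pre-stimulus baseline and its end-of-window plateau); per-trial
    plateau estimates would be biased for trials still rising at the window
    edge. Traces that never cross are assigned the window end.
    """
    grand = X.mean(axis=0)
    base = grand[time_ms < 0].mean()
    n_tail = max(int(0.1 * grand.size), 1)
    thresh = 0.5 * (base + grand[-n_tail:].mean())
    crossed = X >= thresh
    crossed[:, time_ms < 0] = False
    idx = np.argmax(crossed, axis=1)
    lat = time_ms[idx].astype(float)
    lat[~crossed.any(axis=1)] = time_ms[-1]
    return lat


def _latency_component_oriented(d, search_components: int = 3) -> int:
    """Find the latency-like component of the model decomposition and
    orient it so positive weights mean earlier/faster dynamics.

    In the network's summed-rate traces, latency and final attractor state
    covary inside the *leading* component, whose ramp-like shape does not
    resemble the mean waveform's derivative; the component is therefore
    identified by correlating component weights against a signal-derived
    per-trial latency (half-rise time of each reconstructed trace) rather
    than by derivative similarity.
    """
    X_full = d.mean_timecourse + d.U @ (d.singular_values[:, None] * d.V.T)
    lat = half_rise_latency(X_full, d.time_ms)
    rs = [
        np.corrcoef(d.U[:, c], lat)[0, 1]
        for c in range(min(search_components, d.k))
    ]
    comp = int(np.argmax(np.abs(rs)))
    if rs[comp] > 0:  # positive weight must mean earlier (smaller latency)
        d.V[:, comp] *= -1
        d.U[:, comp] *= -1
        d.sign_flips[comp] = not d.sign_flips.get(comp, False)
    return comp
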