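# Methods

`pfcdyn` implements a pipeline for recovering a single-trial index of
decision dynamics from evoked field potentials, relating it to task
variables and spiking, and reproducing the findings mechanistically with a
spiking attractor network. This note documents the models, the estimators,
the numerical choices, and what the synthetic data can and cannot show.

## Task and value model

Trials present two options, each a (reward level, cost level) pair with
levels 1–4; on half the trials the cost is physical effort, on the other
half delay to reward, interleaved. Option value is reward level minus cost
level (range −3..+3). Choices follow a softmax on the left-minus-right
value difference, `P(choose L) = logistic((v_L − v_R)/T)` with temperature
`T` (default 1 value-unit). An *error* trial is a choice of the strictly
lower-valued option; ties are never errors. Chosen and unchosen value, the
action-value difference and the chosen side are the decision variables
used throughout.

## Stacked-trial PCA of evoked responses

Single-trial waveforms from all electrodes and sessions are stacked into
one matrix `X` ([electrodes × trials] rows by timepoints, default window
−200..+1000 ms at 100 Hz). Artifact rows are excluded by a within-trial
variability index (square root of the waveform's standard deviation over
time); a row is dropped when its index exceeds the mean by more than 2.32
standard deviations — the Gaussian 99th-percentile quantile truncated to
two decimals. The per-timepoint mean over retained rows (the mean
timecourse) is removed, and `X` is decomposed by SVD,
`X_demeaned = U·diag(s)·Vᵀ`. Columns of `V` are orthonormal temporal
components; rows of `U` are single-trial weights, one per retained
(electrode, trial) row, so a weight is local to an electrode while the
component's meaning is shared across the whole stack.

Because the SVD sign is arbitrary, components are anchored: the first
component is constrained positive at 190 ms and the second negative at
530 ms (anchor times snap to the nearest sample; flips are recorded). With
the bundled waveform family these conventions make positive
amplitude-component weights mean a larger response and positive
latency-component weights mean an *earlier* late component (adding a
waveform's temporal derivative advances it).

Which component is the latency index is decided from the data, not
hard-coded: each leading component is correlated with the 80 ms-smoothed
temporal derivative of the mean waveform over 200–1000 ms, and the best
match wins. For recorded-LFP-like data this selects the second component.
Demeaning is global across the stack by default, matching the rationale of
stacking — a single decomposition with one meaning everywhere; whether the
original analysis demeaned globally or per electrode is not knowable from
the available description, so a `demean="per_electrode"` flag removes each
(session, electrode) block's own mean instead.

For multi-subject source-space data, where beamforming leaves each
subject's polarity arbitrary, per-subject signs are resolved before
stacking by iteratively flipping any subject whose trial-mean response
correlates negatively with the signed grand mean of the others; the global
sign is fixed by majority (+1). Phase/power maps use zero-phase Butterworth
band-passes (octave bands 2–4, 4–8, 8–16, 16–32 Hz by default) and the
analytic signal.

## Regression and the coefficient of partial determination

Spiking is converted to rates with a 200 ms boxcar in sliding bins (10 ms
step by default). The decision model regresses, across trials, each bin's
rate onto a constant per trial type, the left-minus-right value difference,
the chosen action (±1, left positive) and the chosen value, by ordinary
least squares with classical standard errors. Value regressors are
z-scored by default so coefficients are comparable across units and
electrodes; raw-level coding is available by flag. The unique contribution
of a factor is the coefficient of partial determination,

    CPD(X_i) = [SSE(X_without_i) − SSE(X)] / SSE(X_without_i),

equal to the squared partial correlation for single-column factors. The
analytic chance level `1/(n − p)` is reported alongside so "at chance"
statements are concrete. The LFP value regression fits chosen and unchosen
value per timepoint per electrode and aggregates Z-scored coefficients
across electrodes; the ERP derivative (centered differences, 80 ms boxcar,
zero-phase even-window handling) locates where the waveform is ramping.

## Coupling analyses

Single-trial component weights always come from an electrode *other than*
the unit's own (nearest same-region electrode id, deterministic). The
augmented model adds the weight(s) to the task set and reports their CPD;
the task set is a registry — `reduced` is the five-column decision model,
`full` adds documented covariates (unchosen value, chosen/unchosen reward,
error flag, previous choice, trial index) and is user-extensible. CPD
reduction compares, per factor and timebin, a model containing the
amplitude/latency weights against a control model containing either two
high-order noise components (indices 101/102 when the decomposition
retains them, else the last two, with a warning) or weights shuffled
across trials *within chosen-value strata* — the shuffle preserves the
weights' correlation with chosen value while destroying trial-specific
coupling, which makes it the control of choice when collinearity between
weights and value must not be mistaken for mediation. Local-versus-distal
contrasts orthogonalise one region's weights with respect to another's
(plus intercept), run the reduction both ways and subtract. The
cross-regional model explains target-region firing with six terms:
constants per trial type and each source region's latency weights split by
trial type; the effort-minus-delay CPD difference per source is the
statistic of interest. Median splits sort stably, ties and the odd element
to the lower half.

## Population inference

Per-unit effects are referenced to a 500 ms pre-choice baseline and tested
with a one-sided sign-flip permutation: p = (#{permuted means ≥ observed}
+ 1)/(n_perm + 1), 10,000 flips by default. Units are put in a canonical
order before flip assignment so the p-value does not depend on caller
ordering. Multiple-comparison thresholds across timebins are estimated by
permuting whole design rows (preserving regressor covariance), refitting,
and taking the (1 − α) quantile of the maximum (and α quantile of the
minimum) Z over the test window; the thresholds are data-dependent by
design and never hard-coded. The circular–linear correlation uses the
two-harmonic form — the multiple correlation of the linear variable on
(cos θ, sin θ) — which is non-negative, rotation-invariant, and equals the
binned-regression variant in the limit; the harmonic form is implemented
because the underlying measure is only cited, not specified, in the
source material.

## Synthetic data generator

The generator is first-class, tested code; every downstream stage is
exercised against its ground-truth side tables (latents are always emitted
and never re-derived).

*Evoked responses.* The template is a fast biphasic sensory deflection
(gamma bumps peaking at 100 ms, complete by ~250 ms) plus a slow
decision-related bump peaking near 430 ms. Latency on trial i, electrode e
in region r is

    τ = −latency_gain·z(chosen value) − latency_error·error
        + shared_r + local_e,

applied to the *late component only* by evaluating the template on a
shifted grid (array templates are interpolated with boundary-value
padding, avoiding wrap-around); the fast deflection is fixed, mirroring
the observation that early-component variability is orthogonal to the late
component. Amplitude scales the whole waveform by
`1 + amp_gain·z(value sum) + N(0, σ_amp)`. Defaults: latency_gain 10 ms/z,
latency_error 15 ms (errors earlier), σ_shared 20 ms (region latent),
σ_local 8 ms (electrode latent), amp_gain 0.1, σ_amp 0.15, σ_noise 0.25
against a template peak of ~1.5 — i.e. the evoked response is plainly
visible in single trials, the regime the pipeline assumes. These are free
parameters of the generator: they were chosen once so that the documented
recovery properties (weight/latent correlations ≥ 0.8) hold at defaults,
and they are not calibrated to any recorded dataset.

*Spikes.* Inhomogeneous Poisson, 1 ms resolution. Each unit has a
selectivity gain (lognormal-ish, sd 0.5) and a preferred side; the rate is
baseline plus an early Gaussian-kernel drive by the action-value
difference, a late drive by the chosen side, and a mid-trial drive that
carries chosen value. The `mediation` dial routes that chosen-value drive
through the region's latency latent: the pathway transmits the
chosen-value signal unchanged and adds the latent's trial-specific
fluctuation scaled by the routed fraction, so coding strength is constant
while the mediated (LFP-visible) share grows. The unit gain multiplies all
drives, so chosen-value selectivity and latent coupling covary across
units — which is what makes selectivity-based median splits informative.

*Humans.* One virtual electrode per subject, a random recorded sign flip
per subject, and reaction times
`rt = base − value_slope·chosen value + tau_slope·τ + noise` truncated
positive (defaults 800 ms, 50 ms per value unit, 2 ms/ms, 100 ms noise):
slower internal dynamics mean slower responses.

All streams derive from one master seed via named child sequences
(CRC32-keyed `SeedSequence`), so regeneration is bit-identical and
independent of call order.

What the generator does *not* emulate: 1/f background spectra, oscillatory
phase resetting, eye-movement or motor artifacts, electrode drift,
inter-areal conduction delays, or any biophysical LFP forward model.
Passing recovery tests therefore shows the estimators are correct and
well-calibrated under the stated statistical structure, not that recorded
data meet that structure.

## Attractor network

Two selective pools of 240 excitatory cells, 1120 non-selective excitatory
cells and 400 inhibitory interneurons, all-to-all connected with
block-constant weights: within-pool w+ = 1.7, between-pool and
non-selective→selective w− = 1 − f(w+ − 1)/(1 − f) = 0.8765 (f = 0.15),
everything else 1. The physiological constants (conductance-based LIF with
AMPA, saturating NMDA with Mg²⁺ block, GABA; pyramidal Cm 0.5 nF, gL
25 nS, interneuron 0.2 nF/20 nS; thresholds −50 mV, reset −55 mV; NMDA
rise 2 ms, decay 100 ms, α 0.5 ms⁻¹) follow the classic two-population
reverberation model of perceptual choice and ship as editable dataclasses;
the test suite asserts behavioural contracts (spontaneous excitatory
activity a few Hz, winner-take-all, psychometric/chronometric
monotonicity), never particular voltages. Synaptic transmission latency is
omitted. Because weights are block-constant, recurrent drive is computed
from per-pool sums of gating variables (AMPA/GABA pool sums decay
analytically; NMDA keeps per-neuron state for its saturation), which makes
the integration O(N) per step; autapses are included in the pool sums
(a 1/240 effect). Euler integration, dt 0.02 ms by default with a 0.1 ms
fast mode used in tests; external input is Poisson at 2.4 kHz per cell
plus, for selective pools during the 2500 ms stimulus (after 500 ms
settling), a rate μ ~ U(20, 60) Hz redrawn every 50 ms from N(μ, 10),
rectified at zero. The choice readout fires when a pool's 50 ms sliding
rate first exceeds 25 Hz while leading the other pool by 15 Hz; the
simulation always runs the full 3 s. Undecided trials are excluded from
model regressions (counts logged).

Model regressions use the printed value normalisation (μ/80) with an
intercept, a chose-A indicator (±1), the value difference and the chosen
value, on the A-pool's 50 ms rates. The model's LFP proxy is the summed
firing rate of all cells. Its stacked decomposition differs from data in
one important way, which the analysis respects: latency and final
attractor state covary inside the *leading* component, whose ramp-like
shape does not resemble the mean waveform's derivative. The model harness
therefore identifies the latency-like component by correlating component
weights with a signal-derived per-trial latency — the first crossing of
the grand mean's half-rise level — and orients it so positive weights mean
faster dynamics. With that convention the model reproduces the data-side
pattern: weights correlate negatively with decision time, positively with
chosen value, and including them as a coregressor selectively explains
away chosen-value CPD in A-pool firing while leaving value-difference and
choice coding intact.

## Test and analysis problem sizes

The bundled suites run the full pipeline at reduced but statistically
adequate sizes chosen as deliberate design points: 500-trial sessions with
four electrodes for recovery properties; 300 trials × 50 units for the
mediation construction (with the strongly value-coupled latent,
latency_gain 25 ms/z and σ_shared 10 ms, so the routed chosen-value
variance dominates the pathway's channel noise and the reduction is
monotone in the routed fraction); 150-trial network experiments plus 150
symmetric-input trials at the 0.1 ms fast step; 500 × 1,000-permutation
repeats for sign-flip calibration. Larger runs only tighten the same
statistics.

## Known limitations

- Single-trial weights contain observation noise, so mediation estimates
  are lower bounds on the variance a noiseless dynamics index could
  explain; the recovery correlations quantify that noise for the default
  generator.
- The empirical multiplicity thresholds assume exchangeable trials; they
  do not correct across units.
- The cross-regional model is correlational; no directed or causal claim
  is encoded, and a shared third variable could produce the same pattern.
- The network is a single-area model; cross-regional phenomena have no
  mechanistic counterpart in it.
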