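# pfcdyn

Single-trial indices of prefrontal decision dynamics.

Neural correlates of economic variables — above all the value of the chosen
option — are found across prefrontal cortex, but firing at a fixed time in
the trial confounds *what* is represented with *how fast* the decision is
unfolding on that trial: any variable that speeds the decision will appear
"encoded" wherever activity is ramping. `pfcdyn` implements the analysis
programme that disentangles the two, for electrophysiologists and
computational neuroscientists working with trial-locked field potentials
(LFP or source-space MEG) and simultaneous spiking:

- **Stacked-trial PCA.** Single-trial evoked waveforms from all electrodes
  and sessions are stacked into one matrix `X` ([electrodes × trials] ×
  timepoints), demeaned, and decomposed, `X = U·diag(s)·Vᵀ`. The leading
  temporal components `V` capture cross-trial variation in waveform shape:
  an amplitude component resembling the mean response, and a latency
  component resembling its temporal derivative (adding a waveform's
  derivative shifts it earlier). The per-trial weights `U` are a
  *neurally-derived, electrode-local index of decision speed*, with
  artifact exclusion (2.32 SD rule on within-trial variability), sign
  conventions, and cross-subject sign alignment for MEG.
- **Value regression with the CPD.** Sliding-window OLS of task variables
  on firing and LFP, with the coefficient of partial determination
  `CPD(X_i) = [SSE(X_{~i}) − SSE(X)]/SSE(X_{~i})` as the variance-unique
  statistic, plus Z-scored LFP value coefficients and the smoothed ERP
  derivative.
- **Dynamics–spiking coupling.** Augmented unit models with the PC weights
  from a *neighbouring* electrode, CPD-reduction against noise-component
  and value-preserving-shuffle controls, local-vs-distal orthogonalisation,
  six-term cross-regional effort/delay models, and median splits by
  selectivity.
- **Non-parametric inference.** Sign-flip permutation tests against a
  pre-choice baseline, empirical multiple-comparison Z thresholds from
  design permutation, and the circular–linear phase correlation.
- **A spiking attractor network.** A 2000-neuron conductance-based LIF
  network (two selective pools of 240 cells, w+ = 1.7,
  w− = 1 − f(w+−1)/(1−f) = 0.8765) that makes value-guided choices by
  winner-take-all competition, with the same analysis harness applied to
  its summed-rate LFP proxy.
- **A seeded synthetic-data generator** that emulates the statistical
  structure all of the above assumes (value-dependent amplitude and
  latency, shared-plus-local latency latents, mediated chosen-value
  spiking, MEG-style sign flips and reaction times), with ground-truth
  side tables for every latent.

No recorded datasets ship with the package; all stages consume either the
generator's output or user data in the documented HDF5 + CSV container
format (see `pfcdyn.io`).

## Worked example

```python
import numpy as np
from pfcdyn import synthetic as syn, pca, regression as reg

trials = syn.gen_trial_table(500, softmax_temperature=1.0, seed=7)
arrays, truth = syn.gen_lfp(trials, n_electrodes_per_region=4,
                            regions=("DLPFC",), seed=7)

stacked = pca.stack(arrays)
mask = pca.artifact_mask(stacked)
decomp = pca.decompose(stacked, k=10, mask=mask)
lc = pca.latency_component(decomp)
print(f"stacked {stacked.n_rows} rows, excluded {mask.sum()}")
print(f"explained variance (top 3): {np.round(decomp.explained_variance_fraction[:3], 3)}")
print(f"latency component: PC{lc + 1}")

rows = trials.set_index("trial_id").loc[decomp.row_index.trial_id].reset_index()
print(reg.pc_weight_regression(decomp.U[:, lc], rows).round(3))
```

prints

```
stacked 2000 rows, excluded 22
explained variance (top 3): [0.145 0.059 0.011]
latency component: PC2
                 coef     se       z
intercept      -0.008  0.001  -9.260
chosen_value    0.005  0.000  12.302
unchosen_value -0.003  0.000  -6.698
error           0.017  0.002   8.929
```

Four electrodes × 500 trials give 2000 stacked rows, of which 22 are
excluded as artifacts. The derivative-similarity statistic identifies PC2
as the latency component. Regressing its single-trial weights on the
decision variables recovers the generative structure: higher chosen value
and error trials both push the weights positive — the evoked response
peaks *earlier* on those trials — which is exactly the signature of
faster decision dynamics the index is designed to expose.

The same decomposition drives the coupling analyses
(`pfcdyn.coupling.augmented_unit_model`, `cpd_reduction`,
`cross_region_model`) and the network harness
(`pfcdyn.network.simulate_experiment`, `model_lfp_analysis`).

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
pfcdyn simulate --trials 500 --seed 7 --out dataset.h5   # + dataset.trials.csv
pfcdyn pca --in dataset.h5 --region DLPFC --out pca.h5
pfcdyn regress --what lfp --in dataset.h5 --trials dataset.trials.csv --out lfp.csv
pfcdyn network --trials 400 --seed 7 --out model.h5
```

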