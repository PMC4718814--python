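"""Coupling single-trial LFP component weights to unit firing.

These analyses ask whether the speed/amplitude of the locally recorded
evoked response — the single-trial PC weights from a *neighbouring*
electrode, never the unit's own — explains firing variance beyond the task
variables, and whether apparent chosen-value coding is mediated by those
dynamics. Controls: high-order noise components from the same decomposition,
and shuffles that preserve the weights' correlation with chosen value while
destroying trial-specific coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BinnedRates, RegressionResult
from .regression import cpd, decision_design, orthogonalize, regression_result
from .synthetic import zscore

logger = logging.getLogger(__name__)


def _reduced_design(trials, zscore_values=True):
    return decision_design(trials, zscore_values)


def _full_design(trials, zscore_values=True):
    """Reduced set plus plausible task covariates.

    The original full set of nuisance regressors is not enumerable from the
    available description, so this registry entry extends the reduced set
    with documented covariates; headline analyses are expected to behave
    similarly under either set, and callers may register their own.
    """
    X, names, factors = decision_design(trials, zscore_values)
    chose_left = trials["chosen_side"] == "L"
    prev_choice = np.where(chose_left, 1.0, -1.0)
    prev_choice = np.concatenate([[0.0], prev_choice[:-1]])
    extras = {
        "unchosen_value": zscore(trials["unchosen_value"].to_numpy(float)),
        "chosen_reward": zscore(
            np.where(chose_left, trials["reward_left"], trials["reward_right"]).astype(float)
        ),
        "unchosen_reward": zscore(
            np.where(chose_left, trials["reward_right"], trials["reward_left"]).astype(float)
        ),
        "is_error": trials["is_error"].to_numpy(float),
        "previous_choice": prev_choice,
        "trial_index": zscore(np.arange(len(trials), dtype=float)),
    }
    X = np.column_stack([X] + list(extras.values()))
    names = names + list(extras)
    return X, names, factors


#: name -> callable(trials, zscore_values) -> (X, names, factors)
REGRESSOR_SETS = {"reduced": _reduced_design, "full": _full_design}


@dataclass
class CouplingSpec:
    """Configuration of a unit/LFP coupling analysis."""

    regressor_set: str = "reduced"
    components: tuple = (0, 1)
    control: str = "noise_pcs"  # noise_pcs | shuffled_pcs | none
    unit_electrode: int | None = None
    source_electrode: int | None = None

    def __post_init__(self) -> None:
        if self.regressor_set not in REGRESSOR_SETS:
            raise ValueError(f"unknown regressor set {self.regressor_set!r}")
        if (
            self.unit_electrode is not None
            and self.unit_electrode == self.source_electrode
        ):
            raise ValueError("PC weights must come from a different electrode than the unit")


def neighbouring_electrode(unit_electrode: int, candidates) -> int:
    """Deterministic neighbouring-electrode pairing: the nearest same-region
    electrode by id, excluding the unit's own."""
    others = sorted(e for e in candidates if e != unit_electrode)
    if not others:
        raise ValueError("no other electrode available in the region")
    pick = min(others, key=lambda e: (abs(e - unit_electrode), e))
    logger.info("paired unit electrode %s with LFP electrode %s", unit_electrode, pick)
    return pick


def _pc_matrix(pc_weights) -> np.ndarray:
    W = np.asarray(pc_weights, float)
    return W[:, None] if W.ndim == 1 else W


def augmented_unit_model(
    rates: BinnedRates,
    trials: pd.DataFrame,
    pc_weights,
    spec: CouplingSpec | None = None,
) -> RegressionResult:
    """Task-variable model augmented with single-trial PC weight(s).

    Returns the usual per-factor CPDs plus ``cpd["pc"]``, the per-bin CPD of
    the PC regressor block after partialling out the task set.
    """
    spec = spec or CouplingSpec()
    W = _pc_matrix(pc_weights)
    if W.shape[0] != len(trials) or rates.n_trials != len(trials):
        raise ValueError("rates, trials and PC weights must be row-aligned")
    X, names, factors = REGRESSOR_SETS[spec.regressor_set](trials)
    p0 = X.shape[1]
    X = np.column_stack([X, W])
    names = names + [f"pc_w{i}" for i in range(W.shape[1])]
    factors = dict(factors, pc=list(range(p0, p0 + W.shape[1])))
    return regression_result(rates.rates, X, names, factors, rates.bin_centers_ms)


def cpd_reduction(
    rates: BinnedRates,
    trials: pd.DataFrame,
    pcs: np.ndarray,
    control_pcs: np.ndarray,
    regressor_set: str = "reduced",
) -> dict:
    """Reduction in per-factor CPD attributable to the PC weights.

    For each task factor, DeltaCPD = CPD(factor | task + control PCs)
    - CPD(factor | task + PC1/2), per timebin. Positive values mean the
    component weights absorb variance previously credited to the factor;
    the reduction can never exceed the control-model CPD itself.
    """
    X, names, factors = REGRESSOR_SETS[regressor_set](trials)
    X_pc = np.column_stack([X, _pc_matrix(pcs)])
    X_ctrl = np.column_stack([X, _pc_matrix(control_pcs)])
    out = {}
    for f, cols in factors.items():
        out[f] = cpd(rates.rates, X_ctrl, cols) - cpd(rates.rates, X_pc, cols)
    return out


def shuffled_pc_control(
    pc_weights, trials: pd.DataFrame, preserve: str = "chosen_value", seed: int = 0
) -> np.ndarray:
    """Permute PC weights across trials within strata of ``preserve``.

    Destroys trial-specific coupling while preserving the weights'
    correlation with the preserved variable. Singleton strata are left in
    place (logged).
    """
    W = _pc_matrix(pc_weights)
    strata = trials[preserve].to_numpy()
    rng = np.random.default_rng(seed)
    out = W.copy()
    for val in np.unique(strata):
        rows = np.flatnonzero(strata == val)
        if rows.size < 2:
            logger.info("stratum %s=%r is a singleton; left unshuffled", preserve, val)
            continue
        out[rows] = W[rows[rng.permutation(rows.size)]]
    return out if np.asarray(pc_weights).ndim > 1 else out[:, 0]


def local_vs_distal(
    rates: BinnedRates,
    trials: pd.DataFrame,
    local_pcs: np.ndarray,
    distal_pcs: np.ndarray,
    control_pcs: np.ndarray,
    regressor_set: str = "reduced",
) -> dict:
    """Local-versus-distal orthogonalisation contrast.

    Orthogonalises the local PC weights with respect to the distal ones,
    runs :func:`cpd_reduction`, repeats with the roles reversed, and returns
    the former minus the latter per factor. Positive values mean local
    dynamics absorb more of the factor's variance than distal dynamics.
    """
    L, D = _pc_matrix(local_pcs), _pc_matrix(distal_pcs)
    L_orth = np.column_stack([orthogonalize(L[:, j], D) for j in range(L.shape[1])])
    D_orth = np.column_stack([orthogonalize(D[:, j], L) for j in range(D.shape[1])])
    red_local = cpd_reduction(rates, trials, L_orth, control_pcs, regressor_set)
    red_distal = cpd_reduction(rates, trials, D_orth, control_pcs, regressor_set)
    return {f: red_local[f] - red_distal[f] for f in red_local}


def cross_region_model(
    rates: BinnedRates,
    trials: pd.DataFrame,
    ofc_pc2: np.ndarray,
    acc_pc2: np.ndarray,
) -> dict:
    """Six-term cross-regional model of target-region firing.

    Design: constants for effort and delay trials, plus the OFC and ACC
    latency-component weights split by trial type (weight on trials of that
    type, zero elsewhere). Returns per-bin CPDs for the four source terms
    and the effort-minus-delay CPD difference per source region.
    """
    eff = (trials["trial_type"] == "effort").to_numpy(float)
    dly = (trials["trial_type"] == "delay").to_numpy(float)
    if eff.sum() == 0 or dly.sum() == 0:
        raise ValueError("cross-region model needs both trial types")
    ofc = np.asarray(ofc_pc2, float)
    acc = np.asarray(acc_pc2, float)
    X = np.column_stack([eff, dly, ofc * eff, ofc * dly, acc * eff, acc * dly])
    names = ["const_effort", "const_delay", "ofc_effort", "ofc_delay", "acc_effort", "acc_delay"]
    cpds = {name: cpd(rates.rates, X, [j]) for j, name in enumerate(names) if j >= 2}
    return {
        "cpd": cpds,
        "effort_minus_delay": {
            "OFC": cpds["ofc_effort"] - cpds["ofc_delay"],
            "ACC": cpds["acc_effort"] - cpds["acc_delay"],
        },
    }


def median_split(selectivity) -> tuple:
    """Split units into low/high groups by a selectivity scalar.

    Stable sort; ties go to the lower half; the lower half takes the extra
    unit when n is odd. Returns ``(low_indices, high_indices)``.
    """
    s = np.asarray(selectivity, float)
    order = np.argsort(s, kind="stable")
    n_low = (len(s) + 1) // 2
    return np.sort(order[:n_low]), np.sort(order[n_low:])


def pc_weight_cross_correlation(weights_by_electrode: dict) -> pd.DataFrame:
    """Pairwise Pearson correlation of trial-aligned weights across
    simultaneously recorded electrodes.

    ``weights_by_electrode`` maps electrode id -> (region, weights). Returns
    one row per unordered pair with the correlation and a within-region
    flag; medians can be taken per group by the caller.
    """
    items = sorted(weights_by_electrode.items())
    rows = []
    for i, (e1, (r1, w1)) in enumerate(items):
        for e2, (r2, w2) in items[i + 1:]:
            w1a, w2a = np.asarray(w1, float), np.asarray(w2, float)
            if w1a.size != w2a.size:
                logger.info("electrodes %s/%s have mismatched trials; pair skipped", e1, e2)
                continue
            rows.append(
                {
                    "electrode_a": e1,
                    "electrode_b": e2,
                    "region_a": r1,
                    "region_b": r2,
                    "within_region": r1 == r2,
                    "r": float(np.corrcoef(w1a, w2a)[0, 1]),
                }
            )
    return pd.DataFrame(rows)
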