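"""Synthetic trial and Delphi-panel generator with known ground truth.

The real patient-level trial data are not publicly deposited, so every stage
of the pipeline is exercised against simulated data whose generating
parameters are known exactly.  The generator emulates the trial's structure:

* 190 enrolled moderate-to-severe patients (baseline NRS >= 3.3) all start
  add-on treatment in a 4-week single-blind cycle;
* early responders (NRS improvement >= 20% vs baseline; 134 by default)
  enter a wash-out cycle, of whom a fixed fraction re-qualify (106 by
  default);
* 53 + 53 re-qualifiers are randomised to double-blind add-on treatment or
  placebo for three further cycles; everyone else is retained as a
  single-blind-only stratum with observations truncated at the point of
  leaving the trial.

Severity evolves as a first-order 3-state chain with a separate matrix per
phase (single-blind, wash-out, double-blind per arm).  NRS values are drawn
uniformly inside the severity band of the latent state, so the cycle-level
estimators recover the phase chains exactly in the large-sample limit.
Utilities are state mean + patient random effect + observation noise; a
patient's latent frailty also tilts their transition draws toward improvement
when the coupling coefficient ``rho`` is positive, creating the
transition-utility correlation that distinguishes bootstrap from independent
Monte Carlo uncertainty propagation.

The Delphi generator emits eight experts with log-normal per-item quantities
around severity-monotone means, plus a fixed tariff table.  The bundled
standard-care severity matrix (``SYNTHETIC_SOC_MATRIX``) is a synthetic
stand-in for the external observational long-term matrix used by the
published model, whose values are only available in supplementary material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import published
from .costing import DelphiPanelData, StateCostSet, UnitCostTable
from .trial_data import (
    NRS_MILD_UPPER,
    NRS_MODERATE_UPPER,
    SeverityState,
    Stratum,
    TrialDataset,
    UtilitySet,
)

__all__ = [
    "GeneratorConfig",
    "SYNTHETIC_SOC_MATRIX",
    "DEFAULT_DELPHI_ITEMS",
    "generate_trial",
    "generate_delphi_panel",
    "true_state_costs",
    "true_point_result",
]

#: synthetic stand-in for the long-term observational standard-care severity
#: matrix (rows mild/moderate/severe): sticky, slowly worsening dynamics
SYNTHETIC_SOC_MATRIX = np.array(
    [
        [0.80, 0.17, 0.03],
        [0.03, 0.85, 0.12],
        [0.00, 0.05, 0.95],
    ]
)

#: synthetic relapse dynamics for the placebo double-blind arm: washed-out
#: responders drift back toward moderate/severe spasticity
DEFAULT_PLACEBO_MATRIX = np.array(
    [
        [0.70, 0.25, 0.05],
        [0.05, 0.80, 0.15],
        [0.01, 0.10, 0.89],
    ]
)

#: Delphi item set: name -> (per-cycle mean quantity mild/moderate/severe,
#: EUR tariff).  Quantities are severity-monotone micro-costing inputs.
DEFAULT_DELPHI_ITEMS: dict[str, tuple[tuple[float, float, float], float]] = {
    "antispastic_drug_pack": ((1.0, 1.5, 2.0), 35.0),
    "gp_visit": ((0.3, 0.5, 0.8), 27.0),
    "neurologist_visit": ((0.15, 0.30, 0.50), 45.0),
    "physiotherapy_session": ((4.0, 8.0, 12.0), 25.0),
    "home_nursing_visit": ((0.5, 2.0, 8.0), 40.0),
    "hospital_day": ((0.05, 0.30, 1.00), 450.0),
    "emergency_visit": ((0.02, 0.06, 0.12), 150.0),
    "mri_scan": ((0.05, 0.08, 0.10), 220.0),
    "blood_test": ((0.20, 0.30, 0.40), 30.0),
}

_BAND_LO = np.array([0.0, NRS_MILD_UPPER, NRS_MODERATE_UPPER])
_BAND_HI = np.array([NRS_MILD_UPPER, NRS_MODERATE_UPPER, 10.0])


def _default_single_blind() -> np.ndarray:
    return published.sativex_severity_chain(1)


def _default_washout() -> np.ndarray:
    return published.sativex_severity_chain(2)


def _default_db_sativex() -> np.ndarray:
    return np.stack([published.sativex_severity_chain(c) for c in (3, 4, 5)])


def _default_db_placebo() -> np.ndarray:
    return np.stack([DEFAULT_PLACEBO_MATRIX] * 3)


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of the synthetic trial and panel."""

    n_enrolled: int = 190
    n_db_per_arm: int = 53
    responder_fraction: float = 134.0 / 190.0
    washout_pass_fraction: float = 106.0 / 134.0
    n_cycles_observed: int = 5
    #: baseline probability of entering in the moderate (vs severe) band
    baseline_moderate_fraction: float = 0.5
    #: baseline NRS ranges; entrants had failed prior therapy, so baselines
    #: sit in the upper part of each band (and the 20% responder criterion
    #: is attainable from most post-titration states)
    baseline_moderate_range: tuple[float, float] = (4.5, NRS_MODERATE_UPPER)
    baseline_severe_range: tuple[float, float] = (7.5, 10.0)
    single_blind_chain: np.ndarray = field(default_factory=_default_single_blind)
    washout_chain: np.ndarray = field(default_factory=_default_washout)
    db_sativex_chains: np.ndarray = field(default_factory=_default_db_sativex)
    db_placebo_chains: np.ndarray = field(default_factory=_default_db_placebo)
    utility_means: tuple[float, float, float] = (0.594, 0.509, 0.499)
    sigma_patient: float = 0.08
    sigma_obs: float = 0.05
    #: coupling between a patient's utility level and their propensity to
    #: transition toward milder states (0 = independent)
    rho: float = 0.5
    n_experts: int = 8
    delphi_sigma: float = 0.35
    delphi_items: dict = field(default_factory=lambda: dict(DEFAULT_DELPHI_ITEMS))

    def __post_init__(self) -> None:
        self.single_blind_chain = np.asarray(self.single_blind_chain, dtype=float)
        self.washout_chain = np.asarray(self.washout_chain, dtype=float)
        self.db_sativex_chains = np.asarray(self.db_sativex_chains, dtype=float)
        self.db_placebo_chains = np.asarray(self.db_placebo_chains, dtype=float)
        if not 0.0 < self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in (0, 1]")
        if not 0.0 < self.washout_pass_fraction <= 1.0:
            raise ValueError("washout_pass_fraction must lie in (0, 1]")
        if self.sigma_patient < 0 or self.sigma_obs < 0:
            raise ValueError("noise standard deviations must be non-negative")
        n_db_cycles = self.n_cycles_observed - 2
        for name in ("db_sativex_chains", "db_placebo_chains"):
            arr = getattr(self, name)
            if arr.shape != (n_db_cycles, 3, 3):
                raise ValueError(f"{name} must be ({n_db_cycles}, 3, 3)")

    def true_utilities(self) -> UtilitySet:
        return UtilitySet(*self.utility_means)


def _tilted_step(
    states: np.ndarray, chain: np.ndarray, z: np.ndarray, rho: float, rng
) -> np.ndarray:
    """One chain step for all patients, tilted by latent frailty.

    Row probabilities are reweighted by ``exp(-rho * z * severity)`` so
    positive-frailty (high-utility) patients favour milder destinations when
    ``rho > 0``; ``rho = 0`` reproduces the chain exactly.
    """
    p = chain[states]
    if rho != 0.0:
        tilt = np.exp(-rho * z[:, None] * np.arange(3)[None, :])
        p = p * tilt
        p = p / p.sum(axis=1, keepdims=True)
    u = rng.random(len(states))
    cum = np.cumsum(p, axis=1)
    return np.minimum((u[:, None] > cum).sum(axis=1), 2).astype(np.int8)


def _uniform_in(lo: np.ndarray, hi: np.ndarray, rng) -> np.ndarray:
    return lo + (hi - lo) * rng.random(len(lo))


def generate_trial(config: GeneratorConfig, seed) -> TrialDataset:
    """Simulate one complete trial dataset.

    Responder and wash-out gates select exact-count random subsets (134
    responders and 106 re-qualifiers under the defaults) so that the default
    configuration reproduces the published patient flow - and in particular
    the 53/53/84 stratum split - on every seed.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    n = cfg.n_enrolled
    n_db = 2 * cfg.n_db_per_arm
    t_max = cfg.n_cycles_observed + 1  # timepoints: start of cycles 1..n+1

    z = rng.standard_normal(n)
    # baseline: moderate-to-severe entry criterion
    state = np.where(
        rng.random(n) < cfg.baseline_moderate_fraction,
        SeverityState.MODERATE,
        SeverityState.SEVERE,
    ).astype(np.int8)
    states = np.full((n, t_max), -1, dtype=np.int8)
    nrs = np.full((n, t_max), np.nan)
    states[:, 0] = state
    base_lo = np.where(
        state == SeverityState.MODERATE,
        cfg.baseline_moderate_range[0],
        cfg.baseline_severe_range[0],
    )
    base_hi = np.where(
        state == SeverityState.MODERATE,
        cfg.baseline_moderate_range[1],
        cfg.baseline_severe_range[1],
    )
    nrs[:, 0] = _uniform_in(base_lo, base_hi, rng)

    # --- single-blind cycle: everyone on add-on treatment ----------------
    s1 = _tilted_step(states[:, 0], cfg.single_blind_chain, z, cfg.rho, rng)
    states[:, 1] = s1

    # responder gate: >= 20% NRS improvement vs baseline, with the NRS draw
    # placed inside the destination band so that exactly K responders arise
    # whenever the band geometry allows it
    thr = 0.8 * nrs[:, 0]
    lo, hi = _BAND_LO[s1], _BAND_HI[s1]
    can_resp = thr > lo  # the band has room below the improvement threshold
    can_non = hi > thr
    k_target = int(round(cfg.responder_fraction * n))
    forced_resp = ~can_non
    free = can_resp & can_non
    n_needed = k_target - int(forced_resp.sum())
    free_idx = np.flatnonzero(free)
    responder = forced_resp.copy()
    if n_needed > 0:
        pick = rng.choice(free_idx, size=min(n_needed, free_idx.size), replace=False)
        responder[pick] = True
    resp_hi = np.minimum(hi, thr)
    non_lo = np.maximum(lo, thr)
    nrs[:, 1] = np.where(
        responder,
        _uniform_in(lo, np.maximum(resp_hi, lo), rng),
        _uniform_in(np.minimum(non_lo, hi), hi, rng),
    )

    # --- wash-out cycle: responders off treatment ------------------------
    resp_idx = np.flatnonzero(responder)
    # the pass count targets the configured flow (106 of 134 by default);
    # band geometry can leave the responder count a patient or two short of
    # its own target, so cap by what was realised
    n_pass = min(int(round(cfg.washout_pass_fraction * k_target)), resp_idx.size)
    if n_pass < n_db:
        raise ValueError(
            f"only {n_pass} wash-out re-qualifiers but {n_db} are needed for "
            "randomisation; increase n_enrolled or the gate fractions"
        )
    passers = rng.choice(resp_idx, size=n_pass, replace=False)
    randomised = rng.choice(passers, size=n_db, replace=False)
    s2 = _tilted_step(states[randomised, 1], cfg.washout_chain, z[randomised], cfg.rho, rng)
    states[randomised, 2] = s2
    nrs[randomised, 2] = _uniform_in(_BAND_LO[s2], _BAND_HI[s2], rng)

    # --- double-blind phase ----------------------------------------------
    stratum = np.full(n, Stratum.SINGLE_BLIND_ONLY, dtype=np.int8)
    arm_order = rng.permutation(randomised)
    sat_idx = arm_order[: cfg.n_db_per_arm]
    plc_idx = arm_order[cfg.n_db_per_arm :]
    stratum[sat_idx] = Stratum.DB_SATIVEX
    stratum[plc_idx] = Stratum.DB_PLACEBO
    for k in range(cfg.n_cycles_observed - 2):
        t = 2 + k
        for idx, chains in ((sat_idx, cfg.db_sativex_chains), (plc_idx, cfg.db_placebo_chains)):
            nxt = _tilted_step(states[idx, t], chains[k], z[idx], cfg.rho, rng)
            states[idx, t + 1] = nxt
            nrs[idx, t + 1] = _uniform_in(_BAND_LO[nxt], _BAND_HI[nxt], rng)

    # --- utilities at every observed timepoint ----------------------------
    observed = states >= 0
    means = np.asarray(cfg.utility_means)
    utility = np.full((n, t_max), np.nan)
    noise = rng.standard_normal((n, t_max)) * cfg.sigma_obs
    vals = means[np.where(observed, states, 0)] + cfg.sigma_patient * z[:, None] + noise
    utility[observed] = np.clip(vals, -1.0, 1.0)[observed]

    ids = np.array([f"P{i + 1:04d}" for i in range(n)], dtype=object)
    return TrialDataset(ids, stratum, nrs, utility)


def generate_delphi_panel(
    config: GeneratorConfig, seed
) -> tuple[DelphiPanelData, UnitCostTable]:
    """Simulate the expert panel and its tariff table.

    Expert quantities are log-normal around the configured per-state means
    (``delphi_sigma`` is the log-scale spread; 0 collapses the panel to the
    means), so quantities stay non-negative and severity-monotone in
    expectation.
    """
    rng = np.random.default_rng(seed)
    items = list(config.delphi_items)
    means = np.array([config.delphi_items[i][0] for i in items]).T  # (3, n_items)
    tariffs = {i: config.delphi_items[i][1] for i in items}
    sigma = config.delphi_sigma
    if sigma == 0:
        q = np.broadcast_to(means, (config.n_experts, 3, len(items))).copy()
    else:
        mu = np.log(np.maximum(means, 1e-12)) - 0.5 * sigma**2
        q = np.exp(mu + sigma * rng.standard_normal((config.n_experts, 3, len(items))))
        q[:, means == 0] = 0.0
    experts = [f"E{e + 1}" for e in range(config.n_experts)]
    return DelphiPanelData(experts, items, q), UnitCostTable(tariffs)


def true_state_costs(config: GeneratorConfig) -> StateCostSet:
    """Generator-implied expected standard-care cost per cycle and state."""
    items = list(config.delphi_items)
    means = np.array([config.delphi_items[i][0] for i in items]).T
    tariff = np.array([config.delphi_items[i][1] for i in items])
    return StateCostSet(*(means @ tariff).tolist())


def true_point_result(
    gen_config: GeneratorConfig,
    model_config=None,
    scenario: str = "base",
    soc_matrix: np.ndarray | None = None,
):
    """Model outcome implied by the generator's exact parameters.

    Plugs the generator's phase chains, state utility means and expected
    state costs straight into the scenario wiring - the plim of the
    estimate-then-run pipeline at ``rho = 0`` - and is the reference point
    for bootstrap coverage checks.
    """
    from .markov import ModelConfig
    from .pipeline import SCENARIOS, _run_from_parameters
    from .trial_data import TransitionEstimate

    model_config = model_config or ModelConfig()
    if soc_matrix is None:
        soc_matrix = SYNTHETIC_SOC_MATRIX

    def _est(cycle: int, matrix: np.ndarray) -> TransitionEstimate:
        return TransitionEstimate(
            cycle=cycle,
            matrix=np.asarray(matrix, dtype=float),
            n_at_risk=0,
            row_counts=np.zeros(3),
        )

    sat = [_est(1, gen_config.single_blind_chain), _est(2, gen_config.washout_chain)]
    sat += [_est(3 + k, m) for k, m in enumerate(gen_config.db_sativex_chains)]
    soc = None
    if SCENARIOS[scenario].soc_source == "trial":
        plc = gen_config.db_placebo_chains
        soc = [_est(1, plc[0]), _est(2, plc[0])] + [
            _est(3 + k, m) for k, m in enumerate(plc)
        ]
    return _run_from_parameters(
        SCENARIOS[scenario],
        sat,
        soc,
        gen_config.true_utilities(),
        true_state_costs(gen_config),
        model_config,
        np.asarray(soc_matrix, dtype=float),
        None,
    )
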