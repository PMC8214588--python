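"""Shared wiring from data to model outcomes.

Maps trial strata onto per-cycle transition estimates, assembles the
severity-matrix schedule of each arm under the three published scenarios,
and evaluates a single deterministic (point-estimate) model run.  Both the
command-line scenarios layer and the PSA engines are built on this module.

Cycle-to-source mapping for the on-treatment arm: cycle 1 uses all enrolled
patients (everyone was on add-on treatment in the single-blind phase),
cycle 2 uses the randomised strata (the only patients observed across the
wash-out), cycles 3-5 use the double-blind treatment stratum.  When the
standard-care arm is estimated from the trial (scenario S1), cycles 3-5 come
from the double-blind placebo stratum, cycles 1-2 back-fill with the first
available (cycle-3) estimate, and later cycles carry the cycle-5 estimate
forward, mirroring the base case's carry-forward rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .costing import (
    DelphiPanelData,
    DrugPrice,
    StateCostSet,
    UnitCostTable,
    cost_matrix,
    state_cost_per_cycle,
)
from .markov import (
    ArmOutcome,
    IncrementalResult,
    ModelConfig,
    TransitionSchedule,
    incremental_outcomes,
    run_cohort,
)
from .trial_data import (
    Stratum,
    TransitionEstimate,
    TrialDataset,
    UtilitySet,
    estimate_transition_matrix,
    estimate_utilities,
)

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "PointResult",
    "estimate_sativex_matrices",
    "estimate_soc_matrices",
    "build_schedule",
    "evaluate_point",
]

N_TRIAL_CYCLES = 5

#: which strata inform the on-treatment transition estimate of each trial cycle
SATIVEX_SOURCES: dict[int, tuple[Stratum, ...]] = {
    1: (Stratum.SINGLE_BLIND_ONLY, Stratum.DB_SATIVEX, Stratum.DB_PLACEBO),
    2: (Stratum.DB_SATIVEX, Stratum.DB_PLACEBO),
    3: (Stratum.DB_SATIVEX,),
    4: (Stratum.DB_SATIVEX,),
    5: (Stratum.DB_SATIVEX,),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Where each arm's severity matrices come from.

    ``sat_tail`` governs on-treatment cycles beyond the trial window:
    ``carry_forward`` keeps the cycle-5 estimate (sustained benefit),
    ``external`` switches to the standard-care matrix while drug costs
    continue (no benefit beyond the trial).  ``soc_source`` is ``external``
    (long-term observational matrix) or ``trial`` (placebo-stratum
    estimates).
    """

    scenario_id: str
    sat_tail: str
    soc_source: str


SCENARIOS: dict[str, ScenarioSpec] = {
    "base": ScenarioSpec("base", sat_tail="carry_forward", soc_source="external"),
    "s1": ScenarioSpec("s1", sat_tail="carry_forward", soc_source="trial"),
    "s2": ScenarioSpec("s2", sat_tail="external", soc_source="external"),
}


def estimate_sativex_matrices(
    trial: TrialDataset, warn: bool = True
) -> list[TransitionEstimate]:
    """Per-cycle on-treatment severity estimates for trial cycles 1-5."""
    return [
        estimate_transition_matrix(trial, cycle, SATIVEX_SOURCES[cycle], warn=warn)
        for cycle in range(1, N_TRIAL_CYCLES + 1)
    ]


def estimate_soc_matrices(
    trial: TrialDataset, warn: bool = True
) -> list[TransitionEstimate]:
    """Standard-care estimates from the placebo stratum (scenario S1).

    Only the double-blind cycles (3-5) are observed off active treatment;
    cycles 1-2 reuse the cycle-3 estimate.
    """
    db = [
        estimate_transition_matrix(trial, cycle, (Stratum.DB_PLACEBO,), warn=warn)
        for cycle in range(3, N_TRIAL_CYCLES + 1)
    ]
    return [db[0], db[0]] + db


def build_schedule(
    scenario: ScenarioSpec | str,
    sat_estimates: list[TransitionEstimate],
    config: ModelConfig,
    soc_matrix: np.ndarray | None = None,
    soc_estimates: list[TransitionEstimate] | None = None,
) -> TransitionSchedule:
    """Assemble the full 7-state schedule for one scenario."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if len(sat_estimates) != N_TRIAL_CYCLES:
        raise ValueError(f"expected {N_TRIAL_CYCLES} on-treatment estimates")

    if scenario.soc_source == "external":
        if soc_matrix is None:
            raise ValueError(
                f"scenario {scenario.scenario_id!r} needs an external "
                "standard-care severity matrix"
            )
        soc_by_cycle = [np.asarray(soc_matrix, dtype=float)] * config.n_cycles
    else:
        if soc_estimates is None:
            raise ValueError(
                f"scenario {scenario.scenario_id!r} needs placebo-stratum estimates"
            )
        socs = [e.matrix for e in soc_estimates]
        soc_by_cycle = socs + [socs[-1]] * (config.n_cycles - len(socs))

    sats = [e.matrix for e in sat_estimates]
    if scenario.sat_tail == "carry_forward":
        sat_tail = [sats[-1]] * (config.n_cycles - len(sats))
    elif scenario.sat_tail == "external":
        # still on drug, but severity now follows standard-care dynamics
        sat_tail = [soc_by_cycle[c] for c in range(len(sats), config.n_cycles)]
    else:
        raise ValueError(f"unknown sat_tail {scenario.sat_tail!r}")
    sat_by_cycle = sats + sat_tail
    return TransitionSchedule.from_severity(sat_by_cycle, soc_by_cycle, config)


@dataclass
class PointResult:
    """One deterministic model run: both arms plus per-horizon contrasts."""

    treatment: ArmOutcome
    control: ArmOutcome
    incrementals: dict[int, IncrementalResult]
    utilities: UtilitySet
    state_costs: StateCostSet
    sat_estimates: list[TransitionEstimate] = field(default_factory=list)
    soc_estimates: list[TransitionEstimate] | None = None


def evaluate_point(
    trial: TrialDataset,
    panel: DelphiPanelData,
    tariffs: UnitCostTable,
    config: ModelConfig,
    scenario: ScenarioSpec | str = "base",
    soc_matrix: np.ndarray | None = None,
    price: DrugPrice | None = None,
    fallback_utilities: UtilitySet | None = None,
    warn: bool = True,
) -> PointResult:
    """Estimate all parameters from the data and run both arms once."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    sat_est = estimate_sativex_matrices(trial, warn=warn)
    soc_est = (
        estimate_soc_matrices(trial, warn=warn)
        if scenario.soc_source == "trial"
        else None
    )
    utilities = estimate_utilities(trial, fallback=fallback_utilities)
    state_costs = state_cost_per_cycle(panel, tariffs)
    return _run_from_parameters(
        scenario, sat_est, soc_est, utilities, state_costs, config, soc_matrix, price
    )


def _run_from_parameters(
    scenario: ScenarioSpec,
    sat_estimates: list[TransitionEstimate],
    soc_estimates: list[TransitionEstimate] | None,
    utilities: UtilitySet,
    state_costs: StateCostSet,
    config: ModelConfig,
    soc_matrix: np.ndarray | None,
    price: DrugPrice | None,
) -> PointResult:
    schedule = build_schedule(scenario, sat_estimates, config, soc_matrix, soc_estimates)
    costs = cost_matrix(state_costs, config, price)
    treat = run_cohort(config, schedule, utilities, costs, arm="treatment")
    ctrl = run_cohort(config, schedule, utilities, costs, arm="control")
    incr = {h: incremental_outcomes(treat, ctrl, h) for h in config.horizons}
    return PointResult(
        treatment=treat,
        control=ctrl,
        incrementals=incr,
        utilities=utilities,
        state_costs=state_costs,
        sat_estimates=sat_estimates,
        soc_estimates=soc_estimates,
    )
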