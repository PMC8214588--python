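"""Seven-state cohort Markov engine.

States: three severity states while on add-on nabiximols (SAT_*), the same
three severities on standard care alone (SOC_*), and absorbing DEATH.  The
treatment arm starts in the SAT block and leaks into the SOC block through
per-cycle discontinuation (same severity, no drug cost thereafter); the
control arm starts and stays in the SOC block.  Death is severity- and
arm-independent, so both arms share one per-cycle mortality schedule.

Cycles are 28 days, the default horizon is 65 cycles (five years at 13
cycles/year).  Costs discount at 3.0%/year and QALYs at 1.5%/year; the
discount exponent uses exact elapsed time from the start of cycle 1 (a
completed-year step variant is available via ``annual_steps``).  Accrual uses
start-of-cycle occupancy and no half-cycle correction: the cohort earns a
full cycle of cost and utility in the state it occupies when the cycle opens,
then transitions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .trial_data import SeverityState, UtilitySet

__all__ = [
    "ModelState",
    "ModelConfig",
    "TransitionSchedule",
    "ArmOutcome",
    "IncrementalResult",
    "discount_factor",
    "compose_full_matrix",
    "load_published_matrix",
    "run_cohort",
    "incremental_outcomes",
]

DAYS_PER_YEAR = 365.25


class ModelState(enum.IntEnum):
    SAT_MILD = 0
    SAT_MOD = 1
    SAT_SEV = 2
    SOC_MILD = 3
    SOC_MOD = 4
    SOC_SEV = 5
    DEATH = 6


#: severity index of each living state (DEATH has none)
SEVERITY_OF_STATE = (0, 1, 2, 0, 1, 2)
SAT_STATES = (ModelState.SAT_MILD, ModelState.SAT_MOD, ModelState.SAT_SEV)
SOC_STATES = (ModelState.SOC_MILD, ModelState.SOC_MOD, ModelState.SOC_SEV)


def _default_mortality() -> np.ndarray:
    # national life-table ramp: 0.020% at model start (age 51) rising to
    # 0.035% by the end of year 5 (age 56)
    return np.linspace(2.0e-4, 3.5e-4, 65)


def _default_discontinuation() -> np.ndarray:
    # no discontinuation during the titration cycle; trial-observed 3.8% for
    # cycles 2-4; long-term 3.5% from cycle 5 onward
    d = np.full(65, 0.035)
    d[0] = 0.0
    d[1:4] = 0.038
    return d


@dataclass
class ModelConfig:
    """Structural and economic settings of the cohort model."""

    n_cycles: int = 65
    cycle_days: float = 28.0
    discount_rate_costs: float = 0.03
    discount_rate_qalys: float = 0.015
    starting_age: float = 51.0
    cycles_per_year: int = 13
    days_per_year: float = DAYS_PER_YEAR
    annual_steps: bool = False
    mortality_per_cycle: np.ndarray = field(default_factory=_default_mortality)
    discontinuation_per_cycle: np.ndarray = field(
        default_factory=_default_discontinuation
    )
    #: cohort start split over (mild, moderate, severe); the trial enrolled
    #: moderate-to-severe patients only, hence zero initial mild mass
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.5, 0.5])
    )

    def __post_init__(self) -> None:
        self.mortality_per_cycle = np.asarray(self.mortality_per_cycle, dtype=float)
        self.discontinuation_per_cycle = np.asarray(
            self.discontinuation_per_cycle, dtype=float
        )
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        for name in ("mortality_per_cycle", "discontinuation_per_cycle"):
            arr = getattr(self, name)
            if arr.shape != (self.n_cycles,):
                raise ValueError(f"{name} must have length n_cycles={self.n_cycles}")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if self.initial_distribution.shape != (3,) or np.any(
            self.initial_distribution < 0
        ):
            raise ValueError("initial_distribution must be 3 non-negative weights")
        if abs(self.initial_distribution.sum() - 1.0) > 1e-12:
            raise ValueError("initial_distribution must sum to 1")
        if self.discount_rate_costs < 0 or self.discount_rate_qalys < 0:
            raise ValueError("discount rates must be non-negative")

    @property
    def horizons(self) -> tuple[int, ...]:
        """Whole-year horizons covered by the cycle grid (1..5 by default)."""
        return tuple(range(1, self.n_cycles // self.cycles_per_year + 1))

    def to_yaml(self, path) -> None:
        data = {
            "n_cycles": self.n_cycles,
            "cycle_days": self.cycle_days,
            "discount_rate_costs": self.discount_rate_costs,
            "discount_rate_qalys": self.discount_rate_qalys,
            "starting_age": self.starting_age,
            "cycles_per_year": self.cycles_per_year,
            "days_per_year": self.days_per_year,
            "annual_steps": self.annual_steps,
            "mortality_per_cycle": self.mortality_per_cycle.tolist(),
            "discontinuation_per_cycle": self.discontinuation_per_cycle.tolist(),
            "initial_distribution": self.initial_distribution.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def discount_factor(
    cycle: int,
    annual_rate: float,
    cycle_days: float = 28.0,
    days_per_year: float = DAYS_PER_YEAR,
    annual_steps: bool = False,
) -> float:
    """Discount factor applied to accruals of a given cycle.

    The first cycle is undiscounted; elapsed time is
    ``t = (cycle - 1) * cycle_days / days_per_year`` years, stepped down to
    completed years when ``annual_steps`` is set.
    """
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    if annual_rate < 0:
        raise ValueError("annual_rate must be non-negative")
    t = (cycle - 1) * cycle_days / days_per_year
    if annual_steps:
        t = math.floor(t)
    return float((1.0 + annual_rate) ** (-t))


def _check_row_stochastic(m: np.ndarray, label: str, atol: float = 1e-9) -> None:
    sums = m.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > atol)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"{label}: row {i} ({SeverityState(i).name}) sums to {sums[i]:.6f}, not 1"
        )
    if np.any(m < -atol) or np.any(m > 1 + atol):
        raise ValueError(f"{label}: entries outside [0, 1]")


def compose_full_matrix(
    sev_sat: np.ndarray,
    sev_soc: np.ndarray,
    discontinuation_p: float,
    death_p: float,
) -> np.ndarray:
    """Assemble one 7x7 model matrix from its severity/discontinuation parts.

    Competing risks are applied in order death, then discontinuation: a SAT
    row sends ``death_p`` to DEATH, ``(1 - death_p) * discontinuation_p`` to
    the SOC state of the same severity, and the remainder through the on-
    treatment severity matrix; SOC rows send ``death_p`` to DEATH and the
    rest through the standard-care severity matrix.
    """
    sev_sat = np.asarray(sev_sat, dtype=float)
    sev_soc = np.asarray(sev_soc, dtype=float)
    _check_row_stochastic(sev_sat, "on-treatment severity matrix")
    _check_row_stochastic(sev_soc, "standard-care severity matrix")
    if not 0.0 <= discontinuation_p <= 1.0:
        raise ValueError("discontinuation_p must lie in [0, 1]")
    if not 0.0 <= death_p <= 1.0:
        raise ValueError("death_p must lie in [0, 1]")
    alive = 1.0 - death_p
    full = np.zeros((7, 7))
    full[:3, :3] = alive * (1.0 - discontinuation_p) * sev_sat
    full[:3, 3:6] = alive * discontinuation_p * np.eye(3)
    full[3:6, 3:6] = alive * sev_soc
    full[:6, 6] = death_p
    full[6, 6] = 1.0
    return full


def load_published_matrix(
    published: np.ndarray, discontinuation_p: float, tol: float = 0.005
) -> np.ndarray:
    """Recover the conditional severity matrix behind a printed one.

    Published on-treatment matrices are printed with the discontinuation
    probability already multiplied in, so each printed row sums to
    ``1 - d`` (up to print rounding).  Dividing by ``1 - d`` and
    renormalising each row restores the matrix conditional on staying on
    treatment.
    """
    published = np.asarray(published, dtype=float)
    if published.shape != (3, 3):
        raise ValueError("published matrix must be 3x3")
    target = 1.0 - discontinuation_p
    sums = published.sum(axis=1)
    for i, s in enumerate(sums):
        if abs(s - target) > tol:
            raise ValueError(
                f"row {i} ({SeverityState(i).name}) sums to {s:.4f}; expected "
                f"{target:.4f} +/- {tol} for discontinuation {discontinuation_p}"
            )
    conditional = published / sums[:, None]
    return conditional


class TransitionSchedule:
    """Per-cycle 7x7 matrices for the full model horizon."""

    def __init__(self, matrices: np.ndarray) -> None:
        matrices = np.asarray(matrices, dtype=float)
        if matrices.ndim != 3 or matrices.shape[1:] != (7, 7):
            raise ValueError("schedule must be (n_cycles, 7, 7)")
        sums = matrices.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("every schedule row must sum to 1")
        if np.any(matrices < -1e-12) or np.any(matrices > 1 + 1e-12):
            raise ValueError("schedule entries outside [0, 1]")
        death = matrices[:, 6, :]
        if np.any(np.abs(death - np.eye(7)[6]) > 1e-12):
            raise ValueError("DEATH must be absorbing in every cycle")
        if np.any(matrices[:, 3:6, :3] > 1e-12):
            raise ValueError("standard-care states may not re-initiate treatment")
        self.matrices = matrices

    def __len__(self) -> int:
        return self.matrices.shape[0]

    def __getitem__(self, cycle: int) -> np.ndarray:
        """Matrix applied at the end of 1-based ``cycle``."""
        if not 1 <= cycle <= len(self):
            raise IndexError(f"cycle {cycle} outside 1..{len(self)}")
        return self.matrices[cycle - 1]

    @classmethod
    def from_severity(
        cls,
        sat_by_cycle: Sequence[np.ndarray],
        soc_by_cycle: Sequence[np.ndarray],
        config: ModelConfig,
    ) -> "TransitionSchedule":
        if len(sat_by_cycle) != config.n_cycles or len(soc_by_cycle) != config.n_cycles:
            raise ValueError("severity matrix lists must cover every cycle")
        mats = np.empty((config.n_cycles, 7, 7))
        for c in range(config.n_cycles):
            mats[c] = compose_full_matrix(
                sat_by_cycle[c],
                soc_by_cycle[c],
                config.discontinuation_per_cycle[c],
                config.mortality_per_cycle[c],
            )
        return cls(mats)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(len(self)):
            for i in ModelState:
                for j in ModelState:
                    rows.append(
                        {
                            "cycle": c + 1,
                            "from_state": i.name,
                            "to_state": j.name,
                            "probability": self.matrices[c, int(i), int(j)],
                        }
                    )
        return pd.DataFrame(rows, columns=["cycle", "from_state", "to_state", "probability"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TransitionSchedule":
        df = pd.read_csv(path)
        n_cycles = int(df["cycle"].max())
        mats = np.zeros((n_cycles, 7, 7))
        idx = {s.name: int(s) for s in ModelState}
        for row in df.itertuples(index=False):
            mats[int(row.cycle) - 1, idx[row.from_state], idx[row.to_state]] = (
                row.probability
            )
        return cls(mats)


@dataclass
class ArmOutcome:
    """Cohort trace plus discounted totals of one model arm."""

    trace: np.ndarray  # (n_cycles + 1, 7); row 0 is the initial distribution
    discounted_costs: np.ndarray  # per-cycle discounted EUR
    discounted_qalys: np.ndarray  # per-cycle discounted QALYs
    cycles_per_year: int = 13

    @property
    def discounted_costs_by_horizon(self) -> dict[int, float]:
        return {h: self.costs_at(h) for h in self._horizons()}

    @property
    def discounted_qalys_by_horizon(self) -> dict[int, float]:
        return {h: self.qalys_at(h) for h in self._horizons()}

    def _horizons(self) -> range:
        return range(1, len(self.discounted_costs) // self.cycles_per_year + 1)

    def costs_at(self, horizon_years: int) -> float:
        return float(self.discounted_costs[: horizon_years * self.cycles_per_year].sum())

    def qalys_at(self, horizon_years: int) -> float:
        return float(self.discounted_qalys[: horizon_years * self.cycles_per_year].sum())


@dataclass(frozen=True)
class IncrementalResult:
    """Treatment-minus-control contrast at one horizon."""

    horizon: int
    delta_costs: float
    delta_qalys: float
    icer: float | None
    dominant: bool


def run_cohort(
    config: ModelConfig,
    schedule: TransitionSchedule,
    utilities: UtilitySet,
    cost_per_state_cycle: np.ndarray,
    arm: str = "treatment",
) -> ArmOutcome:
    """Propagate the cohort and accrue discounted costs and QALYs.

    ``cost_per_state_cycle`` is an ``(n_cycles, 7)`` EUR matrix.  The cohort
    starts in the SAT block (``arm='treatment'``) or the SOC block
    (``arm='control'``), split over severities by
    ``config.initial_distribution``.  Each cycle accrues
    ``occupancy . utility x cycle_days/days_per_year`` QALYs and
    ``occupancy . cost`` EUR at start-of-cycle occupancy, discounted at the
    respective annual rate, before the end-of-cycle transition.
    """
    if len(schedule) != config.n_cycles:
        raise ValueError(
            f"schedule covers {len(schedule)} cycles but config expects {config.n_cycles}"
        )
    cost_per_state_cycle = np.asarray(cost_per_state_cycle, dtype=float)
    if cost_per_state_cycle.shape != (config.n_cycles, 7):
        raise ValueError("cost_per_state_cycle must be (n_cycles, 7)")
    u = utilities.as_array()
    u7 = np.array([u[0], u[1], u[2], u[0], u[1], u[2], 0.0])
    s = np.zeros(7)
    if arm == "treatment":
        s[:3] = config.initial_distribution
    elif arm == "control":
        s[3:6] = config.initial_distribution
    else:
        raise ValueError("arm must be 'treatment' or 'control'")

    year_frac = config.cycle_days / config.days_per_year
    n = config.n_cycles
    trace = np.empty((n + 1, 7))
    trace[0] = s
    costs = np.empty(n)
    qalys = np.empty(n)
    for c in range(1, n + 1):
        occ = trace[c - 1]
        df_c = discount_factor(
            c, config.discount_rate_costs, config.cycle_days,
            config.days_per_year, config.annual_steps,
        )
        df_q = discount_factor(
            c, config.discount_rate_qalys, config.cycle_days,
            config.days_per_year, config.annual_steps,
        )
        costs[c - 1] = occ @ cost_per_state_cycle[c - 1] * df_c
        qalys[c - 1] = occ @ u7 * year_frac * df_q
        trace[c] = occ @ schedule[c]
    return ArmOutcome(trace, costs, qalys, config.cycles_per_year)


def incremental_outcomes(
    arm_treatment: ArmOutcome, arm_control: ArmOutcome, horizon: int
) -> IncrementalResult:
    """Incremental costs, QALYs, ICER and dominance at a whole-year horizon."""
    for arm, label in ((arm_treatment, "treatment"), (arm_control, "control")):
        if horizon not in arm._horizons():
            raise ValueError(f"{label} outcome does not cover horizon {horizon}")
    dc = arm_treatment.costs_at(horizon) - arm_control.costs_at(horizon)
    dq = arm_treatment.qalys_at(horizon) - arm_control.qalys_at(horizon)
    icer = dc / dq if dq != 0.0 else None
    return IncrementalResult(
        horizon=horizon,
        delta_costs=dc,
        delta_qalys=dq,
        icer=icer,
        dominant=(dc < 0.0 and dq > 0.0),
    )
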