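"""Probabilistic sensitivity analysis engines.

The primary engine replaces the conventional parametric Monte Carlo PSA with
a *stratified bootstrap of the source data*: each replicate redraws, with
replacement and at original size, (1) the patients of each trial stratum -
the two double-blind arms and the single-blind-only remainder - and (2) the
Delphi panel experts; re-estimates every model parameter (transition
matrices, state utilities, state costs) from the redrawn data jointly; and
re-runs the cohort model.  Because all parameters of a replicate come from
the *same* resampled patients, any correlation structure in the trial data -
e.g. patients who improve faster also reporting higher utilities - is
propagated into the joint distribution of incremental costs and QALYs,
without distributional assumptions.

A conventional Monte Carlo engine is provided as a comparator: it samples
each parameter independently from standard parametric choices (Dirichlet
rows for transition matrices with concentration ``n x p``, normal state
utilities, gamma state costs) and therefore carries no cross-parameter
correlation.

Replicate streams are spawned from a single root seed, so results are
reproducible bit-for-bit and invariant to evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .costing import DelphiPanelData, DrugPrice, StateCostSet, UnitCostTable
from .markov import IncrementalResult, ModelConfig
from .pipeline import (
    SCENARIOS,
    PointResult,
    ScenarioSpec,
    _run_from_parameters,
    estimate_sativex_matrices,
    estimate_soc_matrices,
    evaluate_point,
)
from .trial_data import (
    SeverityState,
    Stratum,
    TransitionEstimate,
    TrialDataset,
    UtilitySet,
    estimate_utilities,
)

__all__ = [
    "BootstrapConfig",
    "Replicate",
    "PSASummary",
    "DispersionSpec",
    "draw_bootstrap_replicate",
    "identity_resample",
    "run_bootstrap_psa",
    "run_monte_carlo_psa",
    "summarize_psa",
    "summarize_all_horizons",
    "replicates_to_frame",
    "ceac",
]


@dataclass
class BootstrapConfig:
    """Settings of a bootstrap PSA run."""

    n_replicates: int = 1000
    seed: int = 0
    scenario: str = "base"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class Replicate:
    """Per-horizon totals of both arms for one PSA replicate."""

    replicate_id: int
    horizons: tuple[int, ...]
    costs_treatment: np.ndarray
    qalys_treatment: np.ndarray
    costs_control: np.ndarray
    qalys_control: np.ndarray

    @property
    def delta_costs(self) -> np.ndarray:
        return self.costs_treatment - self.costs_control

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.qalys_treatment - self.qalys_control

    def incremental(self, horizon: int) -> IncrementalResult:
        i = self.horizons.index(horizon)
        dc = float(self.delta_costs[i])
        dq = float(self.delta_qalys[i])
        return IncrementalResult(
            horizon=horizon,
            delta_costs=dc,
            delta_qalys=dq,
            icer=dc / dq if dq != 0.0 else None,
            dominant=(dc < 0.0 and dq > 0.0),
        )


@dataclass
class PSASummary:
    """Distributional summary of one horizon's replicates.

    Quadrants follow the cost-effectiveness plane with incremental QALYs on
    the abscissa and incremental costs on the ordinate; the south-east
    quadrant (more effective, cheaper) is dominance.  Intervals are
    empirical 2.5/97.5 percentiles; the ICER interval is the percentile
    interval of the per-replicate ratio, reported alongside quadrant counts
    because ratio percentiles mix signs across quadrants.
    """

    horizon: int
    n: int
    dominance_probability: float
    prob_qaly_gain: float
    quadrant_counts: dict[str, int]
    ci_delta_costs: tuple[float, float]
    ci_delta_qalys: tuple[float, float]
    ci_icer: tuple[float, float]
    n_icer_defined: int
    delta_costs: np.ndarray = field(repr=False)
    delta_qalys: np.ndarray = field(repr=False)

    def ce_plane_points(self) -> np.ndarray:
        """(n, 2) array of (delta QALYs, delta costs) pairs."""
        return np.column_stack([self.delta_qalys, self.delta_costs])


def draw_bootstrap_replicate(
    trial: TrialDataset, panel: DelphiPanelData, rng: np.random.Generator
) -> tuple[TrialDataset, DelphiPanelData]:
    """One stratified with-replacement redraw of patients and experts.

    Each stratum is resampled separately at its original size, so every
    replicate preserves the trial's 53/53/remainder structure exactly; the
    expert panel is resampled at its original size of eight.
    """
    rows = np.empty(trial.n_patients, dtype=np.intp)
    pos = 0
    for s in Stratum:
        idx = np.flatnonzero(trial.stratum == int(s))
        if idx.size == 0:
            raise ValueError(f"stratum {s.name} is empty; cannot bootstrap")
        rows[pos : pos + idx.size] = rng.choice(idx, size=idx.size, replace=True)
        pos += idx.size
    experts = rng.integers(0, panel.n_experts, size=panel.n_experts)
    return trial.subset(rows), panel.resample(experts)


def identity_resample(
    trial: TrialDataset, panel: DelphiPanelData, rng: np.random.Generator
) -> tuple[TrialDataset, DelphiPanelData]:
    """Test hook: a 'resample' that returns the original data unchanged."""
    return trial, panel


def run_bootstrap_psa(
    trial: TrialDataset,
    panel: DelphiPanelData,
    tariffs: UnitCostTable,
    model_config: ModelConfig,
    psa_config: BootstrapConfig,
    soc_matrix: np.ndarray | None = None,
    price: DrugPrice | None = None,
    resample: Callable = draw_bootstrap_replicate,
) -> tuple[list[Replicate], dict[int, PSASummary]]:
    """Stratified-bootstrap PSA.

    Per replicate: redraw patients and experts, re-estimate transition
    matrices and utilities from the combined redrawn strata, re-cost the
    states from the redrawn panel, rebuild the scenario's schedules and run
    both arms.  Rare replicates can miss a severity state entirely; those
    fall back to identity transition rows and to the original point
    utilities, so every replicate yields a usable model run.
    """
    scenario = SCENARIOS[psa_config.scenario]
    point_utilities = estimate_utilities(trial)
    streams = np.random.SeedSequence(psa_config.seed).spawn(psa_config.n_replicates)
    horizons = model_config.horizons
    replicates: list[Replicate] = []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        b_trial, b_panel = resample(trial, panel, rng)
        result = evaluate_point(
            b_trial,
            b_panel,
            tariffs,
            model_config,
            scenario,
            soc_matrix=soc_matrix,
            price=price,
            fallback_utilities=point_utilities,
            warn=False,
        )
        replicates.append(_replicate_from_result(r, horizons, result))
    return replicates, summarize_all_horizons(replicates, horizons)


def _replicate_from_result(
    replicate_id: int, horizons: tuple[int, ...], result: PointResult
) -> Replicate:
    return Replicate(
        replicate_id=replicate_id,
        horizons=tuple(horizons),
        costs_treatment=np.array([result.treatment.costs_at(h) for h in horizons]),
        qalys_treatment=np.array([result.treatment.qalys_at(h) for h in horizons]),
        costs_control=np.array([result.control.costs_at(h) for h in horizons]),
        qalys_control=np.array([result.control.qalys_at(h) for h in horizons]),
    )


# ---------------------------------------------------------------------------
# Monte Carlo comparator
# ---------------------------------------------------------------------------


@dataclass
class DispersionSpec:
    """Independent parametric distributions for the Monte Carlo comparator.

    Transition rows are Dirichlet with concentration ``row count x point
    probability`` (zero-probability cells stay structural zeros); state
    utilities are independent normals around the pooled means with a
    patient-clustered standard error; state costs are gammas matching the
    mean and standard error of the panel-mean cost.
    """

    sat_alphas: list[np.ndarray]
    sat_points: list[TransitionEstimate]
    utility_mean: np.ndarray
    utility_se: np.ndarray
    cost_mean: np.ndarray
    cost_se: np.ndarray
    soc_alphas: list[np.ndarray] | None = None
    soc_points: list[TransitionEstimate] | None = None

    @classmethod
    def from_data(
        cls,
        trial: TrialDataset,
        panel: DelphiPanelData,
        tariffs: UnitCostTable,
        scenario: str = "base",
    ) -> "DispersionSpec":
        sat = estimate_sativex_matrices(trial, warn=False)
        soc = (
            estimate_soc_matrices(trial, warn=False)
            if SCENARIOS[scenario].soc_source == "trial"
            else None
        )
        u_mean, u_se = _clustered_utility_moments(trial)
        tariff = tariffs.tariff_vector(panel.items)
        expert_costs = panel.quantities @ tariff  # (E, 3)
        c_mean = expert_costs.mean(axis=0)
        c_se = expert_costs.std(axis=0, ddof=1) / np.sqrt(panel.n_experts)
        return cls(
            sat_alphas=[e.row_counts[:, None] * e.matrix for e in sat],
            sat_points=sat,
            utility_mean=u_mean,
            utility_se=u_se,
            cost_mean=c_mean,
            cost_se=c_se,
            soc_alphas=None if soc is None else [e.row_counts[:, None] * e.matrix for e in soc],
            soc_points=soc,
        )


def _clustered_utility_moments(trial: TrialDataset) -> tuple[np.ndarray, np.ndarray]:
    """Pooled state-utility means with patient-clustered standard errors.

    Utility observations of one patient share a random level, so the naive
    independent-observation standard error would understate the sampling
    variance; the linearised ratio-estimator variance over patients is used
    instead.
    """
    from .trial_data import classify_nrs_array

    states = classify_nrs_array(trial.nrs)
    has_u = ~np.isnan(trial.utility)
    mean = np.empty(3)
    se = np.empty(3)
    for s in range(3):
        mask = has_u & (states == s)
        n_p = mask.sum(axis=1).astype(float)
        t_p = np.where(mask, trial.utility, 0.0).sum(axis=1)
        n_tot = n_p.sum()
        if n_tot == 0:
            raise ValueError(f"no utility observations for state {SeverityState(s).name}")
        mean[s] = t_p.sum() / n_tot
        resid = t_p - mean[s] * n_p
        se[s] = np.sqrt((resid**2).sum()) / n_tot
    return mean, se


def _sample_matrix(
    alphas: np.ndarray, point: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = point.copy()
    for i in range(3):
        a = alphas[i]
        pos = a > 0
        if pos.sum() > 1:
            row = np.zeros(3)
            row[pos] = rng.dirichlet(a[pos])
            out[i] = row
    return out


def _sample_gamma(mean: float, se: float, rng: np.random.Generator) -> float:
    if se <= 0 or mean <= 0:
        return mean
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return float(rng.gamma(shape, scale))


def run_monte_carlo_psa(
    point_estimates: PointResult,
    dispersion_spec: DispersionSpec,
    model_config: ModelConfig,
    n_replicates: int,
    seed: int,
    scenario: str = "base",
    soc_matrix: np.ndarray | None = None,
    price: DrugPrice | None = None,
) -> tuple[list[Replicate], dict[int, PSASummary]]:
    """Independent-parameter Monte Carlo PSA (the conventional comparator).

    Each replicate draws every parameter from its own distribution with no
    cross-parameter dependence, then runs the model; summaries are identical
    in form to the bootstrap engine's.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    spec = dispersion_spec
    scen = SCENARIOS[scenario]
    if scen.soc_source == "trial" and spec.soc_points is None:
        raise ValueError("scenario s1 requires placebo-stratum dispersions")
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    horizons = model_config.horizons
    replicates: list[Replicate] = []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sat_draw = [
            TransitionEstimate(
                cycle=e.cycle,
                matrix=_sample_matrix(a, e.matrix, rng),
                n_at_risk=e.n_at_risk,
                row_counts=e.row_counts,
                identity_rows=e.identity_rows,
            )
            for e, a in zip(spec.sat_points, spec.sat_alphas)
        ]
        soc_draw = None
        if scen.soc_source == "trial":
            soc_draw = [
                TransitionEstimate(
                    cycle=e.cycle,
                    matrix=_sample_matrix(a, e.matrix, rng),
                    n_at_risk=e.n_at_risk,
                    row_counts=e.row_counts,
                    identity_rows=e.identity_rows,
                )
                for e, a in zip(spec.soc_points, spec.soc_alphas)
            ]
        u = np.clip(
            spec.utility_mean + spec.utility_se * rng.standard_normal(3), -1.0, 1.0
        )
        utilities = UtilitySet(*u.tolist())
        costs = StateCostSet(
            *(
                _sample_gamma(m, s, rng)
                for m, s in zip(spec.cost_mean, spec.cost_se)
            )
        )
        result = _run_from_parameters(
            scen, sat_draw, soc_draw, utilities, costs, model_config, soc_matrix, price
        )
        replicates.append(_replicate_from_result(r, horizons, result))
    return replicates, summarize_all_horizons(replicates, horizons)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_psa(replicates: Sequence[Replicate], horizon: int) -> PSASummary:
    """Dominance probability, quadrant counts and percentile intervals."""
    if not replicates:
        raise ValueError("cannot summarize an empty replicate list")
    i = replicates[0].horizons.index(horizon)
    dc = np.array([r.delta_costs[i] for r in replicates])
    dq = np.array([r.delta_qalys[i] for r in replicates])
    n = len(replicates)
    gain = dq > 0
    saving = dc < 0
    quadrants = {
        "NE": int(np.sum(gain & ~saving)),
        "SE": int(np.sum(gain & saving)),
        "SW": int(np.sum(~gain & saving)),
        "NW": int(np.sum(~gain & ~saving)),
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        icer = np.where(dq != 0, dc / dq, np.nan)
    finite = icer[np.isfinite(icer)]
    ci_icer = (
        tuple(np.percentile(finite, [2.5, 97.5]).tolist())
        if finite.size
        else (float("nan"), float("nan"))
    )
    return PSASummary(
        horizon=horizon,
        n=n,
        dominance_probability=quadrants["SE"] / n,
        prob_qaly_gain=float(np.mean(gain)),
        quadrant_counts=quadrants,
        ci_delta_costs=tuple(np.percentile(dc, [2.5, 97.5]).tolist()),
        ci_delta_qalys=tuple(np.percentile(dq, [2.5, 97.5]).tolist()),
        ci_icer=ci_icer,
        n_icer_defined=int(finite.size),
        delta_costs=dc,
        delta_qalys=dq,
    )


def summarize_all_horizons(
    replicates: Sequence[Replicate], horizons: Sequence[int]
) -> dict[int, PSASummary]:
    return {h: summarize_psa(replicates, h) for h in horizons}


def replicates_to_frame(replicates: Sequence[Replicate]) -> pd.DataFrame:
    """Long-format serialisation: one row per replicate x horizon x arm."""
    rows = []
    for r in replicates:
        for i, h in enumerate(r.horizons):
            inc = r.incremental(h)
            for arm, c, q in (
                ("treatment", r.costs_treatment[i], r.qalys_treatment[i]),
                ("control", r.costs_control[i], r.qalys_control[i]),
            ):
                rows.append(
                    {
                        "replicate_id": r.replicate_id,
                        "horizon": h,
                        "arm": arm,
                        "costs": c,
                        "qalys": q,
                        "delta_costs": inc.delta_costs,
                        "delta_qalys": inc.delta_qalys,
                        "icer": inc.icer,
                        "dominant": inc.dominant,
                    }
                )
    return pd.DataFrame(rows)


def ceac(
    replicates: Sequence[Replicate], horizon: int, thresholds: np.ndarray
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve (plotting convenience).

    For each willingness-to-pay threshold, the fraction of replicates with
    non-negative incremental net monetary benefit.
    """
    i = replicates[0].horizons.index(horizon)
    dc = np.array([r.delta_costs[i] for r in replicates])
    dq = np.array([r.delta_qalys[i] for r in replicates])
    thresholds = np.asarray(thresholds, dtype=float)
    prob = [(float(np.mean(t * dq - dc >= 0))) for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "probability_cost_effective": prob})
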