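"""Scenario runner and results tables.

Wires data, estimators, costing, the cohort engine and the PSA engines into
the three published analysis scenarios:

* ``base`` - on-treatment matrices from the trial for cycles 1-5 and carried
  forward thereafter; standard-care matrices from an external long-term
  observational source.
* ``s1``   - as base, but the standard-care matrices are estimated from the
  trial's placebo stratum (and re-estimated inside every bootstrap
  replicate).
* ``s2``   - conservative: no treatment benefit beyond the trial window; the
  on-treatment arm follows standard-care dynamics from cycle 6 while still
  paying for the drug.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .costing import DelphiPanelData, DrugPrice, UnitCostTable
from .markov import IncrementalResult, ModelConfig
from .pipeline import SCENARIOS, PointResult, ScenarioSpec, evaluate_point
from .psa import (
    BootstrapConfig,
    DispersionSpec,
    PSASummary,
    Replicate,
    replicates_to_frame,
    run_bootstrap_psa,
    run_monte_carlo_psa,
)
from .trial_data import TrialDataset

__all__ = [
    "ScenarioResult",
    "run_scenario",
    "write_results_table",
    "read_soc_matrix",
    "write_soc_matrix",
]

_SEVERITY_NAMES = ("MILD", "MODERATE", "SEVERE")


def read_soc_matrix(path) -> np.ndarray:
    """Read a 3x3 standard-care severity matrix from long-format CSV."""
    df = pd.read_csv(path)
    m = np.full((3, 3), np.nan)
    idx = {n: i for i, n in enumerate(_SEVERITY_NAMES)}
    for row in df.itertuples(index=False):
        m[idx[row.from_state], idx[row.to_state]] = row.probability
    if np.any(np.isnan(m)):
        raise ValueError(f"standard-care matrix in {path} is incomplete")
    return m


def write_soc_matrix(matrix: np.ndarray, path) -> None:
    rows = [
        {"from_state": _SEVERITY_NAMES[i], "to_state": _SEVERITY_NAMES[j],
         "probability": float(matrix[i, j])}
        for i in range(3)
        for j in range(3)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class ScenarioResult:
    """Everything one scenario run produced."""

    scenario: str
    mode: str
    point: PointResult
    replicates: list[Replicate] | None = None
    summaries: dict[int, PSASummary] | None = None


def run_scenario(
    scenario: ScenarioSpec | str,
    trial: TrialDataset,
    panel: DelphiPanelData,
    tariffs: UnitCostTable,
    model_config: ModelConfig | None = None,
    mode: str = "point",
    n_replicates: int = 1000,
    seed: int = 0,
    soc_matrix: np.ndarray | None = None,
    price: DrugPrice | None = None,
) -> ScenarioResult:
    """Run one scenario in point, bootstrap or Monte Carlo mode."""
    if isinstance(scenario, str):
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        scenario = SCENARIOS[scenario]
    model_config = model_config or ModelConfig()
    if scenario.soc_source == "external" and soc_matrix is None:
        raise ValueError(
            f"scenario {scenario.scenario_id!r} requires an external "
            "standard-care matrix; none was provided"
        )
    point = evaluate_point(
        trial, panel, tariffs, model_config, scenario,
        soc_matrix=soc_matrix, price=price, warn=False,
    )
    if mode == "point":
        return ScenarioResult(scenario.scenario_id, mode, point)
    if mode == "bootstrap":
        reps, summaries = run_bootstrap_psa(
            trial,
            panel,
            tariffs,
            model_config,
            BootstrapConfig(n_replicates, seed, scenario.scenario_id),
            soc_matrix=soc_matrix,
            price=price,
        )
    elif mode == "mc":
        spec = DispersionSpec.from_data(trial, panel, tariffs, scenario.scenario_id)
        reps, summaries = run_monte_carlo_psa(
            point, spec, model_config, n_replicates, seed,
            scenario=scenario.scenario_id, soc_matrix=soc_matrix, price=price,
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ScenarioResult(scenario.scenario_id, mode, point, reps, summaries)


def _fmt(x: float | None) -> float | None:
    return None if x is None else float(x)


def results_table(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """One row per (scenario, horizon): point contrasts plus PSA intervals."""
    rows = []
    for res in results:
        horizons = sorted(res.point.incrementals)
        missing = []
        for h in horizons:
            inc = res.point.incrementals[h]
            summ = res.summaries.get(h) if res.summaries else None
            rows.append(
                {
                    "scenario": res.scenario,
                    "horizon_years": h,
                    "delta_costs": inc.delta_costs,
                    "delta_costs_lo": summ.ci_delta_costs[0] if summ else None,
                    "delta_costs_hi": summ.ci_delta_costs[1] if summ else None,
                    "delta_qalys": inc.delta_qalys,
                    "delta_qalys_lo": summ.ci_delta_qalys[0] if summ else None,
                    "delta_qalys_hi": summ.ci_delta_qalys[1] if summ else None,
                    "icer": _fmt(inc.icer),
                    "icer_lo": summ.ci_icer[0] if summ else None,
                    "icer_hi": summ.ci_icer[1] if summ else None,
                    "dominant": inc.dominant,
                    "dominance_pct": 100.0 * summ.dominance_probability if summ else None,
                }
            )
    return pd.DataFrame(rows)


def write_results_table(results: Sequence[ScenarioResult], out_dir) -> Path:
    """Write the results table plus CE-plane point clouds; returns the table path.

    Raises if any scenario is missing a horizon so partial runs cannot be
    mistaken for complete ones.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for res in results:
        expected = set(range(1, max(res.point.incrementals) + 1))
        have = set(res.point.incrementals)
        if expected - have:
            raise ValueError(
                f"scenario {res.scenario}: missing horizons {sorted(expected - have)}"
            )
    table = results_table(results)
    table_path = out_dir / "results_table.csv"
    # 17 significant digits so every float round-trips bit-exactly
    table.to_csv(table_path, index=False, float_format="%.17g")
    for res in results:
        if res.summaries:
            for h, summ in res.summaries.items():
                pts = summ.ce_plane_points()
                pd.DataFrame(
                    {"delta_qalys": pts[:, 0], "delta_costs": pts[:, 1]}
                ).to_csv(out_dir / f"ce_plane_{res.scenario}_{h}y.csv", index=False)
        if res.replicates:
            replicates_to_frame(res.replicates).to_csv(
                out_dir / f"replicates_{res.scenario}.csv", index=False
            )
    return table_path


def plot_ce_plane(summary: PSASummary, path, title: str | None = None) -> None:
    """Scatter the replicate cloud on the cost-effectiveness plane.

    Requires matplotlib (the ``plot`` extra); the CSV emitted by
    :func:`write_results_table` carries the same points for external tools.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = summary.ce_plane_points()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(pts[:, 0], pts[:, 1], s=6, alpha=0.4)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("incremental QALYs per patient")
    ax.set_ylabel("incremental costs per patient (EUR)")
    ax.set_title(title or f"{summary.horizon}-year horizon")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_manifest(seed: int, config: ModelConfig, extra: Mapping | None = None) -> dict:
    """Reproducibility record: seed, config hash, package version."""
    from . import __version__

    cfg = {
        "n_cycles": config.n_cycles,
        "cycle_days": config.cycle_days,
        "discount_rate_costs": config.discount_rate_costs,
        "discount_rate_qalys": config.discount_rate_qalys,
        "initial_distribution": config.initial_distribution.tolist(),
        "mortality_per_cycle": config.mortality_per_cycle.tolist(),
        "discontinuation_per_cycle": config.discontinuation_per_cycle.tolist(),
        "annual_steps": config.annual_steps,
    }
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    manifest = {"seed": seed, "config_sha256": digest, "version": __version__}
    if extra:
        manifest.update(extra)
    return manifest
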