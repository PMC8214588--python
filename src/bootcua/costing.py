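"""Drug and standard-care costing.

Drug cost follows the observed dose curve: 6.9 sprays/day in the titration
cycle, 7.7 for cycles 2-5, then a linear taper from 7.3 (cycle 6) to the
long-term 6.2 sprays/day at cycle 14, held thereafter.  Sprays are priced
continuously off the pack list price by default (no wastage rule); a
whole-pack rounding mode exists for sensitivity exploration.

Standard-care cost per severity state is micro-costed from a Delphi panel:
eight experts each state per-cycle resource quantities per severity state;
the panel mean quantity of each item is multiplied by its tariff.  Unit
costs are point values (their uncertainty is not propagated); the expert
quantities are what the bootstrap resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd

from . import published
from .markov import ModelConfig, ModelState
from .trial_data import SeverityState

__all__ = [
    "DrugPrice",
    "DelphiPanelData",
    "UnitCostTable",
    "StateCostSet",
    "sativex_dose_for_cycle",
    "sativex_cost_per_cycle",
    "state_cost_per_cycle",
    "cost_matrix",
]

_DOSE_CYCLE_1 = 6.9
_DOSE_CYCLES_2_5 = 7.7
_DOSE_CYCLE_6 = 7.3
_DOSE_LONG_TERM = 6.2


def sativex_dose_for_cycle(cycle: int, n_cycles: int = 65) -> float:
    """Mean sprays/day for a model cycle."""
    if not 1 <= cycle <= n_cycles:
        raise ValueError(f"cycle must lie in 1..{n_cycles}, got {cycle}")
    if cycle == 1:
        return _DOSE_CYCLE_1
    if cycle <= 5:
        return _DOSE_CYCLES_2_5
    if cycle <= 14:
        return _DOSE_CYCLE_6 - (_DOSE_CYCLE_6 - _DOSE_LONG_TERM) * (cycle - 6) / 8.0
    return _DOSE_LONG_TERM


@dataclass(frozen=True)
class DrugPrice:
    pack_price: float = published.PACK_PRICE_EUR
    vials_per_pack: int = published.VIALS_PER_PACK
    sprays_per_vial: int = published.SPRAYS_PER_VIAL

    @property
    def sprays_per_pack(self) -> int:
        return self.vials_per_pack * self.sprays_per_vial

    @property
    def price_per_spray(self) -> float:
        return self.pack_price / self.sprays_per_pack


def sativex_cost_per_cycle(
    cycle: int,
    price: DrugPrice | None = None,
    cycle_days: float = 28.0,
    whole_packs: bool = False,
    n_cycles: int = 65,
) -> float:
    """Drug cost (EUR) of one cycle on treatment.

    Continuous per-spray pricing by default; with ``whole_packs`` the cycle's
    spray count is rounded up to full packs.
    """
    price = price or DrugPrice()
    sprays = sativex_dose_for_cycle(cycle, n_cycles) * cycle_days
    if whole_packs:
        return math.ceil(sprays / price.sprays_per_pack) * price.pack_price
    return sprays * price.price_per_spray


class UnitCostTable:
    """EUR tariff per resource item."""

    def __init__(self, costs: Mapping[str, float]) -> None:
        self.costs = dict(costs)
        for item, c in self.costs.items():
            if c < 0:
                raise ValueError(f"negative unit cost for {item!r}")

    def __getitem__(self, item: str) -> float:
        return self.costs[item]

    def __contains__(self, item: str) -> bool:
        return item in self.costs

    def tariff_vector(self, items: Sequence[str]) -> np.ndarray:
        missing = [i for i in items if i not in self.costs]
        if missing:
            raise KeyError(f"no unit cost for item(s): {missing}")
        return np.array([self.costs[i] for i in items], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item": list(self.costs), "unit_cost_eur": list(self.costs.values())}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "UnitCostTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df["item"], df["unit_cost_eur"])))


class DelphiPanelData:
    """Per-expert resource quantities per severity state.

    ``quantities[e, s, i]`` is expert ``e``'s per-cycle quantity of item ``i``
    for severity state ``s``.  All experts cover the identical item set; the
    elicitation had no missing values.
    """

    def __init__(
        self,
        expert_ids: Sequence[str],
        items: Sequence[str],
        quantities: np.ndarray,
    ) -> None:
        self.expert_ids = list(expert_ids)
        self.items = list(items)
        self.quantities = np.asarray(quantities, dtype=float)
        if self.quantities.shape != (len(self.expert_ids), 3, len(self.items)):
            raise ValueError("quantities must be (n_experts, 3, n_items)")
        if np.any(np.isnan(self.quantities)):
            raise ValueError("panel data may not contain missing values")
        if np.any(self.quantities < 0):
            raise ValueError("resource quantities must be non-negative")

    @property
    def n_experts(self) -> int:
        return len(self.expert_ids)

    def resample(self, rows: np.ndarray) -> "DelphiPanelData":
        return DelphiPanelData(
            [self.expert_ids[r] for r in rows], self.items, self.quantities[rows]
        )

    def mean_quantities(self) -> np.ndarray:
        """Panel-mean quantity per (state, item)."""
        return self.quantities.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e, eid in enumerate(self.expert_ids):
            for s in SeverityState:
                for i, item in enumerate(self.items):
                    rows.append(
                        {
                            "expert_id": eid,
                            "severity": s.name,
                            "item": item,
                            "quantity_per_cycle": self.quantities[e, int(s), i],
                        }
                    )
        return pd.DataFrame(rows, columns=["expert_id", "severity", "item", "quantity_per_cycle"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "DelphiPanelData":
        df = pd.read_csv(path, dtype={"expert_id": str})
        experts = list(dict.fromkeys(df["expert_id"]))
        items = list(dict.fromkeys(df["item"]))
        q = np.full((len(experts), 3, len(items)), np.nan)
        e_idx = {e: i for i, e in enumerate(experts)}
        i_idx = {it: i for i, it in enumerate(items)}
        for row in df.itertuples(index=False):
            q[e_idx[row.expert_id], int(SeverityState[row.severity]), i_idx[row.item]] = (
                row.quantity_per_cycle
            )
        return cls(experts, items, q)


@dataclass(frozen=True)
class StateCostSet:
    """Standard-care cost (EUR) per 28-day cycle for each severity state."""

    mild: float
    moderate: float
    severe: float

    def __post_init__(self) -> None:
        if min(self.mild, self.moderate, self.severe) < 0:
            raise ValueError("state costs must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.mild, self.moderate, self.severe], dtype=float)


def state_cost_per_cycle(
    panel: DelphiPanelData, tariffs: UnitCostTable
) -> StateCostSet:
    """Mean-then-price micro-costing of standard care.

    For each severity state, the panel-mean quantity of every item is priced
    at its tariff and summed.  Identical for both model arms.
    """
    if panel.n_experts == 0:
        raise ValueError("empty Delphi panel")
    tariff = tariffs.tariff_vector(panel.items)
    costs = panel.mean_quantities() @ tariff
    return StateCostSet(*costs.tolist())


def cost_matrix(
    state_costs: StateCostSet,
    config: ModelConfig,
    price: DrugPrice | None = None,
    whole_packs: bool = False,
) -> np.ndarray:
    """Per-cycle EUR cost of each model state, shape ``(n_cycles, 7)``.

    On-treatment states pay drug plus care for their severity, standard-care
    states pay care only, death accrues nothing.
    """
    care = state_costs.as_array()
    out = np.zeros((config.n_cycles, 7))
    for c in range(1, config.n_cycles + 1):
        drug = sativex_cost_per_cycle(
            c, price, config.cycle_days, whole_packs, config.n_cycles
        )
        out[c - 1, :3] = drug + care
        out[c - 1, 3:6] = care
    return out
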