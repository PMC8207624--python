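"""Resource use to euro costs (payer perspective, direct medical only).

Each resource category (ONS bottles, service days, visits, enteral /
parenteral nutrition days, hospital days, mucositis episodes) has a unit
cost with a price year; amounts are inflated to a common target year with
a user-supplied index and held internally in integer cents so category
amounts always sum exactly to the total. Arm comparisons use Welch
t-tests per category and a stratified bootstrap percentile test for the
total, which is robust to the heavy right tails of hospitalization and
parenteral-nutrition costs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .synthetic_trial import COST_GROUPS, DEFAULT_UNIT_COSTS, PatientRecord

__all__ = [
    "UnitCostTable",
    "CostBreakdown",
    "inflate",
    "patient_cost",
    "cost_dataframe",
    "cost_table",
    "default_unit_cost_table",
]

logger = logging.getLogger(__name__)


def inflate(
    amount: float, from_year: int, to_year: int, index: Mapping[int, float]
) -> float:
    """Rescale `amount` by the price index ratio index(to)/index(from)."""
    for y in (from_year, to_year):
        if y not in index:
            raise KeyError(f"year {y} not covered by the inflation index")
    if index[from_year] <= 0:
        raise ValueError(f"non-positive index value for year {from_year}")
    return amount * index[to_year] / index[from_year]


@dataclass(frozen=True)
class UnitCostTable:
    """Per-category unit costs (€) with units and price years, plus an
    inflation index mapping year -> price level.

    The default index is the identity (every year at 100): unit costs are
    then used as given, which is announced once via logging so users know
    no real price adjustment happened.
    """

    unit_costs: Mapping[str, float]
    units: Mapping[str, str]
    price_years: Mapping[str, int]
    inflation_index: Mapping[int, float] | None = None
    target_year: int = 2017

    def __post_init__(self):
        for cat, c in self.unit_costs.items():
            if c < 0:
                raise ValueError(f"negative unit cost for {cat!r}")
        if self.inflation_index is None:
            logger.info(
                "no inflation index configured: using identity (unit costs "
                "taken at face value, no adjustment to %d prices)",
                self.target_year,
            )
        else:
            for cat, y in self.price_years.items():
                if y not in self.inflation_index or self.target_year not in self.inflation_index:
                    raise ValueError(
                        f"inflation index does not cover price year {y} "
                        f"(category {cat!r}) and/or target year {self.target_year}"
                    )

    def factor(self, category: str) -> float:
        if self.inflation_index is None:
            return 1.0
        return inflate(1.0, self.price_years[category], self.target_year, self.inflation_index)


def default_unit_cost_table(inflation_index: Mapping[int, float] | None = None) -> UnitCostTable:
    return UnitCostTable(
        unit_costs={k: v[0] for k, v in DEFAULT_UNIT_COSTS.items()},
        units={k: v[1] for k, v in DEFAULT_UNIT_COSTS.items()},
        price_years={k: v[2] for k, v in DEFAULT_UNIT_COSTS.items()},
        inflation_index=inflation_index,
    )


@dataclass(frozen=True)
class CostBreakdown:
    """Per-category euro amounts for one patient; amounts are stored in
    cents internally so the total is exact."""

    cents: Mapping[str, int]

    @property
    def amounts(self) -> dict[str, float]:
        return {k: v / 100.0 for k, v in self.cents.items()}

    @property
    def total(self) -> float:
        return sum(self.cents.values()) / 100.0

    def grouped(self, groups: Mapping[str, Sequence[str]] = COST_GROUPS) -> dict[str, float]:
        return {
            g: sum(self.cents.get(c, 0) for c in cats) / 100.0 for g, cats in groups.items()
        }


def patient_cost(resources: Mapping[str, float], table: UnitCostTable) -> CostBreakdown:
    """Cost one patient's resource use: amount = quantity × unit cost ×
    inflation factor, rounded to the cent per category."""
    cents: dict[str, int] = {}
    for cat, qty in resources.items():
        if cat not in table.unit_costs:
            raise KeyError(f"unknown resource category {cat!r}")
        if qty < 0:
            raise ValueError(f"negative quantity for {cat!r}: {qty}")
        cents[cat] = int(round(qty * table.unit_costs[cat] * table.factor(cat) * 100.0))
    return CostBreakdown(cents)


def cost_dataframe(
    patients: Sequence[PatientRecord], table: UnitCostTable
) -> pd.DataFrame:
    """id, arm, one column per reporting group, and total (euros)."""
    rows = []
    for p in patients:
        bd = patient_cost(p.resources, table)
        rows.append({"id": p.id, "arm": p.arm, **bd.grouped(), "total": bd.total})
    return pd.DataFrame(rows)


def cost_table(
    costs: pd.DataFrame,
    b_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-category arm means with Welch-t p-values, plus the stratified
    bootstrap percentile p-value for the total.

    The bootstrap p is 2·min(P(Δ* ≤ 0), P(Δ* ≥ 0)) over `b_boot` resamples
    drawn with replacement within each arm.
    """
    if b_boot < 100:
        logger.warning("b_boot=%d is small; bootstrap p-value will be coarse", b_boot)
    arms = sorted(costs["arm"].unique())
    if len(arms) < 2:
        raise ValueError("both arms required for the cost comparison")
    t = costs[costs["arm"] == "treatment"]
    c = costs[costs["arm"] == "control"]
    if t.empty or c.empty:
        raise ValueError("both arms required for the cost comparison")

    cats = [col for col in costs.columns if col not in ("id", "arm")]
    rows = []
    for cat in cats:
        xt, xc = t[cat].to_numpy(float), c[cat].to_numpy(float)
        if np.allclose(xt.var(), 0) and np.allclose(xc.var(), 0):
            p_welch = 1.0 if np.isclose(xt.mean(), xc.mean()) else 0.0
        else:
            p_welch = float(stats.ttest_ind(xt, xc, equal_var=False).pvalue)
        rows.append(
            {
                "category": cat,
                "mean_treatment": xt.mean(),
                "mean_control": xc.mean(),
                "difference": xt.mean() - xc.mean(),
                "p_welch": p_welch,
            }
        )
    out = pd.DataFrame(rows).set_index("category")

    rng = substream(seed, "cost-bootstrap")
    xt, xc = t["total"].to_numpy(float), c["total"].to_numpy(float)
    it = rng.integers(0, xt.size, size=(b_boot, xt.size))
    ic = rng.integers(0, xc.size, size=(b_boot, xc.size))
    deltas = xt[it].mean(axis=1) - xc[ic].mean(axis=1)
    p_boot = 2.0 * min((deltas <= 0).mean(), (deltas >= 0).mean())
    out["p_bootstrap"] = np.nan
    out.loc["total", "p_bootstrap"] = min(p_boot, 1.0)
    return out.reset_index()
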