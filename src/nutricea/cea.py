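"""Decision-analytic core: bootstrap of incremental cost/effect and the
value-of-information summaries built on it.

Everything here operates on a :class:`CEDistribution` — a cloud of
(ΔC, ΔE) pairs produced either by the nonparametric patient-level
bootstrap or by the parametric probabilistic sensitivity analysis — so
the two uncertainty engines are interchangeable downstream.

At willingness-to-pay k (€/QALY), each pair has incremental net benefit
INB = k·ΔE − ΔC. The cost-effectiveness acceptability curve is
P(INB > 0) over a k-grid, the expected incremental benefit is mean INB,
and the per-patient expected value of perfect information is

    EVPI(k) = E[max(0, INB)] − max(0, E[INB]),

the expected opportunity loss of deciding under current information.
Population EVPI scales this by the annual number of patients affected
over a discounted decision horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "CEDistribution",
    "WTPGrid",
    "bootstrap_pairs",
    "icer",
    "ceac",
    "eib",
    "evpi",
    "population_evpi",
]


@dataclass(frozen=True)
class CEDistribution:
    """Cloud of bootstrap/PSA (ΔC, ΔE) pairs plus the original-sample
    point estimate."""

    delta_cost: np.ndarray  # €
    delta_effect: np.ndarray  # QALYs (or life years)
    point_estimate: tuple[float, float]  # (ΔC, ΔE) from the original sample
    source: str = "bootstrap"
    seed: int | None = None

    def __post_init__(self):
        dc = np.asarray(self.delta_cost, dtype=float)
        de = np.asarray(self.delta_effect, dtype=float)
        object.__setattr__(self, "delta_cost", dc)
        object.__setattr__(self, "delta_effect", de)
        if dc.shape != de.shape or dc.ndim != 1 or dc.size < 1:
            raise ValueError("delta_cost/delta_effect must be 1-d, equal length, non-empty")
        if not (np.isfinite(dc).all() and np.isfinite(de).all()):
            raise ValueError("pairs must be finite")
        if not all(np.isfinite(self.point_estimate)):
            raise ValueError("point estimate must be finite")

    @property
    def n_pairs(self) -> int:
        return self.delta_cost.size

    def net_benefit(self, k: float) -> np.ndarray:
        return k * self.delta_effect - self.delta_cost

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost": self.delta_cost, "delta_qaly": self.delta_effect})


@dataclass(frozen=True)
class WTPGrid:
    """Willingness-to-pay thresholds (€ per QALY), default 0..50,000 by 100."""

    thresholds: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        t = self.thresholds
        if t is None:
            t = np.arange(0.0, 50_000.0 + 1.0, 100.0)
        t = np.asarray(t, dtype=float)
        if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be non-negative and strictly increasing")
        object.__setattr__(self, "thresholds", t)


def bootstrap_pairs(
    costs: pd.DataFrame | pd.Series,
    effects: pd.DataFrame | pd.Series,
    arms: pd.Series | np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> CEDistribution:
    """Stratified patient-level bootstrap of (ΔC, ΔE).

    Each replicate resamples patients with replacement *within arm*
    (preserving the two arm sizes), recomputes arm means, and stores the
    treatment-minus-control differences.
    """
    arms = np.asarray(arms)
    cost = np.asarray(costs, dtype=float)
    eff = np.asarray(effects, dtype=float)
    ct, cc = cost[arms == "treatment"], cost[arms == "control"]
    et, ec = eff[arms == "treatment"], eff[arms == "control"]
    if ct.size == 0 or cc.size == 0:
        raise ValueError("both arms must be non-empty")

    rng = substream(seed, "cea-bootstrap")
    it = rng.integers(0, ct.size, size=(B, ct.size))
    ic = rng.integers(0, cc.size, size=(B, cc.size))
    dc = ct[it].mean(axis=1) - cc[ic].mean(axis=1)
    de = et[it].mean(axis=1) - ec[ic].mean(axis=1)
    point = (float(ct.mean() - cc.mean()), float(et.mean() - ec.mean()))
    return CEDistribution(dc, de, point, source="bootstrap", seed=seed)


def icer(delta_cost: float, delta_effect: float) -> dict:
    """Incremental cost-effectiveness ratio with its quadrant label.

    ΔC<0, ΔE>0 is dominant (less costly, more effective); ΔC>0, ΔE<0 is
    dominated; both-negative / both-positive are trade-offs where the
    ratio must be read against a threshold. ΔE = 0 flags the ratio
    undefined instead of raising.
    """
    if delta_effect == 0:
        label = "undefined (no effect difference)"
        ratio = np.nan
    else:
        ratio = delta_cost / delta_effect
        if delta_cost < 0 and delta_effect > 0:
            label = "dominant"
        elif delta_cost > 0 and delta_effect < 0:
            label = "dominated"
        elif delta_cost <= 0 and delta_effect <= 0:
            label = "trade-off (less costly, less effective)"
        elif delta_cost == 0:
            label = "dominant" if delta_effect > 0 else "dominated"
        else:
            label = "trade-off (more costly, more effective)"
    return {
        "delta_cost": float(delta_cost),
        "delta_effect": float(delta_effect),
        "icer": float(ratio),
        "defined": delta_effect != 0,
        "label": label,
    }


def ceac(dist: CEDistribution, grid: WTPGrid | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: for each threshold k the
    fraction of pairs with positive net benefit k·ΔE − ΔC."""
    grid = grid or WTPGrid()
    nb = grid.thresholds[:, None] * dist.delta_effect[None, :] - dist.delta_cost[None, :]
    prob = (nb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": grid.thresholds, "probability": prob})


def eib(dist: CEDistribution, k: float) -> dict:
    """Expected incremental benefit at threshold k: mean of per-pair net
    benefits, with a 2.5/97.5 percentile interval."""
    nb = dist.net_benefit(k)
    lo, hi = np.percentile(nb, [2.5, 97.5])
    return {
        "wtp": float(k),
        "eib": float(nb.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
    }


def evpi(dist: CEDistribution, k: float) -> float:
    """Per-patient expected value of perfect information at threshold k
    (always ≥ 0; exactly 0 when every pair agrees on the decision)."""
    nb = dist.net_benefit(k)
    return float(np.maximum(nb, 0.0).mean() - max(nb.mean(), 0.0))


def population_evpi(
    evpi_per_patient: float,
    incidence: float,
    horizon_years: int,
    discount_rate: float,
) -> float:
    """Population EVPI: per-patient EVPI scaled by the annual number of
    patients affected, summed over years t = 1..horizon and discounted by
    (1 + r)^t — every year including the first is discounted."""
    if min(evpi_per_patient, incidence, horizon_years, discount_rate) < 0:
        raise ValueError("all population-EVPI inputs must be non-negative")
    t = np.arange(1, int(horizon_years) + 1)
    return float(np.sum(incidence * evpi_per_patient / (1.0 + discount_rate) ** t))
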