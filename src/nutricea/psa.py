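"""Parametric probabilistic sensitivity analysis.

Per-arm costs and (transformed) QALYs are fitted by maximum likelihood to
candidate families — normal, gamma, Weibull, lognormal — and the family
with the lowest AIC is selected. QALYs are left-skewed and bounded above
by the 5-month maximum of 5/12 ≈ 0.417 years, so their *complement to the
maximum* (a right-skewed positive quantity) is fitted instead and samples
are back-transformed. Cost samples with exact zeros are handled as a
mixture: a point mass at zero plus a positive family fitted to the
positive part. Independent draws per arm and quantity are assembled into
a :class:`~nutricea.cea.CEDistribution`, so the whole decision-analytic
toolkit applies unchanged.

Costs and effects are sampled independently within arm; any cost-effect
correlation present in the trial data is not propagated (a documented
limitation of this PSA design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._rng import substream
from .cea import CEDistribution

__all__ = [
    "FitResult",
    "ZeroInflatedFit",
    "fit_family",
    "fit_best_distribution",
    "fit_cost_distribution",
    "transform_qaly_complement",
    "inverse_qaly_complement",
    "sample_psa",
    "MAX_QALY_DEFAULT",
]

MAX_QALY_DEFAULT = 5.0 / 12.0

_FAMILIES: dict[str, stats.rv_continuous] = {
    "normal": stats.norm,
    "gamma": stats.gamma,
    "weibull": stats.weibull_min,
    "lognormal": stats.lognorm,
}
# number of free parameters per family (location fixed at 0 for the
# positive-support families)
_N_PARAMS = {"normal": 2, "gamma": 2, "weibull": 2, "lognormal": 2}


@dataclass(frozen=True)
class FitResult:
    family: str
    parameters: tuple[float, ...]  # scipy frozen-distribution args
    log_likelihood: float
    aic: float
    n: int

    def frozen(self) -> stats.rv_continuous:
        return _FAMILIES[self.family](*self.parameters)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.frozen().rvs(size=size, random_state=rng)


def fit_family(values: np.ndarray, family: str) -> FitResult:
    """Maximum-likelihood fit of one candidate family.

    Positive-support families are fitted with location pinned at zero
    (two free parameters each, like the normal), so AICs are comparable.
    """
    x = np.asarray(values, dtype=float)
    dist = _FAMILIES[family]
    if family == "normal":
        params = dist.fit(x)
    else:
        if np.any(x <= 0):
            raise ValueError(f"{family} requires strictly positive values")
        params = dist.fit(x, floc=0)
    ll = float(np.sum(dist.logpdf(x, *params)))
    k = _N_PARAMS[family]
    return FitResult(family, tuple(float(p) for p in params), ll, 2.0 * k - 2.0 * ll, x.size)


def fit_best_distribution(
    values: Sequence[float],
    candidates: Sequence[str] = ("normal", "gamma", "weibull", "lognormal"),
) -> tuple[FitResult, list[FitResult]]:
    """Fit every candidate family and select by lowest AIC.

    Ties are broken by fewer parameters, then lexicographic family name.
    Requires n ≥ 10 and a non-degenerate sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 values to fit a distribution (got {x.size})")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample: no distribution is identifiable")
    unknown = set(candidates) - set(_FAMILIES)
    if unknown:
        raise ValueError(f"unknown candidate families: {sorted(unknown)}")
    fits = [fit_family(x, fam) for fam in sorted(candidates)]
    best = min(fits, key=lambda f: (f.aic, _N_PARAMS[f.family], f.family))
    return best, fits


@dataclass(frozen=True)
class ZeroInflatedFit:
    """Point mass at zero with probability `p_zero`, positive part fitted
    separately (gamma/Weibull/lognormal exclude zero from their support)."""

    p_zero: float
    positive: FitResult

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.zeros(size)
        pos = rng.random(size) >= self.p_zero
        k = int(pos.sum())
        if k:
            out[pos] = self.positive.sample(rng, k)
        return out


def fit_cost_distribution(
    values: Sequence[float],
    candidates: Sequence[str] = ("normal", "gamma", "weibull", "lognormal"),
) -> ZeroInflatedFit:
    """Fit per-arm costs, treating exact zeros as a point mass."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("costs must be non-negative")
    pos = x[x > 0]
    p_zero = 1.0 - pos.size / x.size
    cand = [c for c in candidates if c != "normal"] if p_zero > 0 else list(candidates)
    best, _ = fit_best_distribution(pos, cand)
    return ZeroInflatedFit(p_zero, best)


def transform_qaly_complement(
    qalys: Sequence[float], max_q: float = MAX_QALY_DEFAULT
) -> np.ndarray:
    """Map QALYs in [0, max_q] to their right-skewed complement max_q − q.

    Exact-zero complements (patients at the theoretical maximum) are
    shifted by epsilon = half the smallest positive complement, keeping
    the values inside the positive support of gamma/Weibull/lognormal.
    """
    q = np.asarray(qalys, dtype=float)
    if np.any(q < 0) or np.any(q > max_q + 1e-12):
        raise ValueError(f"QALYs must lie in [0, {max_q}]")
    comp = np.clip(max_q - q, 0.0, None)
    zero = comp <= 0
    if zero.any():
        positive = comp[~zero]
        if positive.size == 0:
            raise ValueError("every QALY equals the maximum: complement degenerate")
        comp[zero] = positive.min() / 2.0
    return comp


def inverse_qaly_complement(
    samples: np.ndarray, max_q: float = MAX_QALY_DEFAULT
) -> np.ndarray:
    """Back-transform complement samples to the QALY scale, clamped to
    [0, max_q]."""
    return np.clip(max_q - np.asarray(samples, dtype=float), 0.0, max_q)


def sample_psa(
    cost_fits: Mapping[str, ZeroInflatedFit | FitResult],
    qaly_fits: Mapping[str, FitResult],
    point_estimate: tuple[float, float],
    N: int = 1000,
    seed: int = 0,
    max_q: float = MAX_QALY_DEFAULT,
) -> CEDistribution:
    """Draw N independent PSA samples per arm and assemble (ΔC, ΔE) pairs.

    `qaly_fits` are fits of the QALY *complement*; draws are
    back-transformed and clamped to [0, max_q].
    """
    rng = substream(seed, "psa")
    draws = {}
    for arm in ("treatment", "control"):
        draws[arm, "cost"] = cost_fits[arm].sample(rng, N)
        draws[arm, "qaly"] = inverse_qaly_complement(qaly_fits[arm].sample(rng, N), max_q)
    dc = draws["treatment", "cost"] - draws["control", "cost"]
    de = draws["treatment", "qaly"] - draws["control", "qaly"]
    return CEDistribution(dc, de, point_estimate, source="psa", seed=seed)
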