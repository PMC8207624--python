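"""Long-term survival analysis for the 6-year follow-up.

Implements the product-limit (Kaplan–Meier) estimator with Greenwood
variance, the reverse-KM median follow-up, restricted mean survival time
(RMST) with its integrated-Greenwood variance and difference test, the
Fleming–Harrington G(p, q) weighted log-rank family, the max-combo
(versatile) test with a permutation reference distribution, and the
discounted life-years-gained ICER table over yearly horizons.

The weighted log-rank weight at pooled event time t is
``S_pool(t-)^p * (1 - S_pool(t-))^q`` with S_pool the left-continuous
pooled KM estimate: q > 0 emphasises late differences, p > 0 early ones,
and (0, 0) is the ordinary log-rank test. The max-combo statistic takes
the maximum |z| over a small set of (p, q) weights so power is retained
when the hazard-difference shape is unknown a priori.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .cea import icer as _icer_label

__all__ = [
    "SurvivalCurve",
    "WeightedLogRankResult",
    "km_fit",
    "reverse_km_median",
    "rmst",
    "rmst_difference",
    "weighted_logrank",
    "maxcombo",
    "discounted_lyg_icer",
    "DAYS_PER_YEAR",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

DEFAULT_COMBOS = ((0, 0), (1, 0), (0, 2))


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous step-function survival estimate.

    Steps occur at event times only; `survival[k]` is S(t) just after
    `event_times[k]`, `at_risk[k]` and `n_events[k]` are the risk set and
    event count at that time, and `greenwood_var[k]` is the Greenwood
    variance of S at that step. `max_time` is the largest observed
    (event or censoring) time, bounding the supported horizon.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray
    n_subjects: int
    max_time: float

    def evaluate(self, t) -> np.ndarray:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate(([1.0], self.survival))
        return s[idx]

    def evaluate_left(self, t) -> np.ndarray:
        """S(t-), left-continuous (value just before t)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="left")
        s = np.concatenate(([1.0], self.survival))
        return s[idx]

    def integrate(self, a: float, b: float) -> float:
        """Integral of the step function S over [a, b] (same time units)."""
        if b <= a:
            return 0.0
        knots = np.concatenate(([a], self.event_times[(self.event_times > a) & (self.event_times < b)], [b]))
        heights = self.evaluate(knots[:-1])
        return float(np.sum(np.diff(knots) * heights))


def _sorted_events(times: np.ndarray, events: np.ndarray):
    """Sort ascending by time with events before censorings at ties."""
    order = np.lexsort((1 - events, times))
    return times[order], events[order]


def km_fit(times, events) -> SurvivalCurve:
    """Product-limit survival estimate with Greenwood variance.

    At tied times, events are processed before censorings (both count in
    the risk set at that time).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if np.any(t < 0):
        raise ValueError("survival times must be non-negative")
    ts, es = _sorted_events(t, e)
    n = t.size

    ev_times, surv, risk, nev, gvar = [], [], [], [], []
    s = 1.0
    gsum = 0.0
    uniq = np.unique(ts[es == 1])
    for tt in uniq:
        n_at_risk = int(np.sum(ts >= tt))
        d = int(np.sum((ts == tt) & (es == 1)))
        s *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            gsum += d / (n_at_risk * (n_at_risk - d))
        else:
            gsum = np.inf if s > 0 else gsum  # curve hits 0: variance term degenerate
        ev_times.append(tt)
        surv.append(s)
        risk.append(n_at_risk)
        nev.append(d)
        gvar.append(s**2 * gsum if s > 0 else 0.0)
    return SurvivalCurve(
        np.asarray(ev_times),
        np.asarray(surv),
        np.asarray(risk),
        np.asarray(nev),
        np.asarray(gvar),
        n_subjects=n,
        max_time=float(ts.max()),
    )


def _band_crossing(curve: SurvivalCurve, band: np.ndarray, level: float) -> float:
    below = band <= level
    if not below.any():
        return np.nan
    return float(curve.event_times[int(np.argmax(below))])


def reverse_km_median(times, events) -> dict:
    """Median potential follow-up by the reverse Kaplan–Meier method.

    Censorings become the 'event' and deaths are censored, so the curve
    estimates the follow-up distribution; the median is the first time it
    drops to 0.5 or below, with a 95% CI from the log-log-transformed
    Greenwood bands. If the curve never reaches 0.5 the median is flagged
    undefined (NaN).
    """
    e = np.asarray(events, dtype=int)
    curve = km_fit(times, 1 - e)
    med = _band_crossing(curve, curve.survival, 0.5)
    z = stats.norm.ppf(0.975)
    s = curve.survival
    with np.errstate(divide="ignore", invalid="ignore"):
        se_loglog = np.sqrt(curve.greenwood_var) / np.abs(s * np.log(s))
        theta = np.exp(z * se_loglog)
        upper = s ** (1.0 / theta)
        lower = s**theta
    lower = np.where(np.isfinite(lower), lower, 0.0)
    upper = np.where(np.isfinite(upper), upper, 1.0)
    return {
        "median_days": med,
        "defined": np.isfinite(med),
        "ci_low_days": _band_crossing(curve, lower, 0.5),
        "ci_high_days": _band_crossing(curve, upper, 0.5),
        "curve": curve,
    }


def rmst(curve: SurvivalCurve, tau_days: float) -> dict:
    """Restricted mean survival time to `tau_days`, in years, with the
    integrated-Greenwood variance."""
    if tau_days > curve.max_time:
        raise ValueError(
            f"tau={tau_days:g} d exceeds the largest observed time "
            f"({curve.max_time:g} d) for this arm"
        )
    area_days = curve.integrate(0.0, tau_days)
    # var(RMST) = sum over event times t_j<=tau of [int_{t_j}^{tau} S]^2 * d/(n(n-d))
    var = 0.0
    for tt, n_r, d in zip(curve.event_times, curve.at_risk, curve.n_events):
        if tt >= tau_days or n_r <= d:
            continue
        a_j = curve.integrate(tt, tau_days)
        var += a_j**2 * d / (n_r * (n_r - d))
    return {
        "tau_days": float(tau_days),
        "rmst_years": area_days / DAYS_PER_YEAR,
        "variance_years2": var / DAYS_PER_YEAR**2,
    }


def rmst_difference(curve_t: SurvivalCurve, curve_c: SurvivalCurve, tau_days: float) -> dict:
    """Treatment-minus-control RMST difference with a normal z-test."""
    rt, rc = rmst(curve_t, tau_days), rmst(curve_c, tau_days)
    diff = rt["rmst_years"] - rc["rmst_years"]
    se = np.sqrt(rt["variance_years2"] + rc["variance_years2"])
    z = diff / se if se > 0 else np.nan
    return {
        "tau_days": float(tau_days),
        "rmst_treatment": rt["rmst_years"],
        "rmst_control": rc["rmst_years"],
        "difference_years": diff,
        "se": float(se),
        "z": float(z),
        "p_value": float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
    }


@dataclass(frozen=True)
class WeightedLogRankResult:
    p: float
    q: float
    statistic: float  # sum of weighted (O - E) for the treatment arm
    variance: float
    z: float
    p_value: float


def _event_table(times: np.ndarray, events: np.ndarray, group1: np.ndarray):
    """Pooled distinct event times with (n, n1, d, d1) at each."""
    uniq = np.unique(times[events == 1])
    n = np.array([np.sum(times >= tt) for tt in uniq], dtype=float)
    n1 = np.array([np.sum((times >= tt) & group1) for tt in uniq], dtype=float)
    d = np.array([np.sum((times == tt) & (events == 1)) for tt in uniq], dtype=float)
    d1 = np.array([np.sum((times == tt) & (events == 1) & group1) for tt in uniq], dtype=float)
    return uniq, n, n1, d, d1


def _fh_weights(times, events, uniq, p: float, q: float) -> np.ndarray:
    pooled = km_fit(times, events)
    s_minus = pooled.evaluate_left(uniq)
    return s_minus**p * (1.0 - s_minus) ** q


def weighted_logrank(times, events, arm, p: float = 0.0, q: float = 0.0) -> WeightedLogRankResult:
    """Fleming–Harrington G(p, q) weighted log-rank test (two arms).

    The statistic sums w(t)·(observed − expected) treatment events over
    pooled event times, with the hypergeometric variance; the reference
    distribution is standard normal.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(arm)
    g1 = g == "treatment" if g.dtype.kind in "UO" else g.astype(bool)
    if g1.all() or (~g1).all():
        raise ValueError("weighted log-rank needs subjects in both arms")
    if e.sum() == 0:
        raise ValueError("no events in the pooled sample")
    uniq, n, n1, d, d1 = _event_table(t, e, g1)
    w = _fh_weights(t, e, uniq, p, q)
    o_minus_e = d1 - d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * (n1 / n) * (1.0 - n1 / n) * (n - d) / np.maximum(n - 1.0, 1.0)
    stat = float(np.sum(w * o_minus_e))
    var = float(np.sum(w**2 * var_terms))
    z = stat / np.sqrt(var) if var > 0 else np.nan
    pv = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return WeightedLogRankResult(p, q, stat, var, float(z), pv)


def _z_matrix(times, events, labels_matrix, combos) -> np.ndarray:
    """z-statistics for each label permutation (rows) and combo (cols).

    `labels_matrix` holds 0/1 treatment indicators under the *sorted*
    subject order (events first at ties). Weights depend only on the
    pooled sample, so they are shared across permutations.
    """
    ts, es = times, events  # already sorted
    n_sub = ts.size
    uniq, first_idx = np.unique(ts, return_index=True)
    ev_mask = es == 1
    uniq_ev = np.unique(ts[ev_mask])
    keep = np.isin(uniq, uniq_ev)
    first_idx = first_idx[keep]
    uniq = uniq[keep]

    n_at = (n_sub - first_idx).astype(float)
    # totals per distinct event time
    d = np.array([np.sum((ts == tt) & ev_mask) for tt in uniq], dtype=float)

    L = labels_matrix.astype(float)  # (P, n_sub)
    suffix = np.cumsum(L[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, first_idx]  # (P, K)
    ev_labels = L * ev_mask[None, :]
    # arm-1 events at each distinct event time via cumulative sums
    seg_starts = np.searchsorted(ts, uniq, side="left")
    last_idx = np.searchsorted(ts, uniq, side="right")
    cum_ev = np.concatenate(
        [np.zeros((L.shape[0], 1)), np.cumsum(ev_labels, axis=1)], axis=1
    )
    d1 = cum_ev[:, last_idx] - cum_ev[:, seg_starts]

    zs = np.empty((L.shape[0], len(combos)))
    pooled = km_fit(ts, es)
    s_minus = pooled.evaluate_left(uniq)
    frac = n1 / n_at[None, :]
    ome = d1 - d[None, :] * frac
    var_core = d[None, :] * frac * (1.0 - frac) * (n_at[None, :] - d[None, :]) / np.maximum(
        n_at[None, :] - 1.0, 1.0
    )
    for j, (p, q) in enumerate(combos):
        w = s_minus**p * (1.0 - s_minus) ** q
        stat = np.sum(w[None, :] * ome, axis=1)
        var = np.sum((w**2)[None, :] * var_core, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            zs[:, j] = np.where(var > 0, stat / np.sqrt(var), 0.0)
    return zs


def maxcombo(
    times,
    events,
    arm,
    combos=DEFAULT_COMBOS,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Versatile (max-combo) test: maximum |z| over weighted log-rank
    statistics, with a permutation reference distribution.

    Arm labels are permuted `n_perm` times; the p-value is
    (1 + #{permutation max-|z| ≥ observed}) / (1 + n_perm), with its
    Monte-Carlo standard error reported.
    """
    if n_perm < 1000:
        logger.warning("n_perm=%d permutations is few; p-value will be coarse", n_perm)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(arm)
    g1 = (g == "treatment") if g.dtype.kind in "UO" else g.astype(bool)
    if g1.all() or (~g1).all():
        raise ValueError("max-combo needs subjects in both arms")

    order = np.lexsort((1 - e, t))
    ts, es, gs = t[order], e[order], g1[order].astype(int)

    z_obs = _z_matrix(ts, es, gs[None, :], combos)[0]
    stat_obs = float(np.max(np.abs(z_obs)))

    rng = substream(seed, "maxcombo-perm")
    perms = gs[np.argsort(rng.random((n_perm, gs.size)), axis=1)]
    z_perm = _z_matrix(ts, es, perms, combos)
    stat_perm = np.max(np.abs(z_perm), axis=1)
    exceed = int(np.sum(stat_perm >= stat_obs - 1e-12))
    p_val = (1 + exceed) / (1 + n_perm)
    mc_se = float(np.sqrt(p_val * (1 - p_val) / n_perm))
    return {
        "combos": tuple(combos),
        "z_per_combo": tuple(float(z) for z in z_obs),
        "statistic": stat_obs,
        "p_value": float(p_val),
        "mc_se": mc_se,
        "n_perm": int(n_perm),
    }


def discounted_lyg_icer(
    curve_t: SurvivalCurve,
    curve_c: SurvivalCurve,
    delta_cost: float,
    taus_years=(1, 2, 3, 4, 5, 6),
    discount_rate: float = 0.035,
) -> pd.DataFrame:
    """Yearly cost-per-life-year-gained table.

    Mean overall survival per arm is the (undiscounted) RMST at each
    horizon; life years gained discount the incremental area accrued in
    year t by (1 + r)^-(t-1) — the first year is undiscounted. The
    incremental cost is carried over from the on-trial analysis under the
    assumption that post-trial costs do not differ by arm.
    """
    rows = []
    max_tau = max(taus_years)
    yearly_incr = []
    for yr in range(1, max_tau + 1):
        a, b = (yr - 1) * DAYS_PER_YEAR, yr * DAYS_PER_YEAR
        incr = (curve_t.integrate(a, b) - curve_c.integrate(a, b)) / DAYS_PER_YEAR
        yearly_incr.append(incr / (1.0 + discount_rate) ** (yr - 1))
    for tau in taus_years:
        tau_days = tau * DAYS_PER_YEAR
        diff = rmst_difference(curve_t, curve_c, tau_days)
        lyg = float(np.sum(yearly_incr[:tau]))
        lab = _icer_label(delta_cost, lyg)
        rows.append(
            {
                "tau_years": tau,
                "mean_os_treatment": diff["rmst_treatment"],
                "mean_os_control": diff["rmst_control"],
                "difference_years": diff["difference_years"],
                "p_value": diff["p_value"],
                "discounted_lyg": lyg,
                "icer_eur_per_lyg": lab["icer"],
                "icer_defined": lab["defined"],
                "label": lab["label"],
            }
        )
    return pd.DataFrame(rows)
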