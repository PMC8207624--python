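"""From longitudinal utility data to per-patient QALYs.

The on-trial effectiveness endpoint is the quality-adjusted life-year,
computed per patient as the (linearly) interpolated area under the
utility-vs-time curve over the 5-month horizon and expressed in years
(divide the month-scale area by 12). Missing utilities are handled in two
stages, mirroring standard trial practice:

1. rule-based assignment for informative dropout — patients hospitalized
   or moved to artificial nutrition receive literature-based utilities
   (default 0.35 up to the end of radiotherapy, 0.30 after); decedents
   receive 0 from death onwards;
2. chained multiple imputation (predictive mean matching) for the
   remaining sporadic or loss-to-follow-up gaps, conditioning on baseline
   covariates and the utilities observed at the other visits.

A random-intercept linear mixed model compares the utility profiles of
the two arms over time; the supported test for the arm-by-time
interaction is the likelihood-ratio test between the ML fits with and
without the interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from ._rng import substream
from .synthetic_trial import PatientRecord, UtilityTrajectory

__all__ = [
    "MappingSpec",
    "map_scores_to_utility",
    "assign_dropout_utility",
    "impute_chained",
    "qaly_auc",
    "qaly_table",
    "pool_rubin",
    "fit_random_intercept_lmm",
    "MAX_QALY_5_MONTHS",
]

#: maximum attainable QALY over the 5-month horizon (5/12 of a year)
MAX_QALY_5_MONTHS = 5.0 / 12.0


# ----------------------------------------------------------------------
# Mapping hook (EORTC QLQ-C30 scales -> utility)


@dataclass(frozen=True)
class MappingSpec:
    """User-supplied linear mapping from quality-of-life scale scores to a
    preference-based utility. Coefficients come from an external mapping
    study; none are bundled."""

    predictor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float = 0.0
    link: str = "identity"  # or "logit-inverse"

    def __post_init__(self):
        if len(self.predictor_names) != len(self.coefficients):
            raise ValueError("one coefficient per predictor required")
        if self.link not in ("identity", "logit-inverse"):
            raise ValueError(f"unknown link {self.link!r}")


def map_scores_to_utility(scores: Mapping[str, float], spec: MappingSpec) -> float:
    """Linear predictor over the named scales, transformed by the link and
    clamped to [0, 1]."""
    try:
        x = np.array([scores[name] for name in spec.predictor_names], dtype=float)
    except KeyError as e:
        raise KeyError(f"missing scale score: {e.args[0]!r}") from None
    eta = spec.intercept + float(np.dot(x, spec.coefficients))
    if spec.link == "logit-inverse":
        eta = 1.0 / (1.0 + np.exp(-eta))
    return float(np.clip(eta, 0.0, 1.0))


# ----------------------------------------------------------------------
# Rule-based dropout utilities


def assign_dropout_utility(
    traj: UtilityTrajectory,
    end_of_rt_month: float = 2.0,
    u_before: float = 0.35,
    u_after: float = 0.30,
) -> UtilityTrajectory:
    """Fill visits lost to informative dropout with rule-based utilities.

    Hospitalization / artificial-nutrition dropouts: missing visits from
    the dropout time on get `u_before` while the visit is at or before the
    end of radiotherapy, `u_after` later. Death: visits at or after the
    death time get utility 0. Observed values are never overwritten;
    other dropout reasons (or none) leave the trajectory unchanged.
    """
    out = traj.copy()
    if traj.dropout_reason in ("none", "lost") or traj.dropout_time is None:
        return out
    if traj.dropout_time > traj.times[-1]:
        return out
    affected = (out.times >= traj.dropout_time) & np.isnan(out.values)
    if traj.dropout_reason == "death":
        out.values[affected] = 0.0
    elif traj.dropout_reason in ("hospitalization", "artificial_nutrition"):
        out.values[affected & (out.times <= end_of_rt_month)] = u_before
        out.values[affected & (out.times > end_of_rt_month)] = u_after
    return out


# ----------------------------------------------------------------------
# Chained multiple imputation (predictive mean matching)

_BASELINE_PREDICTORS = (
    "age",
    "gender",
    "malnourished_at_inclusion",
    "tumor_site",
    "tumor_stage",
    "handgrip",
    "phase_angle",
)


def _design_matrix(df: pd.DataFrame, value_cols: Sequence[str]) -> pd.DataFrame:
    X = pd.get_dummies(
        df[list(_BASELINE_PREDICTORS)], drop_first=True, dtype=float
    ).astype(float)
    for c in value_cols:
        X[c] = df[c].to_numpy(dtype=float)
    return X


def _pmm_draw(
    y: np.ndarray,
    X: np.ndarray,
    miss: np.ndarray,
    rng: np.random.Generator,
    k_donors: int,
) -> np.ndarray:
    """One PMM step: Bayesian linear regression on the observed rows, then
    each missing row borrows the observed value of one of the `k_donors`
    nearest predicted means."""
    obs = ~miss
    Xo, yo = X[obs], y[obs]
    n, p = Xo.shape
    XtX = Xo.T @ Xo + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    cov = sigma2 * np.linalg.inv(XtX)
    beta = rng.multivariate_normal(beta_hat, cov, method="svd")
    mu_obs = Xo @ beta
    mu_mis = X[miss] @ beta
    # nearest observed predicted means as donor pool
    order = np.argsort(np.abs(mu_obs[None, :] - mu_mis[:, None]), axis=1)[:, :k_donors]
    pick = rng.integers(0, order.shape[1], size=order.shape[0])
    donors = order[np.arange(order.shape[0]), pick]
    return yo[donors]


def impute_chained(
    dataset: Sequence[PatientRecord],
    m: int = 20,
    seed: int = 0,
    n_iter: int = 10,
    k_donors: int = 5,
) -> list[list[UtilityTrajectory]]:
    """Multiply impute remaining missing utilities by chained equations.

    Each visit with missing values is regressed in turn on the baseline
    covariates plus the (current) utilities at the other visits; imputed
    values are drawn by predictive mean matching, so they are always
    observed donor values and hence stay in [0, 1]. Returns, per
    imputation, one completed trajectory per patient (input order).
    Rule-based dropout assignment must have been applied first.
    """
    if m < 2:
        raise ValueError("m must be at least 2 (multiple imputation)")
    patients = list(dataset)
    times = patients[0].utilities.times
    vcols = [f"u{j}" for j in range(len(times))]
    rows = []
    for p in patients:
        row = {c: getattr(p, c) for c in _BASELINE_PREDICTORS}
        for j, v in enumerate(p.utilities.values):
            row[vcols[j]] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    miss = df[vcols].isna().to_numpy()
    for j, c in enumerate(vcols):
        if miss[:, j].all():
            raise ValueError(
                f"utility at visit month {times[j]} missing for every patient; "
                "imputation model unidentifiable"
            )

    if not miss.any():
        return [[p.utilities.copy() for p in patients] for _ in range(m)]

    completed: list[list[UtilityTrajectory]] = []
    for imp in range(m):
        rng = substream(seed, f"mice-{imp}")
        work = df[vcols].to_numpy(dtype=float).copy()
        # start from observed per-visit means
        col_means = np.nanmean(work, axis=0)
        for j in range(work.shape[1]):
            work[miss[:, j], j] = col_means[j]
        for _ in range(n_iter):
            for j in range(work.shape[1]):
                mj = miss[:, j]
                if not mj.any():
                    continue
                dfx = df.copy()
                for jj, c in enumerate(vcols):
                    dfx[c] = work[:, jj]
                X = _design_matrix(dfx, [c for c in vcols if c != vcols[j]])
                X.insert(0, "const", 1.0)
                work[mj, j] = _pmm_draw(work[:, j], X.to_numpy(), mj, rng, k_donors)
        trajs = []
        for i, p in enumerate(patients):
            t = p.utilities.copy()
            t.values = work[i].copy()
            trajs.append(t)
        completed.append(trajs)
    return completed


# ----------------------------------------------------------------------
# QALY area under the curve


def qaly_auc(traj: UtilityTrajectory) -> float:
    """Trapezoidal area under the utility curve, in years.

    Times are months since randomization, so the month-scale area is
    divided by 12; a constant utility of 1 over a 5-month horizon yields
    5/12 ≈ 0.417 years, the maximum attainable.
    """
    if np.isnan(traj.values).any():
        raise ValueError("trajectory has missing utilities: impute before qaly_auc")
    return float(np.trapezoid(traj.values, traj.times) / 12.0)


def qaly_table(
    imputations: Sequence[Sequence[UtilityTrajectory]],
    patients: Sequence[PatientRecord],
) -> pd.DataFrame:
    """Per-patient QALYs averaged over imputations (id, arm, qaly,
    n_imputations). Downstream bootstrap operates on this average."""
    m = len(imputations)
    qalys = np.array([[qaly_auc(t) for t in trajs] for trajs in imputations])
    return pd.DataFrame(
        {
            "id": [p.id for p in patients],
            "arm": [p.arm for p in patients],
            "qaly": qalys.mean(axis=0),
            "n_imputations": m,
        }
    )


def pool_rubin(estimates: Sequence[float], variances: Sequence[float]) -> dict:
    """Rubin's rules: pooled estimate, total variance (within + (1+1/m)
    between), and the between/within breakdown."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    qbar = q.mean()
    w = u.mean()
    b = q.var(ddof=1) if m > 1 else 0.0
    t = w + (1.0 + 1.0 / m) * b
    return {"estimate": float(qbar), "variance": float(t), "within": float(w), "between": float(b)}


# ----------------------------------------------------------------------
# Random-intercept linear mixed model


def fit_random_intercept_lmm(long_data: pd.DataFrame) -> dict:
    """Compare arm utility profiles over time with a random-intercept LMM.

    `long_data` needs columns id, arm, visit_month, utility (complete
    cases only are used). Fixed effects: arm, visit (categorical) and
    their interaction; random effect: patient intercept. Reports the REML
    fit of the interaction model and the ML likelihood-ratio test of the
    interaction (the arm-by-time effect).
    """
    df = long_data.dropna(subset=["utility"]).copy()
    arms = df["arm"].unique()
    if len(arms) < 2:
        raise ValueError("both arms required to compare utility profiles")
    df["visit"] = pd.Categorical(df["visit_month"])
    df["arm"] = pd.Categorical(df["arm"], categories=sorted(arms))

    full = "utility ~ C(arm) * C(visit)"
    nointer = "utility ~ C(arm) + C(visit)"

    def _fit(formula, reml):
        import warnings

        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        model = smf.mixedlm(formula, df, groups=df["id"])
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # boundary solutions (zero random-intercept variance) are valid
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            last_err = None
            # gradient-based first; derivative-free fallbacks for small
            # samples where the profiled information matrix turns singular
            for method in (["lbfgs", "powell"], ["powell"], ["nm"]):
                try:
                    return model.fit(reml=reml, method=method, maxiter=2000)
                except np.linalg.LinAlgError as e:  # pragma: no cover - data dependent
                    last_err = e
            raise last_err

    reml_fit = _fit(full, reml=True)
    ml_full = _fit(full, reml=False)
    ml_red = _fit(nointer, reml=False)

    lr = 2.0 * (ml_full.llf - ml_red.llf)
    df_diff = ml_full.model.k_fe - ml_red.model.k_fe
    p = float(stats.chi2.sf(max(lr, 0.0), df_diff))

    return {
        "fixed_effects": reml_fit.fe_params.to_dict(),
        "random_intercept_var": float(np.asarray(reml_fit.cov_re)[0, 0]),
        "residual_var": float(reml_fit.scale),
        "loglike_reml": float(reml_fit.llf),
        "loglike_ml": float(ml_full.llf),
        "lrt_interaction": {"statistic": float(lr), "df": int(df_diff), "p_value": p},
        "converged": bool(reml_fit.converged and ml_full.converged and ml_red.converged),
    }
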