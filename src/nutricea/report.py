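"""End-to-end pipeline: simulate/load -> QALYs -> costs -> bootstrap CEA
-> PSA -> long-term survival, with seed management and a provenance
manifest.

Every artifact is plain CSV/JSON. A run is a pure function of
(input data, configuration, master seed): rerunning with the same
configuration reproduces every file bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import cea, costing, psa, survival, utilities_qaly
from .synthetic_trial import (
    DAYS_PER_YEAR,
    PatientRecord,
    TrialConfig,
    UtilityTrajectory,
    generate_trial,
    true_values,
    write_trial_csvs,
)

__all__ = ["PipelineConfig", "ConfigError", "DataError", "run_pipeline", "load_trial_csvs"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class DataError(ValueError):
    """Input data violate a pipeline precondition."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on besides the data themselves."""

    # simulation mode: embedded trial config; file mode: three CSV paths
    trial: TrialConfig | None = None
    utilities_csv: str | None = None
    resources_csv: str | None = None
    survival_csv: str | None = None

    wtp_max: float = 50_000.0
    wtp_step: float = 100.0
    wtp_reference: float = 30_000.0
    b_bootstrap: int = 1000
    n_psa: int = 1000
    m_imputations: int = 20
    n_perm: int = 10_000
    discount_rate: float = 0.035
    incidence_per_year: float = 5580.0
    evpi_horizon_years: int = 10
    survival_taus_years: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    inflation_index: Mapping[int, float] | None = None
    seed: int = 12345
    outdir: str = "results/pipeline"

    def __post_init__(self):
        for name in ("b_bootstrap", "n_psa", "m_imputations", "n_perm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.m_imputations < 2:
            raise ConfigError("m_imputations must be at least 2")
        if self.wtp_max <= 0 or self.wtp_step <= 0:
            raise ConfigError("WTP grid requires positive wtp_max and wtp_step")
        if self.discount_rate < 0 or self.incidence_per_year < 0:
            raise ConfigError("discount_rate and incidence_per_year must be non-negative")
        if self.trial is None:
            missing = [
                n
                for n in ("utilities_csv", "resources_csv", "survival_csv")
                if getattr(self, n) is None
            ]
            if missing:
                raise ConfigError(
                    "either an embedded trial config or all three input CSVs "
                    f"are required (missing: {', '.join(missing)})"
                )
            for n in ("utilities_csv", "resources_csv", "survival_csv"):
                p = getattr(self, n)
                if not Path(p).exists():
                    raise ConfigError(f"{n} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        trial_raw = raw.pop("trial", None)
        trial = None
        if trial_raw is not None:
            try:
                trial = TrialConfig(**trial_raw)
            except (TypeError, ValueError) as e:
                raise ConfigError(f"invalid trial config: {e}") from e
        try:
            return cls(trial=trial, **raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # where results land does not change what they are
        if self.trial is not None:
            d["trial"] = _jsonable(dataclasses.asdict(self.trial))
        return _jsonable(d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, date):
        return obj.isoformat()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_trial_csvs(utilities_csv, resources_csv, survival_csv) -> list[PatientRecord]:
    """Rebuild PatientRecords from the three on-disk tables."""
    ut = pd.read_csv(utilities_csv)
    rs = pd.read_csv(resources_csv).set_index("id")
    sv = pd.read_csv(survival_csv).set_index("id")
    required = {"id", "arm", "visit_month", "utility", "dropout_reason", "dropout_month"}
    if not required.issubset(ut.columns):
        raise DataError(f"utilities CSV missing columns: {sorted(required - set(ut.columns))}")
    patients = []
    for pid, grp in ut.groupby("id", sort=False):
        grp = grp.sort_values("visit_month")
        first = grp.iloc[0]
        d_month = first["dropout_month"]
        traj = UtilityTrajectory(
            grp["visit_month"].to_numpy(float),
            grp["utility"].to_numpy(float),
            dropout_reason=str(first["dropout_reason"]),
            dropout_time=None if pd.isna(d_month) else float(d_month),
        )
        if pid not in rs.index or pid not in sv.index:
            raise DataError(f"patient {pid!r} missing from resources or survival table")
        res_row = rs.loc[pid].drop(labels=["arm"], errors="ignore")
        srow = sv.loc[pid]
        patients.append(
            PatientRecord(
                id=str(pid),
                arm=str(first["arm"]),
                age=float(first["age"]),
                gender=str(first["gender"]),
                malnourished_at_inclusion=bool(first["malnourished_at_inclusion"]),
                tumor_site=str(first["tumor_site"]),
                tumor_stage=str(first["tumor_stage"]),
                handgrip=float(first["handgrip"]),
                phase_angle=float(first["phase_angle"]),
                utilities=traj,
                resources={k: float(v) for k, v in res_row.items()},
                survival_days=float(srow["time_days"]),
                event=bool(int(srow["event"])),
                accrual_date=date.fromisoformat(str(srow["accrual_date"])),
            )
        )
    return patients


def _stage(name: str, manifest: dict, t0: float):
    # elapsed time is logged but kept out of the manifest so reruns with
    # the same config produce bit-identical output trees
    manifest["stages"].append({"stage": name})
    logger.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full analysis and write all artifacts under config.outdir.

    Returns a result bundle with every intermediate object; the manifest
    records the config hash, seed, and per-stage timings.
    """
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "config": cfg.canonical(),
        "seed": cfg.seed,
        "stages": [],
    }
    bundle: dict[str, Any] = {"manifest": manifest}

    # ---- stage: data -------------------------------------------------
    t0 = time.perf_counter()
    if cfg.trial is not None:
        trial_cfg = cfg.trial.with_(seed=cfg.trial.seed if cfg.trial.seed else cfg.seed)
        patients = generate_trial(trial_cfg)
        write_trial_csvs(patients, trial_cfg, out / "trial")
        bundle["truth"] = true_values(trial_cfg)
        end_of_rt = trial_cfg.end_of_rt_month
        u_before = trial_cfg.dropout_utility_before_rt_end
        u_after = trial_cfg.dropout_utility_after_rt_end
    else:
        patients = load_trial_csvs(cfg.utilities_csv, cfg.resources_csv, cfg.survival_csv)
        end_of_rt, u_before, u_after = 2.0, 0.35, 0.30
    if not patients:
        raise DataError("no patients in input data")
    manifest["n_patients"] = len(patients)
    bundle["patients"] = patients
    _stage("data", manifest, t0)

    # ---- stage: QALYs ------------------------------------------------
    t0 = time.perf_counter()
    for p in patients:
        p.utilities = utilities_qaly.assign_dropout_utility(
            p.utilities, end_of_rt, u_before, u_after
        )
    imputations = utilities_qaly.impute_chained(
        patients, m=cfg.m_imputations, seed=cfg.seed
    )
    qaly_df = utilities_qaly.qaly_table(imputations, patients)
    qaly_df.to_csv(out / "qaly.csv", index=False)
    long_rows = []
    for p in patients:
        for t, v in zip(p.utilities.times, p.utilities.values):
            long_rows.append(
                {"id": p.id, "arm": p.arm, "visit_month": t, "utility": v}
            )
    lmm = utilities_qaly.fit_random_intercept_lmm(pd.DataFrame(long_rows))
    (out / "lmm.json").write_text(json.dumps(_jsonable(lmm), indent=2))
    bundle["qaly"] = qaly_df
    bundle["lmm"] = lmm
    _stage("qaly", manifest, t0)

    # ---- stage: costs ------------------------------------------------
    t0 = time.perf_counter()
    cost_table_cfg = costing.default_unit_cost_table(cfg.inflation_index)
    costs_df = costing.cost_dataframe(patients, cost_table_cfg)
    cost_cmp = costing.cost_table(costs_df, b_boot=cfg.b_bootstrap, seed=cfg.seed)
    costs_df.to_csv(out / "costs.csv", index=False)
    cost_cmp.to_csv(out / "cost_table.csv", index=False)
    bundle["costs"] = costs_df
    bundle["cost_table"] = cost_cmp
    _stage("costs", manifest, t0)

    # ---- stage: bootstrap CEA ---------------------------------------
    t0 = time.perf_counter()
    merged = qaly_df.merge(costs_df[["id", "total"]], on="id")
    dist = cea.bootstrap_pairs(
        merged["total"], merged["qaly"], merged["arm"], B=cfg.b_bootstrap, seed=cfg.seed
    )
    grid = cea.WTPGrid(np.arange(0.0, cfg.wtp_max + cfg.wtp_step, cfg.wtp_step))
    ceac_df = cea.ceac(dist, grid)
    eib_rows = [cea.eib(dist, k) for k in grid.thresholds]
    evpi_rows = [{"wtp": k, "evpi": cea.evpi(dist, k)} for k in grid.thresholds]
    point = cea.icer(*dist.point_estimate)
    k_ref = cfg.wtp_reference
    evpi_pp = cea.evpi(dist, k_ref)
    voi = {
        "point_icer": point,
        "ceac_at_reference": float(
            np.interp(k_ref, ceac_df["wtp"], ceac_df["probability"])
        ),
        "eib_at_reference": cea.eib(dist, k_ref),
        "evpi_per_patient": evpi_pp,
        "population_evpi": cea.population_evpi(
            evpi_pp, cfg.incidence_per_year, cfg.evpi_horizon_years, cfg.discount_rate
        ),
        "wtp_reference": k_ref,
    }
    dist.to_frame().to_csv(out / "cep_pairs.csv", index=False)
    ceac_df.to_csv(out / "ceac.csv", index=False)
    pd.DataFrame(eib_rows).merge(pd.DataFrame(evpi_rows), on="wtp").to_csv(
        out / "eib_evpi.csv", index=False
    )
    (out / "voi.json").write_text(json.dumps(_jsonable(voi), indent=2))
    bundle["bootstrap"] = dist
    bundle["ceac"] = ceac_df
    bundle["voi"] = voi
    _stage("cea", manifest, t0)

    # ---- stage: PSA --------------------------------------------------
    t0 = time.perf_counter()
    cost_fits, qaly_fits, fit_rows = {}, {}, []
    for arm in ("treatment", "control"):
        arm_costs = merged.loc[merged["arm"] == arm, "total"].to_numpy()
        arm_qalys = merged.loc[merged["arm"] == arm, "qaly"].to_numpy()
        cost_fits[arm] = psa.fit_cost_distribution(arm_costs)
        comp = psa.transform_qaly_complement(arm_qalys)
        best, all_fits = psa.fit_best_distribution(comp)
        qaly_fits[arm] = best
        for f in all_fits:
            fit_rows.append(
                {"arm": arm, "quantity": "qaly_complement", "family": f.family,
                 "aic": f.aic, "selected": f.family == best.family,
                 "parameters": json.dumps(f.parameters)}
            )
        pf = cost_fits[arm].positive
        fit_rows.append(
            {"arm": arm, "quantity": "cost_positive", "family": pf.family,
             "aic": pf.aic, "selected": True, "parameters": json.dumps(pf.parameters)}
        )
    psa_dist = psa.sample_psa(
        cost_fits, qaly_fits, dist.point_estimate, N=cfg.n_psa, seed=cfg.seed
    )
    psa_evpi = cea.evpi(psa_dist, k_ref)
    psa_summary = {
        "icer": cea.icer(float(psa_dist.delta_cost.mean()), float(psa_dist.delta_effect.mean())),
        "ceac_at_reference": float(
            np.interp(k_ref, *cea.ceac(psa_dist, grid).to_numpy().T)
        ),
        "eib_at_reference": cea.eib(psa_dist, k_ref),
        "evpi_per_patient": psa_evpi,
    }
    pd.DataFrame(fit_rows).to_csv(out / "psa_fits.csv", index=False)
    psa_dist.to_frame().to_csv(out / "psa_pairs.csv", index=False)
    (out / "psa_summary.json").write_text(json.dumps(_jsonable(psa_summary), indent=2))
    bundle["psa"] = psa_dist
    bundle["psa_summary"] = psa_summary
    _stage("psa", manifest, t0)

    # ---- stage: survival --------------------------------------------
    t0 = time.perf_counter()
    sv = pd.DataFrame(
        {
            "arm": [p.arm for p in patients],
            "time_days": [p.survival_days for p in patients],
            "event": [int(p.event) for p in patients],
        }
    )
    curves = {
        arm: survival.km_fit(
            sv.loc[sv["arm"] == arm, "time_days"], sv.loc[sv["arm"] == arm, "event"]
        )
        for arm in ("treatment", "control")
    }
    revkm = survival.reverse_km_median(sv["time_days"], sv["event"])
    delta_cost = dist.point_estimate[0]
    max_tau = int(
        min(curves[a].max_time for a in curves) // DAYS_PER_YEAR
    )
    taus = tuple(t for t in cfg.survival_taus_years if t <= max_tau)
    if len(taus) < len(cfg.survival_taus_years):
        logger.warning("follow-up supports horizons only up to %d years", max_tau)
    lyg_table = survival.discounted_lyg_icer(
        curves["treatment"], curves["control"], delta_cost, taus, cfg.discount_rate
    )
    tests = {
        "weighted_logrank": [
            dataclasses.asdict(
                survival.weighted_logrank(sv["time_days"], sv["event"], sv["arm"], p, q)
            )
            for (p, q) in ((0, 0), (1, 0), (0, 2))
        ],
        "maxcombo": survival.maxcombo(
            sv["time_days"], sv["event"], sv["arm"], n_perm=cfg.n_perm, seed=cfg.seed
        ),
        "reverse_km_median": {k: v for k, v in revkm.items() if k != "curve"},
    }
    for arm, curve in curves.items():
        pd.DataFrame(
            {
                "time_days": curve.event_times,
                "survival": curve.survival,
                "at_risk": curve.at_risk,
                "greenwood_var": curve.greenwood_var,
            }
        ).to_csv(out / f"km_{arm}.csv", index=False)
    lyg_table.to_csv(out / "lyg_icer_by_year.csv", index=False)
    (out / "survival_tests.json").write_text(json.dumps(_jsonable(tests), indent=2))
    bundle["curves"] = curves
    bundle["lyg_table"] = lyg_table
    bundle["survival_tests"] = tests
    _stage("survival", manifest, t0)

    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return bundle
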