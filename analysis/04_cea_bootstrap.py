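"""Bootstrap cost-effectiveness and value-of-information analysis.

Pairs each patient's total cost with their pooled QALY, bootstraps the
incremental means (1000 stratified resamples), and derives the ICER with
its quadrant, the acceptability curve over WTP 0-50,000 €/QALY, the
expected incremental benefit, the per-patient EVPI at €30,000/QALY and
the population EVPI (5,580 patients/yr, 10 years, 3.5% discount).

Reads results/analysis/{qaly.csv,costs.csv}; writes cep_pairs.csv,
ceac.csv, eib_evpi.csv and voi.json under results/analysis/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from nutricea import cea

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20120701
OUT = Path("results/analysis")
K_REF = 30_000.0

qaly = pd.read_csv(OUT / "qaly.csv")
costs = pd.read_csv(OUT / "costs.csv")
merged = qaly.merge(costs[["id", "total"]], on="id")

dist = cea.bootstrap_pairs(merged["total"], merged["qaly"], merged["arm"], B=1000, seed=SEED)
grid = cea.WTPGrid()
ceac_df = cea.ceac(dist, grid)
eib_rows = pd.DataFrame([cea.eib(dist, k) for k in grid.thresholds])
eib_rows["evpi"] = [cea.evpi(dist, k) for k in grid.thresholds]

point = cea.icer(*dist.point_estimate)
evpi_pp = cea.evpi(dist, K_REF)
voi = {
    "point_icer": point,
    "ceac_at_30000": float(np.interp(K_REF, ceac_df["wtp"], ceac_df["probability"])),
    "eib_at_30000": cea.eib(dist, K_REF),
    "evpi_per_patient": evpi_pp,
    "population_evpi": cea.population_evpi(evpi_pp, 5580.0, 10, 0.035),
}

dist.to_frame().to_csv(OUT / "cep_pairs.csv", index=False)
ceac_df.to_csv(OUT / "ceac.csv", index=False)
eib_rows.to_csv(OUT / "eib_evpi.csv", index=False)
(OUT / "voi.json").write_text(json.dumps(voi, indent=2, default=float))

print(f"point estimate: dC = {point['delta_cost']:.2f} EUR, dE = {point['delta_effect']:.4f} QALY")
print(f"ICER = {point['icer']:.0f} EUR/QALY ({point['label']})")
print(f"P(cost-effective at 30,000 EUR/QALY) = {voi['ceac_at_30000']:.1%}")
print(f"EIB at 30,000 = {voi['eib_at_30000']['eib']:.2f} EUR")
print(f"EVPI = {evpi_pp:.2f} EUR/patient; population EVPI = {voi['population_evpi'] / 1e6:.2f} M EUR")
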