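"""Out-of-sample forecast comparison: constant VAR vs TVP-VAR.

Trains both models on each site's 2007-2017 normalized panel, forecasts the
2018-2019 EVI, and tabulates RMSEs and the accuracy-improvement percentage
(station-table layout). At the typhoon-affected site the comparison is
repeated year by year. Also recomputes the arithmetic of the published
forecast tables as a desk check. Writes results/forecast_by_station.csv and
results/forecast_by_year.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import ORDERING, RESULTS, STATIONS, make_station_panel

import vegelag as vg
from vegelag.published import FORECAST_RMSE_BY_STATION
from vegelag.tvp import McmcConfig

SEED = 20235
ITERATIONS, BURN_IN = 2000, 500


def main() -> None:
    rows = []
    for i, station in enumerate(STATIONS):
        panel, _ = make_station_panel(station, seed=SEED + 10 * i)
        normalized, _ = vg.minmax_normalize(panel)
        p = vg.select_lag_order(normalized, p_max=3).chosen
        ev = vg.compare_models(normalized, split="2018-01-01", p=p, ordering=ORDERING,
                               mcmc=McmcConfig(ITERATIONS, BURN_IN, seed=SEED + i))
        rows.append({"unit": station, "rmse_var": ev.rmse_var,
                     "rmse_tvp": ev.rmse_tvp, "improvement_pct": ev.improvement})
        print(f"{station}: RMSE VAR {ev.rmse_var:.4f} TVP {ev.rmse_tvp:.4f} "
              f"improvement {ev.improvement:+.1f}%")
        if station == "DHF":
            by_year = ev.per_year
    frame = pd.DataFrame(rows)
    mean_row = {"unit": "average",
                "rmse_var": frame.rmse_var.mean(), "rmse_tvp": frame.rmse_tvp.mean(),
                "improvement_pct": frame.improvement_pct.mean()}
    frame = pd.concat([frame, pd.DataFrame([mean_row])], ignore_index=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    frame.to_csv(RESULTS / "forecast_by_station.csv", index=False)
    per_site = frame.iloc[:-1]["improvement_pct"]
    print(f"improvement across sites: mean {mean_row['improvement_pct']:+.1f}%, "
          f"median {per_site.median():+.1f}%")
    print("note: these synthetic panels are dominated by deterministic seasonality,")
    print("which both models must carry through near-unit-root lag dynamics; the")
    print("end-point parameters of the time-varying model compound small errors over")
    print("the 24-month horizon, so per-site improvements are noisy (see methods note).")

    by_year.to_csv(RESULTS / "forecast_by_year.csv", index=False)
    print("\nDHF-like site, year by year:")
    print(by_year.round(4).to_string(index=False))

    # desk check: published station table arithmetic
    recomputed = [vg.improvement_pct(r["var"], r["tvp"])
                  for r in FORECAST_RMSE_BY_STATION.values()]
    printed = [r["improvement_pct"] for r in FORECAST_RMSE_BY_STATION.values()]
    gap = np.abs(np.array(recomputed) - np.array(printed)).max()
    print(f"\npublished station table: max |recomputed - printed| improvement "
          f"= {gap:.2f} points; mean printed improvement {np.mean(printed):.2f}%")
    print(f"wrote {RESULTS / 'forecast_by_station.csv'} and {RESULTS / 'forecast_by_year.csv'}")


if __name__ == "__main__":
    main()
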