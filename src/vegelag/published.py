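"""Published station-level summary values from the subtropical forest EVI study.

These are *inputs*, not results of this package: the per-station variable
ranges that the synthetic generator emulates, the per-station lag-effect
rows, and the per-station / per-year forecast RMSEs of the constant-parameter
VAR and the TVP-VAR. Derived quantities (row sums, improvement percentages,
column averages) are always recomputed by the analysis functions, never
stored here.

Units: PRE mm (monthly total), TEM degC, RHU %, PAR mol/m^2, EVI unitless.
"""

from __future__ import annotations

# Per-station observed monthly ranges (min, max) of the climate record.
STATION_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "SNF": {"PRE": (2.3, 536.6), "TEM": (-9.6, 28.0), "RHU": (71.3, 91.8), "PAR": (185.1, 1431.3)},
    "GGF": {"PRE": (5.2, 490.1), "TEM": (-7.9, 19.8), "RHU": (81.4, 97.0), "PAR": (214.1, 898.1)},
    "HTF": {"PRE": (0.0, 418.7), "TEM": (-1.8, 33.3), "RHU": (69.8, 95.3), "PAR": (138.6, 1260.2)},
    "ALF": {"PRE": (0.0, 540.9), "TEM": (3.8, 16.6), "RHU": (63.3, 96.5), "PAR": (354.0, 1259.7)},
    "DHF": {"PRE": (0.0, 547.8), "TEM": (9.2, 35.3), "RHU": (62.9, 90.0), "PAR": (261.1, 1186.9)},
    "HSF": {"PRE": (0.0, 563.5), "TEM": (9.6, 36.6), "RHU": (56.7, 98.1), "PAR": (87.1, 1290.9)},
}

#: Years of monthly record per station (SNF starts 2009, the rest 2007).
STATION_SPAN_MONTHS: dict[str, int] = {
    "SNF": 132, "GGF": 156, "HTF": 156, "ALF": 156, "DHF": 156, "HSF": 156,
}

# Per-period lag effects of each climate factor on EVI (lag periods 1..6)
# and the printed lag-accumulation value, per station.
LAG_EFFECTS: dict[str, dict[str, dict[str, object]]] = {
    "PAR": {
        "SNF": {"effects": (0.04, 0.01, -0.03, 0.01, 0.00, 0.00), "accumulation": 0.02},
        "GGF": {"effects": (-0.01, 0.05, 0.00, 0.00, 0.00, -0.01), "accumulation": 0.04},
        "HTF": {"effects": (0.04, -0.01, 0.00, 0.00, 0.00, 0.00), "accumulation": 0.03},
        "ALF": {"effects": (0.03, -0.01, 0.00, 0.03, 0.00, 0.01), "accumulation": 0.05},
        "DHF": {"effects": (-0.08, 0.09, 0.00, 0.02, 0.01, 0.00), "accumulation": 0.04},
        "HSF": {"effects": (-0.02, 0.05, 0.03, 0.01, 0.01, 0.00), "accumulation": 0.09},
    },
    "PRE": {
        "SNF": {"effects": (0.03, -0.01, -0.01, 0.00, 0.00, 0.00), "accumulation": 0.02},
        "GGF": {"effects": (0.01, 0.01, 0.00, 0.00, 0.00, 0.00), "accumulation": 0.02},
        "HTF": {"effects": (0.07, -0.02, -0.01, 0.00, 0.00, 0.00), "accumulation": 0.05},
        "ALF": {"effects": (0.04, -0.10, -0.04, 0.02, 0.01, 0.00), "accumulation": -0.07},
        "DHF": {"effects": (0.03, -0.08, -0.01, -0.02, -0.01, 0.00), "accumulation": -0.09},
        "HSF": {"effects": (0.03, -0.03, -0.03, 0.00, 0.00, 0.00), "accumulation": -0.03},
    },
    "RHU": {
        "SNF": {"effects": (0.36, 0.11, -0.04, -0.16, 0.04, 0.01), "accumulation": 0.32},
        "GGF": {"effects": (0.39, 0.00, -0.03, -0.08, 0.01, 0.00), "accumulation": 0.29},
        "HTF": {"effects": (0.13, 0.04, -0.06, 0.01, 0.00, 0.00), "accumulation": 0.12},
        "ALF": {"effects": (-0.07, -0.03, 0.00, 0.04, 0.00, 0.00), "accumulation": -0.07},
        "DHF": {"effects": (-0.34, 0.08, -0.03, 0.17, 0.09, 0.01), "accumulation": -0.02},
        "HSF": {"effects": (0.39, -0.06, -0.12, 0.02, 0.00, 0.00), "accumulation": 0.16},
    },
    "TEM": {
        "SNF": {"effects": (0.13, 0.07, -0.02, -0.04, -0.02, 0.01), "accumulation": 0.13},
        "GGF": {"effects": (0.06, 0.13, 0.06, -0.21, 0.01, 0.00), "accumulation": 0.05},
        "HTF": {"effects": (0.17, 0.00, 0.03, -0.03, 0.00, 0.00), "accumulation": 0.16},
        "ALF": {"effects": (-0.20, 0.05, 0.05, 0.02, 0.01, 0.00), "accumulation": -0.07},
        "DHF": {"effects": (-0.02, -0.01, 0.07, -0.09, -0.04, 0.00), "accumulation": -0.10},
        "HSF": {"effects": (-0.12, 0.14, 0.07, -0.05, 0.00, 0.00), "accumulation": 0.03},
    },
}

# Forecast RMSE of the EVI (normalized scale) on the 2018-2019 test span,
# per station, for the constant-parameter VAR and the TVP-VAR, with the
# printed accuracy-improvement percentage.
FORECAST_RMSE_BY_STATION: dict[str, dict[str, float]] = {
    "SNF": {"var": 0.05631, "tvp": 0.04556, "improvement_pct": 19.09},
    "GGF": {"var": 0.05219, "tvp": 0.04635, "improvement_pct": 11.19},
    "HTF": {"var": 0.05366, "tvp": 0.04813, "improvement_pct": 10.31},
    "ALF": {"var": 0.05903, "tvp": 0.05145, "improvement_pct": 12.84},
    "DHF": {"var": 0.06516, "tvp": 0.04926, "improvement_pct": 24.40},
    "HSF": {"var": 0.05055, "tvp": 0.04486, "improvement_pct": 11.06},
}

#: Printed station-average row of the forecast comparison.
FORECAST_RMSE_AVERAGE_ROW = {"var": 0.05615, "tvp": 0.04760, "improvement_pct": 14.81}

# Year-by-year forecast comparison at the typhoon-affected station (DHF).
FORECAST_RMSE_BY_YEAR: dict[int, dict[str, float]] = {
    2017: {"var": 0.05952, "tvp": 0.05033, "improvement_pct": 15.44},
    2018: {"var": 0.08223, "tvp": 0.07405, "improvement_pct": 9.94},
    2019: {"var": 0.06516, "tvp": 0.04926, "improvement_pct": 24.40},
}

#: Printed average row of the year-by-year comparison.
FORECAST_RMSE_BY_YEAR_AVERAGE_ROW = {"var": 0.06900, "tvp": 0.05788, "improvement_pct": 16.11}

#: Identification ordering of the climate block, EVI last.
DEFAULT_ORDERING: tuple[str, ...] = ("TEM", "RHU", "PRE", "PAR", "EVI")

#: Per-station VAR lag orders used in the study (ALF, DHF, GGF, HSF, HTF, SNF).
STATION_LAG_ORDER: dict[str, int] = {
    "ALF": 3, "DHF": 4, "GGF": 4, "HSF": 2, "HTF": 3, "SNF": 3,
}
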