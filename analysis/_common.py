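"""Shared helpers for the numbered analysis scripts."""

from __future__ import annotations

from pathlib import Path

import vegelag as vg
from vegelag.pipeline import _default_synthetic_dynamics

RESULTS = Path(__file__).resolve().parent.parent / "results"
STATIONS = ("SNF", "GGF", "HTF", "ALF", "DHF", "HSF")
ORDERING = ("TEM", "RHU", "PRE", "PAR", "EVI")

#: Typhoon-like event injected at the southern coastal site.
SHOCK_MONTH = "2018-09-01"
SHOCK_SITE = "DHF"


def make_station_panel(station: str, seed: int, T: int | None = None):
    """Station-like synthetic panel (13 years monthly; 11 for SNF) with the
    documented drifting dynamics, plus the typhoon shock at DHF."""
    from vegelag.published import STATION_SPAN_MONTHS

    T = T or STATION_SPAN_MONTHS[station]
    start = "2009-01" if station == "SNF" else "2007-01"
    seasonal = vg.station_seasonal_specs(station)
    dynamics = _default_synthetic_dynamics(len(seasonal), seed)
    truth = vg.generate_panel(seasonal, dynamics, T=T, seed=seed + 1,
                              start=start, site=station)
    panel = truth.panel
    if station == SHOCK_SITE:
        panel = vg.inject_shock(panel, SHOCK_MONTH, {"EVI": -0.15},
                                ranges={"EVI": (-1.0, 1.0)})
    return panel, truth
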