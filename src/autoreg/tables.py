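"""Packaged dose-response reference table.

Ships the across-animal mean +/- SD envelope of MAP and the three tissue
oxygenation indices (TOIs) over the five infusion doses of every
condition x drug arm, taken from a published swine experiment.  It is the
worked-example input for the MAP-vs-TOI regressions and percent-change
statistics, and supplies the simulator's default MAP targets.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .protocol import TOI_COLUMNS

MAP_VARIABLE = "map_mmHg"


@lru_cache(maxsize=1)
def load_dose_response_table() -> pd.DataFrame:
    """Tidy table with columns condition, drug, dose_ug_kg_min, variable, mean, sd, n_animals."""
    ref = resources.files("autoreg.resources").joinpath("dose_response_means.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    return df


def map_toi_points(condition: str, drug: str, site: str) -> tuple[np.ndarray, np.ndarray]:
    """The five (mean MAP, mean TOI) dose points for one arm and site.

    These are the points the dose-response regression is fit on: one across-animal
    mean per dose, MAP on the abscissa.
    """
    df = load_dose_response_table()
    arm = df[(df.condition == condition) & (df.drug == drug)]
    if arm.empty:
        raise KeyError(f"no arm ({condition!r}, {drug!r}) in the reference table")
    toi_var = TOI_COLUMNS[site]
    x = arm[arm.variable == MAP_VARIABLE].sort_values("dose_ug_kg_min")
    y = arm[arm.variable == toi_var].sort_values("dose_ug_kg_min")
    return x["mean"].to_numpy(float), y["mean"].to_numpy(float)


def mean_value(condition: str, drug: str, dose: float, variable: str) -> float:
    """Single across-animal mean (e.g. TOI at the pre-infusion dose 0)."""
    df = load_dose_response_table()
    row = df[
        (df.condition == condition)
        & (df.drug == drug)
        & (df.dose_ug_kg_min == dose)
        & (df.variable == variable)
    ]
    if len(row) != 1:
        raise KeyError(f"no unique entry for {(condition, drug, dose, variable)}")
    return float(row["mean"].iloc[0])


def default_map_targets() -> dict[tuple[str, str, float], float]:
    """Mean MAP per (condition, drug, dose) — the simulator's default targets."""
    df = load_dose_response_table()
    sub = df[df.variable == MAP_VARIABLE]
    return {
        (r.condition, r.drug, float(r.dose_ug_kg_min)): float(r.mean)
        for r in sub.itertuples()
    }
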