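"""Dose-response aggregation: across-animal summaries, percent changes,
MAP-vs-TOI regressions, and between-condition shifts.

Each animal contributes its window mean to a (condition, drug, dose, variable)
cell; cells are summarized as mean +/- sample SD across animals.  The
MAP-vs-TOI relationship of an arm is summarized by ordinary least squares on
the five per-dose (mean MAP, mean TOI) points — a linear approximation of the
autoregulation curve over the MAP range the drug actually spans, not a model
of the full Lassen curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .data import DoseWindow
from .protocol import TOI_COLUMNS


class DegenerateFitError(ValueError):
    """Regression input with no x spread (or too few points)."""


class ExtrapolationError(ValueError):
    """Evaluation point outside a fit's observed MAP range."""


@dataclass(frozen=True)
class DoseSummary:
    condition: str
    drug: str
    dose: float
    variable: str
    mean: float
    sd: float  # NaN when only one animal contributes
    n_animals: int


@dataclass(frozen=True)
class PercentChange:
    """Relative change from a reference value, on the percent scale.

    ``pct`` is 100 * (reference - comparator) / reference, so a positive value
    is a decrease from reference.  ``rounded_pct`` rounds half away from zero,
    the convention under which the reference envelope's printed integers are
    all reproduced.
    """

    reference: float
    comparator: float

    def __post_init__(self) -> None:
        if self.reference <= 0:
            raise ValueError("reference must be positive")

    @property
    def pct(self) -> float:
        return 100.0 * (self.reference - self.comparator) / self.reference

    @property
    def direction(self) -> str:
        return "decrease" if self.pct > 0 else "increase"

    @property
    def rounded_pct(self) -> int:
        p = self.pct
        return int(math.copysign(math.floor(abs(p) + 0.5), p))


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    x_range: tuple[float, float]

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class ConditionShift:
    """Vertical offset between two arms' fitted lines at a common MAP."""

    map_eval: float
    delta_toi: float
    delta_pct: float


def window_means(
    windows: Iterable[DoseWindow], discard_fraction: float = 0.0
) -> pd.DataFrame:
    """Per-window mean MAP and TOI: the per-animal values entering summaries.

    Output is long-format with a ``variable`` column (``map_mmHg`` or the
    site's TOI column name) so MAP and TOI cells summarize identically.
    NaN TOI samples are excluded from the window mean.

    ``discard_fraction`` drops that leading fraction of each window before
    averaging — use it to exclude the transition after a dose change and
    summarize the steady-state level (published per-dose hemodynamic values
    are steady-state readings, not transition-inclusive averages).
    """
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")
    rows = []
    seen_map = set()
    for w in windows:
        k = int(round(discard_fraction * w.n))
        key = (w.animal_id, w.condition, w.drug, w.dose)
        if key not in seen_map:  # MAP is shared across sites; emit once
            seen_map.add(key)
            rows.append((*key, "map_mmHg", float(np.nanmean(w.map_values[k:]))))
        rows.append((*key, TOI_COLUMNS[w.site], float(np.nanmean(w.toi_values[k:]))))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "condition", "drug", "dose_ug_kg_min", "variable", "value"],
    )


def summarize_dose(means: pd.DataFrame) -> pd.DataFrame:
    """Across-animal mean and sample SD (n-1) per condition x drug x dose x variable.

    ``means`` is the output of :func:`window_means`.  Single-animal cells get
    ``sd = NaN`` (flagged undefined rather than zero).
    """
    out = []
    for key, sub in means.groupby(
        ["condition", "drug", "dose_ug_kg_min", "variable"], sort=False
    ):
        v = sub["value"].to_numpy(float)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
        out.append((*key, float(np.mean(v)), sd, len(v)))
    return pd.DataFrame(
        out,
        columns=["condition", "drug", "dose_ug_kg_min", "variable", "mean", "sd", "n_animals"],
    )


def percent_change(reference: float, comparator: float) -> PercentChange:
    """Percent change of ``comparator`` relative to ``reference`` (> 0 = decrease)."""
    return PercentChange(reference=float(reference), comparator=float(comparator))


def fit_map_toi_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionFit:
    """OLS of TOI on MAP over the per-dose mean points of one arm."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise DegenerateFitError("need at least 2 points")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all MAP values identical: slope undefined")
    res = linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
        x_range=(float(x.min()), float(x.max())),
    )


def condition_shift(
    fit_a: RegressionFit,
    fit_b: RegressionFit,
    map_eval: float,
    allow_extrapolation: bool = False,
) -> ConditionShift:
    """Vertical shift of fit_b relative to fit_a at a common MAP.

    Quantifies how a volume intervention (e.g. the 600-ml bleed) displaces the
    MAP-TOI relationship: ``delta_toi`` in TOI points, ``delta_pct`` as a
    percentage of the reference arm's prediction.
    """
    for fit in (fit_a, fit_b):
        lo, hi = fit.x_range
        if not (lo <= map_eval <= hi) and not allow_extrapolation:
            raise ExtrapolationError(
                f"MAP {map_eval} outside fitted range [{lo}, {hi}] "
                "(pass allow_extrapolation=True to override)"
            )
    a = fit_a.predict(map_eval)
    b = fit_b.predict(map_eval)
    return ConditionShift(
        map_eval=float(map_eval),
        delta_toi=float(b - a),
        delta_pct=float(100.0 * (b - a) / a),
    )
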