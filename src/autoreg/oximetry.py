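"""Oximetry indices and response-state classification.

The oximetry index of a dose window is the Spearman rank correlation between
MAP and a site's TOI over the window's paired samples: COx for the cerebral
site, T-SOx and L-SOx for the thoracic and lumbar spinal cord.  Intact
autoregulation holds tissue oxygenation flat as pressure moves, so the index
sits near zero; a pressure-passive bed tracks pressure (index toward +1); a
paradoxical response moves oxygenation against pressure (index toward -1),
the arteriolar-caliber signature of active flow regulation.

Classification uses the 0.36 threshold: index > 0.36 is pressure-passive,
index < -0.36 is paradoxical, anything in [-0.36, 0.36] is intact.  The
boundary values belong to intact (the defining inequalities for the outer
states are strict).  A window whose MAP or TOI has zero variance — or fewer
than three complete pairs — has no computable rank correlation and is
classified ``undefined``, kept separate from the three physiological states
rather than coerced to zero.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import DoseWindow

#: Classification threshold on the oximetry index.
DEFAULT_THRESHOLD = 0.36

INDEX_COLUMNS = ["animal_id", "condition", "drug", "dose_ug_kg_min", "site", "n", "rho", "state"]


class ResponseState(str, enum.Enum):
    PRESSURE_PASSIVE = "pressure_passive"
    INTACT = "intact"
    PARADOXICAL = "paradoxical"
    UNDEFINED = "undefined"

    def __str__(self) -> str:  # plain value in CSV/logs
        return self.value


@dataclass(frozen=True)
class OximetryIndex:
    """Windowed oximetry index with its classification."""

    animal_id: str
    condition: str
    drug: str
    dose: float
    site: str
    rho: float  # NaN when incomputable
    n: int
    state: ResponseState


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average (mid-) ranks.  Returns NaN — the undefined marker —
    when either vector has zero variance or fewer than 3 pairs remain after
    dropping incomplete pairs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.clip(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)), -1.0, 1.0))


def classify_response(rho: float, threshold: float = DEFAULT_THRESHOLD) -> ResponseState:
    """Three-state classification of an oximetry index (NaN -> undefined)."""
    if rho is None or (isinstance(rho, float) and math.isnan(rho)):
        return ResponseState.UNDEFINED
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation {rho} outside [-1, 1]")
    if rho > threshold:
        return ResponseState.PRESSURE_PASSIVE
    if rho < -threshold:
        return ResponseState.PARADOXICAL
    return ResponseState.INTACT


def compute_oximetry_index(
    window: DoseWindow, threshold: float = DEFAULT_THRESHOLD
) -> OximetryIndex:
    """Index one dose window; incomplete pairs are excluded from n."""
    x = np.asarray(window.map_values, float)
    y = np.asarray(window.toi_values, float)
    n = int((~(np.isnan(x) | np.isnan(y))).sum())
    rho = spearman_rho(x, y)
    return OximetryIndex(
        animal_id=window.animal_id,
        condition=window.condition,
        drug=window.drug,
        dose=window.dose,
        site=window.site,
        rho=rho,
        n=n,
        state=classify_response(rho, threshold),
    )


def compute_indices(
    windows: Iterable[DoseWindow], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Index a collection of windows into a tidy frame (one row per window)."""
    rows = []
    for w in windows:
        ix = compute_oximetry_index(w, threshold)
        rows.append(
            (ix.animal_id, ix.condition, ix.drug, ix.dose, ix.site, ix.n, ix.rho, str(ix.state))
        )
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)


GROUPING = ["condition", "drug", "dose_ug_kg_min", "site"]


def count_response_patterns(
    indices: pd.DataFrame, by: Sequence[str] = GROUPING
) -> pd.DataFrame:
    """Response-pattern counts per group (passive/intact/paradoxical/undefined).

    Undefined windows are tallied in their own column, never folded into the
    three physiological states.
    """
    states = [s.value for s in ResponseState]
    out = []
    for key, sub in indices.groupby(list(by), sort=False):
        counts = sub["state"].value_counts()
        out.append((*key, *[int(counts.get(s, 0)) for s in states]))
    return pd.DataFrame(out, columns=[*by, *states])


def summarize_indices(
    indices: pd.DataFrame, by: Sequence[str] = GROUPING
) -> pd.DataFrame:
    """Median and range of the index per group, excluding undefined windows.

    Median of an even count is the midpoint of the two central values.  A
    group whose windows are all undefined yields NaN summaries with n = 0.
    """
    out = []
    for key, sub in indices.groupby(list(by), sort=False):
        rho = sub.loc[sub["state"] != ResponseState.UNDEFINED.value, "rho"].dropna()
        if len(rho):
            out.append((*key, float(rho.median()), float(rho.min()), float(rho.max()), len(rho)))
        else:
            out.append((*key, float("nan"), float("nan"), float("nan"), 0))
    return pd.DataFrame(out, columns=[*by, "median_rho", "min_rho", "max_rho", "n"])


@dataclass(frozen=True)
class ParadoxicalTally:
    """Paradoxical-response tallies for one site.

    A *stepwise infusion* is one condition x drug arm of one animal (five per
    animal under the full protocol); it counts as paradoxical when any of its
    dose windows is classified paradoxical.
    """

    site: str
    n_paradoxical_infusions: int
    n_infusions: int
    n_paradoxical_animals: int
    n_animals: int


def paradoxical_window_tally(indices: pd.DataFrame, site: str) -> ParadoxicalTally:
    """Tally paradoxical stepwise infusions and affected animals at one site."""
    sub = indices[indices["site"] == site]
    n_infusions = 0
    n_paradoxical = 0
    animals_hit: set[str] = set()
    for (animal, _cond, _drug), arm in sub.groupby(
        ["animal_id", "condition", "drug"], sort=False
    ):
        n_infusions += 1
        if (arm["state"] == ResponseState.PARADOXICAL.value).any():
            n_paradoxical += 1
            animals_hit.add(str(animal))
    n_animals = sub["animal_id"].nunique()
    return ParadoxicalTally(
        site=site,
        n_paradoxical_infusions=n_paradoxical,
        n_infusions=n_infusions,
        n_paradoxical_animals=len(animals_hit),
        n_animals=int(n_animals),
    )
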