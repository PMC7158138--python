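"""Recording data model, tidy-CSV I/O, validation, and dose-window extraction.

A recording is long-format: one row per timestamp carrying the shared MAP and
the TOI of every monitored site (MAP is common to all sites, so site-per-row
would duplicate it).  Time is relative to the start of the dose step
(0, 10, ..., 590 s for a conformant 10-min window).  Site presence is
an animal-level property: a site column that is entirely empty for an animal
means that site was not recorded (e.g. lost probe data); sporadic gaps within
a present site are flagged by validation rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .protocol import SITES, TOI_COLUMNS, ProtocolSpec, DEFAULT_PROTOCOL

logger = logging.getLogger(__name__)

#: Canonical recording-CSV columns, in order.
CSV_COLUMNS = [
    "animal_id",
    "condition",
    "drug",
    "dose_ug_kg_min",
    "t_s",
    "map_mmHg",
    "toi_cerebral_pct",
    "toi_thoracic_pct",
    "toi_lumbar_pct",
]

GROUP_KEYS = ["animal_id", "condition", "drug", "dose_ug_kg_min"]


class FormatError(ValueError):
    """Malformed recording file (header or cell contents)."""


class ValidationError(ValueError):
    """Recording violates the protocol (e.g. out-of-protocol dose)."""


class IntegrityError(ValueError):
    """Internally inconsistent dataset (e.g. unequal paired-vector lengths)."""


@dataclass
class SampleRecord:
    """One timestamped sample: shared MAP plus per-site TOIs (NaN = missing)."""

    animal_id: str
    condition: str
    drug: str
    dose: float
    t: float
    map: float
    toi_cerebral: float = np.nan
    toi_thoracic: float = np.nan
    toi_lumbar: float = np.nan


@dataclass
class ExperimentDataset:
    """Validated collection of recording rows.

    ``frame`` holds the canonical columns; ``sites_present`` maps each animal
    to the sites with any recorded TOI (all-or-nothing presence is a
    validation concern, not an ingestion one).
    """

    frame: pd.DataFrame
    sampling_interval: float = 10.0

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        self.frame = self.frame[CSV_COLUMNS].reset_index(drop=True)

    @property
    def sites_present(self) -> dict[str, frozenset[str]]:
        out: dict[str, frozenset[str]] = {}
        for animal, sub in self.frame.groupby("animal_id", sort=False):
            out[str(animal)] = frozenset(
                site for site, col in TOI_COLUMNS.items() if sub[col].notna().any()
            )
        return out

    @property
    def animals(self) -> list[str]:
        return list(dict.fromkeys(self.frame["animal_id"].astype(str)))

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_records(
        cls, records: Iterable[SampleRecord], sampling_interval: float = 10.0
    ) -> "ExperimentDataset":
        rows = [
            (
                r.animal_id,
                r.condition,
                r.drug,
                r.dose,
                r.t,
                r.map,
                r.toi_cerebral,
                r.toi_thoracic,
                r.toi_lumbar,
            )
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
        return cls(frame, sampling_interval=sampling_interval)


@dataclass(frozen=True)
class DoseWindow:
    """Paired MAP/TOI vectors for one animal x condition x drug x dose x site.

    ``conformant`` is False when the sample count differs from the protocol's
    expected samples-per-window; such windows are kept and flagged, never
    truncated or padded.
    """

    animal_id: str
    condition: str
    drug: str
    dose: float
    site: str
    map_values: np.ndarray
    toi_values: np.ndarray
    conformant: bool = True

    def __post_init__(self) -> None:
        if len(self.map_values) != len(self.toi_values):
            raise IntegrityError(
                f"window {self.key}: MAP length {len(self.map_values)} != "
                f"TOI length {len(self.toi_values)}"
            )

    @property
    def n(self) -> int:
        return len(self.map_values)

    @property
    def key(self) -> tuple:
        return (self.animal_id, self.condition, self.drug, self.dose, self.site)


@dataclass
class ValidationIssue:
    group: tuple
    kind: str
    detail: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    group_counts: pd.DataFrame | None = None

    @property
    def is_clean(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.is_clean:
            return "dataset conformant: no issues"
        lines = [f"{len(self.issues)} issue(s):"]
        lines += [f"  {i.group}: [{i.kind}] {i.detail}" for i in self.issues]
        return "\n".join(lines)


def read_timeseries_csv(
    path: str | Path, spec: ProtocolSpec = DEFAULT_PROTOCOL
) -> ExperimentDataset:
    """Read and validate a tidy recording CSV.

    Empty TOI cells become NaN (explicit missing).  Raises ``FormatError`` for
    header or cell-parsing problems (with the offending row), and
    ``ValidationError`` for values outside the protocol (doses, conditions,
    drugs, non-positive MAP, TOI outside (0, 100) is left to
    :func:`validate_dataset`).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"animal_id": str}, comment="#")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: header lacks required columns {missing}")

    for col in ["dose_ug_kg_min", "t_s", "map_mmHg", *TOI_COLUMNS.values()]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise FormatError(
                f"{path.name}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}"
            )
        df[col] = coerced

    bad_dose = ~df["dose_ug_kg_min"].isin(spec.dose_levels)
    if bad_dose.any():
        raise ValidationError(
            f"{path.name}: dose {df['dose_ug_kg_min'][bad_dose.idxmax()]} not in "
            f"protocol levels {list(spec.dose_levels)}"
        )
    bad_cond = ~df["condition"].isin(spec.conditions)
    if bad_cond.any():
        raise ValidationError(
            f"{path.name}: unknown condition {df['condition'][bad_cond.idxmax()]!r}"
        )
    for cond, sub in df.groupby("condition"):
        allowed = set(spec.drugs_per_condition[str(cond)])
        extra = set(sub["drug"].unique()) - allowed
        if extra:
            raise ValidationError(
                f"{path.name}: drug(s) {sorted(extra)} not in protocol for "
                f"condition {cond!r}"
            )
    if (df["map_mmHg"] <= 0).any():
        raise ValidationError(f"{path.name}: non-positive MAP value")
    if (df["t_s"] < 0).any():
        raise ValidationError(f"{path.name}: negative time value")

    return ExperimentDataset(df, sampling_interval=spec.sampling_interval)


def write_timeseries_csv(ds: ExperimentDataset, path: str | Path) -> None:
    """Write the canonical CSV; floats at full (round-trip) precision."""
    ds.frame.to_csv(path, index=False)


def validate_dataset(
    ds: ExperimentDataset, spec: ProtocolSpec = DEFAULT_PROTOCOL
) -> ValidationReport:
    """Report protocol-conformance findings without modifying the dataset.

    Checks per (animal, condition, drug, dose) group: sample count vs the
    protocol window, strictly increasing and equally spaced times, TOI range,
    and within-present-site missing samples.
    """
    report = ValidationReport()
    counts = []
    sites_present = ds.sites_present
    n_expected = spec.samples_per_window
    for key, sub in ds.frame.groupby(GROUP_KEYS, sort=False):
        key = tuple(key)
        counts.append((*key, len(sub)))
        if len(sub) != n_expected:
            report.issues.append(
                ValidationIssue(key, "short window" if len(sub) < n_expected else "long window",
                                f"{len(sub)} samples, expected {n_expected}")
            )
        t = sub["t_s"].to_numpy()
        if len(t) > 1:
            dt = np.diff(t)
            if (dt <= 0).any():
                report.issues.append(
                    ValidationIssue(key, "non-increasing time", "t_s not strictly increasing")
                )
            elif not np.allclose(dt, spec.sampling_interval, rtol=0, atol=1e-6):
                report.issues.append(
                    ValidationIssue(key, "irregular spacing",
                                    f"sampling deviates from {spec.sampling_interval} s")
                )
        for site, col in TOI_COLUMNS.items():
            animal = key[0]
            if site not in sites_present.get(str(animal), frozenset()):
                continue
            vals = sub[col]
            out = (vals <= 0) | (vals >= 100)
            if out.any():
                report.issues.append(
                    ValidationIssue(key, "TOI out of range",
                                    f"{col} value {vals[out].iloc[0]} outside (0, 100)")
                )
            if vals.isna().any():
                report.issues.append(
                    ValidationIssue(key, "missing TOI sample",
                                    f"{int(vals.isna().sum())} missing {col} cell(s) "
                                    "within a present site")
                )
    report.group_counts = pd.DataFrame(counts, columns=[*GROUP_KEYS, "n_samples"])
    return report


def extract_dose_windows(
    ds: ExperimentDataset, spec: ProtocolSpec = DEFAULT_PROTOCOL
) -> list[DoseWindow]:
    """One window per (animal, condition, drug, dose) group and present site.

    Pairs MAP with each site's TOI sample-by-sample; the windows partition the
    records (each record contributes to exactly one window per present site).
    Non-conformant sample counts are flagged via ``DoseWindow.conformant``.
    """
    windows: list[DoseWindow] = []
    sites_present = ds.sites_present
    n_expected = spec.samples_per_window
    for key, sub in ds.frame.groupby(GROUP_KEYS, sort=False):
        animal, condition, drug, dose = key
        present = sites_present.get(str(animal), frozenset())
        map_vals = sub["map_mmHg"].to_numpy(float)
        for site in SITES:
            if site not in present:
                continue
            toi_vals = sub[TOI_COLUMNS[site]].to_numpy(float)
            windows.append(
                DoseWindow(
                    animal_id=str(animal),
                    condition=str(condition),
                    drug=str(drug),
                    dose=float(dose),
                    site=site,
                    map_values=map_vals,
                    toi_values=toi_vals,
                    conformant=len(sub) == n_expected,
                )
            )
    if not windows and len(ds.frame):
        raise IntegrityError("records present but no windows extracted")
    return windows
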