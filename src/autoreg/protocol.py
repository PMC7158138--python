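"""Experimental protocol description.

The study design is a sequence of vasoactive-drug infusion arms: under each
volume condition (baseline, hypovolemia after a 600-ml bleed, and post-fluid
resuscitation) the animal receives stepwise infusions of phenylephrine
(vasoconstrictor, ramps MAP up) and/or sodium nitroprusside (SNP, vasodilator,
ramps MAP down) at 0, 0.5, 1, 2 and 5 ug/kg/min, each dose held for 10 min
while MAP and tissue oxygenation are sampled every 10 s.  SNP is omitted
during hypovolemia because vasodilation on top of a 25% blood-volume deficit
is not survivable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

CONDITIONS = ("baseline", "hypovolemia", "fluid_resuscitation")
DRUGS = ("phenylephrine", "SNP")
SITES = ("cerebral", "thoracic", "lumbar")

#: CSV column that carries each site's oxygenation index readout.
TOI_COLUMNS = {
    "cerebral": "toi_cerebral_pct",
    "thoracic": "toi_thoracic_pct",
    "lumbar": "toi_lumbar_pct",
}


class ProtocolError(ValueError):
    """Raised when a protocol description is internally inconsistent."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Structure of the infusion protocol.

    Parameters
    ----------
    conditions
        Ordered volume conditions.
    drugs_per_condition
        Drugs infused under each condition, in order.  Hypovolemia admits
        phenylephrine only.
    dose_levels
        Ordered infusion rates in ug/kg/min.  Doses are protocol labels and
        are matched exactly, never by tolerance.
    step_duration
        Seconds each dose is held (default 600 = 10 min).
    sampling_interval
        Seconds between paired MAP/TOI samples (default 10).
    """

    conditions: tuple[str, ...] = CONDITIONS
    drugs_per_condition: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "baseline": ("phenylephrine", "SNP"),
            "hypovolemia": ("phenylephrine",),
            "fluid_resuscitation": ("phenylephrine", "SNP"),
        }
    )
    dose_levels: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 5.0)
    step_duration: float = 600.0
    sampling_interval: float = 10.0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ProtocolError("protocol needs at least one condition")
        for cond in self.conditions:
            if cond not in self.drugs_per_condition:
                raise ProtocolError(f"no drugs listed for condition {cond!r}")
        if len(set(self.dose_levels)) != len(self.dose_levels):
            raise ProtocolError("duplicate dose levels")
        if self.step_duration <= 0 or self.sampling_interval <= 0:
            raise ProtocolError("durations must be positive")
        n = self.step_duration / self.sampling_interval
        if abs(n - round(n)) > 1e-9:
            raise ProtocolError(
                "step_duration must be an integer multiple of sampling_interval"
            )

    @property
    def samples_per_window(self) -> int:
        """Paired samples in one conformant dose window (60 by default)."""
        return round(self.step_duration / self.sampling_interval)

    def arms(self) -> list[tuple[str, str]]:
        """Ordered (condition, drug) infusion arms — five in the default design."""
        return [
            (cond, drug)
            for cond in self.conditions
            for drug in self.drugs_per_condition[cond]
        ]

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "drugs_per_condition": {
                c: list(d) for c, d in self.drugs_per_condition.items()
            },
            "dose_levels": list(self.dose_levels),
            "step_duration": self.step_duration,
            "sampling_interval": self.sampling_interval,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProtocolSpec":
        return cls(
            conditions=tuple(d["conditions"]),
            drugs_per_condition={
                c: tuple(v) for c, v in d["drugs_per_condition"].items()
            },
            dose_levels=tuple(float(x) for x in d["dose_levels"]),
            step_duration=float(d.get("step_duration", 600.0)),
            sampling_interval=float(d.get("sampling_interval", 10.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


#: The study protocol: three conditions, five arms, five dose steps of 10 min
#: sampled at 10 s (60 paired samples per window).
DEFAULT_PROTOCOL = ProtocolSpec()


def expected_window_count(
    spec: ProtocolSpec,
    n_animals: int,
    sites: Sequence[str] = SITES,
    missing: Mapping[str, Sequence[str]] | None = None,
) -> int:
    """Number of dose windows a full protocol run should yield.

    ``missing`` maps a site name to the animals lacking it (e.g. the animal
    whose lumbar recordings were lost).
    """
    missing = missing or {}
    n_cells = len(spec.arms()) * len(spec.dose_levels)
    total = 0
    for site in sites:
        total += (n_animals - len(missing.get(site, ()))) * n_cells
    return total
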