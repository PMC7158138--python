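"""Synthetic protocol-conformant MAP/TOI recordings with ground truth.

The generator emulates the stepwise-infusion study design: for each animal
and each condition x drug arm, MAP steps through per-dose target levels
(defaults are the packaged dose-response means), with a between-animal level
offset, a smooth ramp at each dose change, and AR(1) within-window
fluctuation.  Tissue oxygenation at each site follows a static Lassen-type
autoregulation curve — a plateau between lower and upper MAP limits with
pressure-passive slopes outside — evaluated at the window-mean MAP, shifted
additively by volume condition, plus a per-window *response regime* that sets
how TOI tracks within-window MAP excursions:

- ``intact``            slope ~ 0  (oxygenation decoupled from pressure)
- ``pressure_passive``  slope > 0  (oxygenation tracks pressure)
- ``paradoxical``       slope < 0  (oxygenation moves against pressure)

Regimes are drawn per window (the same animal can switch patterns across
doses), and every generated window carries its ground-truth label, enabling
end-to-end recovery tests of the oximetry classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data import CSV_COLUMNS, ExperimentDataset
from .protocol import SITES, TOI_COLUMNS, ProtocolSpec, DEFAULT_PROTOCOL
from .tables import default_map_targets

logger = logging.getLogger(__name__)

REGIMES = ("pressure_passive", "intact", "paradoxical")

#: Floor applied to simulated MAP; guards degenerate configs, logged when hit.
MAP_FLOOR = 20.0

TRUTH_COLUMNS = ["animal_id", "condition", "drug", "dose_ug_kg_min", "site", "regime", "slope"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class RegimeSpec:
    """Within-window TOI response: regime label, slope (TOI %/mmHg), noise."""

    regime: str
    slope: float
    noise_sd: float = 1.0
    ar_coefficient: float = 0.5
    intact_epsilon: float = 0.05  # |slope| tolerance for the intact regime

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ConfigError(f"unknown regime {self.regime!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ConfigError("ar_coefficient must be in [0, 1)")
        if self.regime == "intact" and abs(self.slope) > self.intact_epsilon:
            raise ConfigError("intact regime requires |slope| <= intact_epsilon")
        if self.regime == "pressure_passive" and self.slope <= 0:
            raise ConfigError("pressure_passive regime requires slope > 0")
        if self.regime == "paradoxical" and self.slope >= 0:
            raise ConfigError("paradoxical regime requires slope < 0")


@dataclass(frozen=True)
class SiteProfile:
    """Static autoregulation curve of one site.

    ``plateau_toi`` is the TOI on the autoregulatory plateau; below
    ``lower_limit_map`` and above ``upper_limit_map`` the curve slopes
    pressure-passively.  ``condition_offsets`` shift the whole curve per
    volume condition (hypovolemia shifts down by a few TOI points, under 5%
    of plateau; resuscitation restores volume but hemodilution keeps the
    curve near the hypovolemic level).
    """

    site: str
    plateau_toi: float
    lower_limit_map: float = 65.0
    upper_limit_map: float = 110.0
    below_limit_slope: float = 0.2
    above_limit_slope: float = 0.05
    condition_offsets: Mapping[str, float] = field(
        default_factory=lambda: {
            "baseline": 0.0,
            "hypovolemia": -2.5,
            "fluid_resuscitation": -2.0,
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.plateau_toi < 100:
            raise ConfigError("plateau_toi must be in (0, 100)")
        if self.lower_limit_map >= self.upper_limit_map:
            raise ConfigError("lower_limit_map must be < upper_limit_map")

    def base_curve(self, map_value: float) -> float:
        """Piecewise-linear Lassen-type curve at a given MAP."""
        if map_value < self.lower_limit_map:
            return self.plateau_toi - self.below_limit_slope * (
                self.lower_limit_map - map_value
            )
        if map_value > self.upper_limit_map:
            return self.plateau_toi + self.above_limit_slope * (
                map_value - self.upper_limit_map
            )
        return self.plateau_toi


def default_site_profiles() -> dict[str, SiteProfile]:
    """Cerebral plateau highest and most robust; spinal sites lower and more
    pressure-dependent (thoracic lowest), matching the reference envelope's
    site ordering cerebral > lumbar > thoracic at every dose."""
    return {
        "cerebral": SiteProfile("cerebral", 65.0, lower_limit_map=45.0,
                                below_limit_slope=0.3, above_limit_slope=0.0),
        "thoracic": SiteProfile("thoracic", 48.0),
        "lumbar": SiteProfile("lumbar", 53.0),
    }


def default_regime_probabilities() -> dict[tuple[str, str], dict[str, float]]:
    """Qualitative pattern of the study: paradoxical responses concentrate in
    the cerebrum under phenylephrine; vasodilator (SNP) windows are mostly
    pressure-passive; the spinal cord is more pressure-passive throughout."""
    return {
        ("cerebral", "phenylephrine"): {"pressure_passive": 0.3, "intact": 0.3, "paradoxical": 0.4},
        ("cerebral", "SNP"): {"pressure_passive": 0.7, "intact": 0.3, "paradoxical": 0.0},
        ("thoracic", "phenylephrine"): {"pressure_passive": 0.5, "intact": 0.35, "paradoxical": 0.15},
        ("thoracic", "SNP"): {"pressure_passive": 0.8, "intact": 0.2, "paradoxical": 0.0},
        ("lumbar", "phenylephrine"): {"pressure_passive": 0.5, "intact": 0.35, "paradoxical": 0.15},
        ("lumbar", "SNP"): {"pressure_passive": 0.8, "intact": 0.2, "paradoxical": 0.0},
    }


def constant_regime_probabilities(
    probs: Mapping[str, float]
) -> dict[tuple[str, str], dict[str, float]]:
    """Apply one regime distribution to every (site, drug) — e.g. an all
    pressure-passive run for classifier-recovery experiments."""
    full = {r: float(probs.get(r, 0.0)) for r in REGIMES}
    return {(s, d): dict(full) for s in SITES for d in ("phenylephrine", "SNP")}


@dataclass(frozen=True)
class SimConfig:
    """Full generative configuration; defaults are the study conditions.

    MAP targets default to the packaged per-dose across-animal means;
    between-animal SD 3 mmHg (the envelope's pre-infusion spread), within-
    window AR(1) fluctuation of SD 3 mmHg, a 30%-of-window ramp at each dose
    change, TOI observation noise SD 1% with AR coefficient 0.5 (10-s
    physiological samples are serially correlated).
    """

    protocol: ProtocolSpec = DEFAULT_PROTOCOL
    n_animals: int = 10
    map_targets: Mapping[tuple[str, str, float], float] | None = None
    map_between_animal_sd: float = 3.0
    map_within_window_sd: float = 3.0
    map_ar_coefficient: float = 0.5
    transition_fraction: float = 0.3
    site_profiles: Mapping[str, SiteProfile] = field(default_factory=default_site_profiles)
    regime_probabilities: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=default_regime_probabilities
    )
    regime_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"pressure_passive": 0.2, "intact": 0.0, "paradoxical": -0.2}
    )
    toi_noise_sd: float = 1.0
    toi_ar_coefficient: float = 0.5
    n_lumbar_missing: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ConfigError("n_animals must be >= 1")
        for sd in (self.map_between_animal_sd, self.map_within_window_sd, self.toi_noise_sd):
            if sd < 0:
                raise ConfigError("standard deviations must be >= 0")
        if not 0 <= self.transition_fraction <= 1:
            raise ConfigError("transition_fraction must be in [0, 1]")
        if not 0 <= self.n_lumbar_missing <= self.n_animals:
            raise ConfigError("n_lumbar_missing out of range")
        for key, probs in self.regime_probabilities.items():
            total = sum(probs.get(r, 0.0) for r in REGIMES)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"regime probabilities for {key} sum to {total}, not 1")

    def resolved_map_targets(self) -> dict[tuple[str, str, float], float]:
        if self.map_targets is not None:
            return dict(self.map_targets)
        return default_map_targets()

    def animal_ids(self) -> list[str]:
        return [f"A{i + 1:02d}" for i in range(self.n_animals)]

    def lumbar_missing_animals(self) -> frozenset[str]:
        # drop from the end so the first animals always have all sites
        ids = self.animal_ids()
        return frozenset(ids[len(ids) - self.n_lumbar_missing:]) if self.n_lumbar_missing else frozenset()


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) series of length n with marginal SD sd."""
    if sd == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def simulate_map_trajectory(
    cfg: SimConfig,
    rng: np.random.Generator,
    condition: str,
    drug: str,
    animal_offset: float = 0.0,
) -> dict[float, np.ndarray]:
    """MAP series per dose step of one arm for one animal.

    Each step is the animal-level target (arm/dose target + between-animal
    offset) with a linear ramp from the previous step's level over the first
    ``transition_fraction`` of the window, plus AR(1) fluctuation.  Samples
    are floored at 20 mmHg (logged) to guard degenerate configurations.
    """
    targets = cfg.resolved_map_targets()
    n = cfg.protocol.samples_per_window
    n_ramp = int(round(cfg.transition_fraction * n))
    out: dict[float, np.ndarray] = {}
    prev_level: float | None = None
    for dose in cfg.protocol.dose_levels:
        try:
            level = targets[(condition, drug, float(dose))] + animal_offset
        except KeyError as e:
            raise ConfigError(f"no MAP target for {(condition, drug, dose)}") from e
        base = np.full(n, level)
        if prev_level is not None and n_ramp > 0:
            base[:n_ramp] = np.linspace(prev_level, level, n_ramp + 1)[1:]
        series = base + _ar1(rng, n, cfg.map_within_window_sd, cfg.map_ar_coefficient)
        n_floored = int((series < MAP_FLOOR).sum())
        if n_floored:
            logger.warning(
                "MAP floor hit %d time(s) in %s/%s dose %s", n_floored, condition, drug, dose
            )
            series = np.maximum(series, MAP_FLOOR)
        out[float(dose)] = series
        prev_level = level
    return out


def simulate_toi_from_map(
    map_series: np.ndarray,
    profile: SiteProfile,
    regime: RegimeSpec,
    condition: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """TOI series for one window given its MAP series and response regime.

    TOI_t = curve(mean MAP) + condition offset + slope * (MAP_t - mean MAP)
    + AR(1) observation noise, clipped into (0, 100) with clipping logged.
    """
    m = np.asarray(map_series, float)
    if len(m) == 0:
        raise ValueError("map_series must be nonempty")
    mean_map = float(m.mean())
    base = profile.base_curve(mean_map) + profile.condition_offsets.get(condition, 0.0)
    toi = base + regime.slope * (m - mean_map)
    toi = toi + _ar1(rng, len(m), regime.noise_sd, regime.ar_coefficient)
    n_clip = int(((toi <= 0) | (toi >= 100)).sum())
    if n_clip:
        logger.warning("TOI clipped into (0, 100) at %d sample(s) [%s]", n_clip, profile.site)
        toi = np.clip(toi, 0.01, 99.99)
    return toi


def simulate_experiment(cfg: SimConfig) -> tuple[ExperimentDataset, pd.DataFrame]:
    """Generate a full protocol run and its per-window ground truth.

    Returns the dataset plus a truth table (one row per generated window) of
    the assigned regime and realized slope.  Deterministic under a fixed
    config, including the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    protocol = cfg.protocol
    n = protocol.samples_per_window
    t_grid = np.arange(n) * protocol.sampling_interval
    lumbar_missing = cfg.lumbar_missing_animals()

    frames: list[pd.DataFrame] = []
    truth_rows: list[tuple] = []
    for animal in cfg.animal_ids():
        animal_offset = rng.normal(0.0, cfg.map_between_animal_sd)
        sites = [s for s in SITES if not (s == "lumbar" and animal in lumbar_missing)]
        for condition, drug in protocol.arms():
            map_by_dose = simulate_map_trajectory(cfg, rng, condition, drug, animal_offset)
            for dose in protocol.dose_levels:
                m = map_by_dose[float(dose)]
                block = pd.DataFrame(
                    {
                        "animal_id": animal,
                        "condition": condition,
                        "drug": drug,
                        "dose_ug_kg_min": float(dose),
                        "t_s": t_grid,
                        "map_mmHg": m,
                        "toi_cerebral_pct": np.nan,
                        "toi_thoracic_pct": np.nan,
                        "toi_lumbar_pct": np.nan,
                    }
                )
                for site in sites:
                    probs = cfg.regime_probabilities[(site, drug)]
                    regime_name = rng.choice(REGIMES, p=[probs.get(r, 0.0) for r in REGIMES])
                    regime = RegimeSpec(
                        regime=str(regime_name),
                        slope=cfg.regime_slopes[str(regime_name)],
                        noise_sd=cfg.toi_noise_sd,
                        ar_coefficient=cfg.toi_ar_coefficient,
                    )
                    block[TOI_COLUMNS[site]] = simulate_toi_from_map(
                        m, cfg.site_profiles[site], regime, condition, rng
                    )
                    truth_rows.append(
                        (animal, condition, drug, float(dose), site, regime.regime, regime.slope)
                    )
                frames.append(block)

    frame = pd.concat(frames, ignore_index=True)[CSV_COLUMNS]
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return ExperimentDataset(frame, sampling_interval=protocol.sampling_interval), truth
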