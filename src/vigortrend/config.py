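"""Configuration containers for cohort simulation and epoch processing.

Every tunable rule of the pipeline lives here so that runs are fully
described by two YAML files: a :class:`CohortConfig` for the synthetic
cohort generator and a :class:`ProcessingParams` for the epoch-level
processing rules (non-wear detection, intensity cut-points, valid-day
criteria).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

# Category vocabularies used throughout the package.
SEX_LEVELS = ("male", "female")
ETHNICITY_LEVELS = ("white", "black", "Hispanic", "other")
EDUCATION_LEVELS = ("high school", "college", "university")
WEIGHT_LEVELS = ("normal", "overweight/obese")
REGION_LEVELS = ("UK", "Europe", "North America", "Brazil", "Australia")

FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": SEX_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
    "maternal_education": EDUCATION_LEVELS,
    "weight_status": WEIGHT_LEVELS,
}

#: Reference level per moderator used when fitting interaction models.
REFERENCE_LEVELS: dict[str, str] = {
    "sex": "male",
    "ethnicity": "white",
    "maternal_education": "high school",
    "weight_status": "normal",
    "region": "UK",
}

MINUTES_PER_DAY = 1440


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class Cutpoints:
    """Counts-per-minute thresholds separating intensity classes.

    Boundaries are half-open: sedentary ``[0, sedentary_upper)``, light
    ``[sedentary_upper, moderate_lower)``, moderate
    ``[moderate_lower, vigorous_lower)``, vigorous ``[vigorous_lower, inf)``.
    """

    sedentary_upper: int = 100
    moderate_lower: int = 2296
    vigorous_lower: int = 4012

    def __post_init__(self) -> None:
        if not (0 < self.sedentary_upper <= self.moderate_lower < self.vigorous_lower):
            raise ConfigurationError(
                "cut-points must satisfy 0 < sedentary_upper <= moderate_lower"
                f" < vigorous_lower, got {self}"
            )


@dataclass(frozen=True)
class ProcessingParams:
    """Rules applied when reducing an epoch count series to daily summaries.

    Attributes
    ----------
    target_epoch
        Epoch length in seconds to which all series are reintegrated.
    nonwear_min_bout
        Minimum length, in minutes, of a zero-count span to count as
        monitor non-wear.
    nonwear_max_interrupt
        Maximum number of isolated nonzero epochs tolerated inside a
        single non-wear bout.
    wear_window
        Clock interval (minutes since midnight, half-open) within which
        wear time is tallied.  Default 07:00-24:00.
    valid_day_min_wear
        Minimum wear minutes for a day to be valid (inclusive).
    min_valid_days
        Minimum number of valid days for a person to be included.
    interrupt_max_cpm
        Optional cap on the counts an epoch may carry while still being
        treated as a non-wear interruption.  ``None`` (default) imposes
        no cap.
    """

    target_epoch: int = 60
    nonwear_min_bout: int = 60
    nonwear_max_interrupt: int = 2
    wear_window: tuple[int, int] = (7 * 60, 24 * 60)
    valid_day_min_wear: int = 500
    min_valid_days: int = 1
    cutpoints: Cutpoints = field(default_factory=Cutpoints)
    interrupt_max_cpm: int | None = None

    def __post_init__(self) -> None:
        if self.target_epoch <= 0 or 60 % self.target_epoch and self.target_epoch % 60:
            raise ConfigurationError(f"unusable target epoch: {self.target_epoch}")
        for name in ("nonwear_min_bout", "valid_day_min_wear", "min_valid_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.nonwear_max_interrupt < 0:
            raise ConfigurationError("nonwear_max_interrupt must be >= 0")
        lo, hi = self.wear_window
        if not (0 <= lo < hi <= MINUTES_PER_DAY):
            raise ConfigurationError(f"invalid wear window {self.wear_window}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProcessingParams":
        d = dict(d)
        if "cutpoints" in d and not isinstance(d["cutpoints"], Cutpoints):
            d["cutpoints"] = Cutpoints(**d["cutpoints"])
        if "wear_window" in d:
            d["wear_window"] = tuple(d["wear_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ProcessingParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wear_window"] = list(self.wear_window)
        return d


@dataclass(frozen=True)
class WearSchedule:
    """Daily monitor-wear schedule for the trace generator.

    The wear period for each simulated day starts at ``start_min`` plus a
    uniform jitter of up to ``start_jitter`` minutes, and lasts a uniform
    number of minutes drawn from ``wear_minutes`` (inclusive bounds).
    """

    start_min: int = 8 * 60
    start_jitter: int = 60
    wear_minutes: tuple[int, int] = (600, 900)

    def __post_init__(self) -> None:
        lo, hi = self.wear_minutes
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid wear_minutes range {self.wear_minutes}")
        if self.start_min < 0 or self.start_jitter < 0:
            raise ConfigurationError("wear start and jitter must be non-negative")
        if self.start_min + self.start_jitter + hi > MINUTES_PER_DAY:
            raise ConfigurationError("wear schedule extends past midnight")


@dataclass(frozen=True)
class NonwearSpec:
    """Optional mid-wear non-wear bouts injected by the cohort generator.

    ``bouts_per_day`` is the expected (Poisson) number of bouts per day;
    zero disables injection entirely.
    """

    bouts_per_day: float = 0.0
    length_minutes: tuple[int, int] = (60, 120)
    interruption_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.bouts_per_day < 0:
            raise ConfigurationError("bouts_per_day must be >= 0")
        lo, hi = self.length_minutes
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid bout length range {self.length_minutes}")
        if not 0.0 <= self.interruption_prob <= 1.0:
            raise ConfigurationError("interruption_prob must be in [0, 1]")


def _default_subgroup_mix() -> dict[str, dict[str, float]]:
    return {
        "sex": {"male": 0.45, "female": 0.55},
        "ethnicity": {"white": 0.52, "black": 0.20, "Hispanic": 0.21, "other": 0.07},
        "maternal_education": {"high school": 0.53, "college": 0.17, "university": 0.30},
        "weight_status": {"normal": 0.90, "overweight/obese": 0.10},
    }


def _default_studies() -> tuple[tuple[str, str], ...]:
    return (
        ("study_uk", "UK"),
        ("study_eu", "Europe"),
        ("study_na", "North America"),
        ("study_au", "Australia"),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic accelerometer cohort.

    A participant of age ``a`` with subgroup levels ``g`` has expected
    daily vigorous minutes::

        baseline_vpa_mean * B_vpa(g) * (annual_ratio_vpa * R_vpa(g))**(a - 5)

    times a person-level log-normal factor with SD ``person_sd_log``;
    ``B`` and ``R`` are the multiplicative subgroup modifiers.  Moderate
    minutes follow the same construction.

    ``day_jitter`` controls how expected (real-valued) minutes become the
    integer minute targets of each simulated day: ``"poisson"`` draws a
    Poisson count, ``"round"`` uses unbiased randomized rounding (the
    near-noiseless mode used for pipeline self-consistency checks).
    """

    n_participants: int = 100
    age_range: tuple[float, float] = (5.0, 18.0)
    study_labels: tuple[tuple[str, str], ...] = field(default_factory=_default_studies)
    subgroup_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_subgroup_mix
    )
    baseline_vpa_mean: float = 12.97
    baseline_mpa_mean: float = 41.32
    annual_ratio_vpa: float = 0.931
    annual_ratio_mpa: float = 0.940
    baseline_modifiers_vpa: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    baseline_modifiers_mpa: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    ratio_modifiers_vpa: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    ratio_modifiers_mpa: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    light_minutes_mean: float = 150.0
    person_sd_log: float = 0.5
    days_per_person: int = 7
    day_jitter: str = "poisson"
    wear_schedule: WearSchedule = field(default_factory=WearSchedule)
    nonwear_spec: NonwearSpec = field(default_factory=NonwearSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        lo, hi = self.age_range
        if not (5.0 <= lo < hi <= 18.0):
            raise ConfigurationError(
                f"age_range must be within [5.0, 18.0], got {self.age_range}"
            )
        if not self.study_labels:
            raise ConfigurationError("at least one study label is required")
        for study, region in self.study_labels:
            if region not in REGION_LEVELS:
                raise ConfigurationError(f"unknown region {region!r} for study {study!r}")
        for factor, mix in self.subgroup_mix.items():
            if factor not in FACTOR_LEVELS:
                raise ConfigurationError(f"unknown subgroup factor {factor!r}")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"proportions for {factor!r} sum to {total}, expected 1"
                )
            unknown = set(mix) - set(FACTOR_LEVELS[factor])
            if unknown:
                raise ConfigurationError(f"unknown {factor} levels: {sorted(unknown)}")
            if any(p < 0 for p in mix.values()):
                raise ConfigurationError(f"negative proportion in {factor!r}")
        for name in ("baseline_vpa_mean", "baseline_mpa_mean", "light_minutes_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("annual_ratio_vpa", "annual_ratio_mpa"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for mods in (
            self.ratio_modifiers_vpa,
            self.ratio_modifiers_mpa,
            self.baseline_modifiers_vpa,
            self.baseline_modifiers_mpa,
        ):
            for factor, bylevel in mods.items():
                if factor not in FACTOR_LEVELS:
                    raise ConfigurationError(f"unknown modifier factor {factor!r}")
                if any(m <= 0 for m in bylevel.values()):
                    raise ConfigurationError(f"non-positive modifier under {factor!r}")
        if self.person_sd_log < 0:
            raise ConfigurationError("person_sd_log must be >= 0")
        if self.days_per_person < 1:
            raise ConfigurationError("days_per_person must be >= 1")
        if self.day_jitter not in ("poisson", "round"):
            raise ConfigurationError(f"unknown day_jitter mode {self.day_jitter!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "wear_schedule" in d and not isinstance(d["wear_schedule"], WearSchedule):
            ws = dict(d["wear_schedule"])
            if "wear_minutes" in ws:
                ws["wear_minutes"] = tuple(ws["wear_minutes"])
            d["wear_schedule"] = WearSchedule(**ws)
        if "nonwear_spec" in d and not isinstance(d["nonwear_spec"], NonwearSpec):
            ns = dict(d["nonwear_spec"])
            if "length_minutes" in ns:
                ns["length_minutes"] = tuple(ns["length_minutes"])
            d["nonwear_spec"] = NonwearSpec(**ns)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "study_labels" in d:
            d["study_labels"] = tuple((s, r) for s, r in d["study_labels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["study_labels"] = [list(sr) for sr in self.study_labels]
        return d
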