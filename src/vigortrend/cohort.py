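"""Synthetic cohort generator: participant metadata and epoch count traces.

The generator produces traces whose expected daily vigorous and moderate
minutes decline geometrically with age at known, configurable per-year
ratios, so the whole downstream pipeline (non-wear detection, cut-point
classification, log-linear modelling) can be validated against ground
truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    FACTOR_LEVELS,
    MINUTES_PER_DAY,
    CohortConfig,
    ConfigurationError,
    Cutpoints,
    WearSchedule,
)

EPOCHS_PER_DAY = MINUTES_PER_DAY  # at the 60-s target epoch

#: Upper bound (exclusive) on simulated vigorous counts; band membership,
#: not magnitude, drives all downstream computation.
VIGOROUS_CAP = 8001

CLASS_ORDER = ("sedentary", "light", "moderate", "vigorous")


@dataclass(frozen=True)
class Participant:
    """One participant-measurement's metadata row."""

    participant_id: str
    study_id: str
    region: str
    age: float
    sex: str
    ethnicity: str
    maternal_education: str
    weight_status: str
    measurement_date: pd.Timestamp

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "study_id": self.study_id,
            "region": self.region,
            "age": self.age,
            "sex": self.sex,
            "ethnicity": self.ethnicity,
            "maternal_education": self.maternal_education,
            "weight_status": self.weight_status,
            "measurement_date": self.measurement_date.date().isoformat(),
        }


@dataclass
class EpochSeries:
    """A contiguous, regularly sampled count trace for one participant."""

    participant_id: str
    start_clock: pd.Timestamp
    epoch_length: int  # seconds
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.epoch_length <= 0 or (60 % self.epoch_length and self.epoch_length != 60):
            raise ValueError(
                f"epoch_length must divide 60 or equal 60, got {self.epoch_length}"
            )
        self.start_clock = pd.Timestamp(self.start_clock)

    def __len__(self) -> int:
        return self.counts.size

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start_clock + pd.to_timedelta(
            np.arange(self.counts.size) * self.epoch_length, unit="s"
        )


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _band_bounds(cutpoints: Cutpoints) -> dict[str, tuple[int, int]]:
    return {
        # sedentary draws start at 1 so that simulated wear epochs are never
        # zero and cannot masquerade as monitor non-wear
        "sedentary": (1, cutpoints.sedentary_upper),
        "light": (cutpoints.sedentary_upper, cutpoints.moderate_lower),
        "moderate": (cutpoints.moderate_lower, cutpoints.vigorous_lower),
        "vigorous": (cutpoints.vigorous_lower, VIGOROUS_CAP),
    }


def generate_day_trace(
    target_minutes: Mapping[str, int],
    wear_start_min: int,
    wear_minutes: int,
    seed,
    *,
    participant_id: str = "p0",
    date="2005-01-01",
    cutpoints: Cutpoints | None = None,
) -> EpochSeries:
    """Build one full-day (1440 epoch) trace with exact class-minute totals.

    Within the wear span of ``wear_minutes`` epochs starting at clock
    minute ``wear_start_min``, exactly ``target_minutes[c]`` randomly
    placed epochs carry counts drawn uniformly inside class band ``c``;
    any wear epochs left over are sedentary.  Epochs outside the wear
    span are zero.

    Raises
    ------
    ValueError
        If the requested minutes exceed the wear span or the span runs
        past midnight.
    """
    rng = _rng(seed)
    cutpoints = cutpoints or Cutpoints()
    unknown = set(target_minutes) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown intensity classes: {sorted(unknown)}")
    wanted = {c: int(target_minutes.get(c, 0)) for c in CLASS_ORDER}
    if any(v < 0 for v in wanted.values()):
        raise ValueError("target minutes must be non-negative")
    requested = sum(wanted.values())
    if requested > wear_minutes:
        raise ValueError(
            f"target minutes ({requested}) exceed scheduled wear ({wear_minutes})"
        )
    if wear_start_min < 0 or wear_start_min + wear_minutes > MINUTES_PER_DAY:
        raise ValueError("wear span must lie within the calendar day")

    wanted["sedentary"] += wear_minutes - requested
    counts = np.zeros(EPOCHS_PER_DAY, dtype=np.int64)
    positions = wear_start_min + rng.permutation(wear_minutes)
    bounds = _band_bounds(cutpoints)
    offset = 0
    for cls in CLASS_ORDER:
        k = wanted[cls]
        if k:
            lo, hi = bounds[cls]
            counts[positions[offset : offset + k]] = rng.integers(lo, hi, size=k)
            offset += k
    return EpochSeries(
        participant_id=participant_id,
        start_clock=pd.Timestamp(date),
        epoch_length=60,
        counts=counts,
    )


@dataclass(frozen=True)
class BoutSpec:
    """One non-wear bout to inject: a zero span with optional interruptions.

    ``interruption_offsets`` are epoch offsets (strictly inside the span)
    that keep a nonzero count of ``interruption_count``.
    """

    start: int
    length: int
    interruption_offsets: tuple[int, ...] = field(default_factory=tuple)
    interruption_count: int = 50

    def __post_init__(self) -> None:
        if self.length <= 0 or self.start < 0:
            raise ValueError("bout start must be >= 0 and length positive")
        for off in self.interruption_offsets:
            if not 0 < off < self.length - 1:
                raise ValueError(
                    f"interruption offset {off} not strictly inside bout of "
                    f"length {self.length}"
                )
        if self.interruption_count <= 0:
            raise ValueError("interruption_count must be positive")

    @property
    def end(self) -> int:
        return self.start + self.length


def inject_nonwear(series: EpochSeries, bout_specs: Sequence[BoutSpec]) -> EpochSeries:
    """Return a copy of ``series`` with the given spans zeroed out.

    Epochs listed in each bout's ``interruption_offsets`` are set to a
    nonzero count instead, producing interrupted non-wear bouts. Bouts
    must not overlap and must lie within the series.
    """
    specs = sorted(bout_specs, key=lambda b: b.start)
    for prev, cur in zip(specs, specs[1:]):
        if cur.start < prev.end:
            raise ValueError(f"overlapping bouts at epochs {cur.start} and {prev.start}")
    counts = series.counts.copy()
    n = counts.size
    for spec in specs:
        if spec.end > n:
            raise ValueError(f"bout [{spec.start}, {spec.end}) exceeds series length {n}")
        counts[spec.start : spec.end] = 0
        for off in spec.interruption_offsets:
            counts[spec.start + off] = spec.interruption_count
    return replace(series, counts=counts)


def _modifier(mods: Mapping[str, Mapping[str, float]], levels: Mapping[str, str]) -> float:
    out = 1.0
    for factor, bylevel in mods.items():
        out *= bylevel.get(levels[factor], 1.0)
    return out


def expected_minutes(
    config: CohortConfig, outcome: str, age: float, levels: Mapping[str, str]
) -> float:
    """Expected daily minutes for ``outcome`` ("vpa"|"mpa") before person noise."""
    if outcome == "vpa":
        base = config.baseline_vpa_mean * _modifier(config.baseline_modifiers_vpa, levels)
        ratio = config.annual_ratio_vpa * _modifier(config.ratio_modifiers_vpa, levels)
    elif outcome == "mpa":
        base = config.baseline_mpa_mean * _modifier(config.baseline_modifiers_mpa, levels)
        ratio = config.annual_ratio_mpa * _modifier(config.ratio_modifiers_mpa, levels)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return base * ratio ** (age - 5.0)


def _draw_levels(config: CohortConfig, rng: np.random.Generator) -> dict[str, str]:
    out = {}
    for factor, levels in FACTOR_LEVELS.items():
        mix = config.subgroup_mix.get(factor)
        if mix is None:
            out[factor] = levels[0]
            continue
        names = list(mix)
        probs = np.array([mix[name] for name in names], dtype=float)
        out[factor] = names[rng.choice(len(names), p=probs / probs.sum())]
    return out


def _day_targets(mu: float, mode: str, rng: np.random.Generator) -> int:
    if mode == "poisson":
        return int(rng.poisson(mu))
    # unbiased randomized rounding: E[target] == mu exactly
    base = int(np.floor(mu))
    return base + int(rng.random() < mu - base)


def _draw_wear(schedule: WearSchedule, rng: np.random.Generator) -> tuple[int, int]:
    start = schedule.start_min + int(rng.integers(0, schedule.start_jitter + 1))
    lo, hi = schedule.wear_minutes
    wear = int(rng.integers(lo, hi + 1))
    wear = min(wear, MINUTES_PER_DAY - start)
    return start, wear


def generate_cohort(
    config: CohortConfig, seed=None
) -> tuple[list[Participant], list[EpochSeries]]:
    """Generate participant metadata and one multi-day trace per participant.

    Each participant receives ``config.days_per_person`` consecutive
    full-day traces (one EpochSeries spanning them, anchored at midnight
    of the measurement date).  Identical seeds yield identical output.
    """
    rng = _rng(config.seed if seed is None else seed)
    lo_age, hi_age = config.age_range
    base_date = pd.Timestamp("2004-01-01")
    participants: list[Participant] = []
    traces: list[EpochSeries] = []
    width = max(4, len(str(max(config.n_participants - 1, 0))))

    for i in range(config.n_participants):
        pid = f"p{i:0{width}d}"
        study_id, region = config.study_labels[
            int(rng.integers(len(config.study_labels)))
        ]
        age = float(rng.uniform(lo_age, hi_age))
        levels = _draw_levels(config, rng)
        # measurement_date monotone in participant index so that
        # first-measurement selection downstream is exercised predictably
        date = base_date + pd.Timedelta(days=i % 3650)
        participants.append(
            Participant(
                participant_id=pid,
                study_id=study_id,
                region=region,
                age=age,
                sex=levels["sex"],
                ethnicity=levels["ethnicity"],
                maternal_education=levels["maternal_education"],
                weight_status=levels["weight_status"],
                measurement_date=date,
            )
        )

        person_factor = (
            float(np.exp(rng.normal(0.0, config.person_sd_log)))
            if config.person_sd_log > 0
            else 1.0
        )
        mu_vpa = expected_minutes(config, "vpa", age, levels) * person_factor
        mu_mpa = expected_minutes(config, "mpa", age, levels) * person_factor

        day_counts = []
        for d in range(config.days_per_person):
            start, wear = _draw_wear(config.wear_schedule, rng)
            vpa = _day_targets(mu_vpa, config.day_jitter, rng)
            mpa = _day_targets(mu_mpa, config.day_jitter, rng)
            light = _day_targets(config.light_minutes_mean, config.day_jitter, rng)
            # clip rare overshoots, giving up light first, then moderate
            light = min(light, max(0, wear - vpa - mpa))
            mpa = min(mpa, max(0, wear - vpa - light))
            vpa = min(vpa, wear - mpa - light)
            day = generate_day_trace(
                {"vigorous": vpa, "moderate": mpa, "light": light},
                start,
                wear,
                rng,
                participant_id=pid,
                date=date + pd.Timedelta(days=d),
            )
            counts = day.counts
            if config.nonwear_spec.bouts_per_day > 0:
                counts = _inject_random_bouts(
                    counts, start, wear, config.nonwear_spec, rng
                )
            day_counts.append(counts)

        traces.append(
            EpochSeries(
                participant_id=pid,
                start_clock=date,
                epoch_length=60,
                counts=np.concatenate(day_counts) if day_counts else np.array([], int),
            )
        )
    return participants, traces


def _inject_random_bouts(counts, wear_start, wear_minutes, spec, rng):
    n_bouts = int(rng.poisson(spec.bouts_per_day))
    if not n_bouts:
        return counts
    counts = counts.copy()
    lo, hi = spec.length_minutes
    for _ in range(n_bouts):
        length = int(rng.integers(lo, hi + 1))
        if length >= wear_minutes:
            continue
        start = wear_start + int(rng.integers(0, wear_minutes - length))
        counts[start : start + length] = 0
        if length > 2 and rng.random() < spec.interruption_prob:
            counts[start + int(rng.integers(1, length - 1))] = 50
    return counts


def generate_person_table(config: CohortConfig, seed=None) -> pd.DataFrame:
    """Model-level fast path: person rows drawn straight from the generative law.

    Returns one row per participant with continuous observed outcomes
    ``vpa_min``/``mpa_min`` equal to the expected minutes times the
    person-level log-normal factor — i.e. the trace pipeline's target
    quantities without epoch-level simulation.  Used for statistical
    parameter-recovery studies where simulating millions of epochs would
    add nothing but runtime.
    """
    rng = _rng(config.seed if seed is None else seed)
    lo_age, hi_age = config.age_range
    n = config.n_participants
    rows = []
    ws = config.wear_schedule
    for i in range(n):
        study_id, region = config.study_labels[
            int(rng.integers(len(config.study_labels)))
        ]
        age = float(rng.uniform(lo_age, hi_age))
        levels = _draw_levels(config, rng)
        factor = (
            float(np.exp(rng.normal(0.0, config.person_sd_log)))
            if config.person_sd_log > 0
            else 1.0
        )
        wear = float(
            np.mean(
                rng.integers(
                    ws.wear_minutes[0], ws.wear_minutes[1] + 1, size=config.days_per_person
                )
            )
        )
        rows.append(
            {
                "participant_id": f"p{i:05d}",
                "age": age,
                "vpa_min": expected_minutes(config, "vpa", age, levels) * factor,
                "mpa_min": expected_minutes(config, "mpa", age, levels) * factor,
                "wear_min": wear,
                "study_id": study_id,
                "region": region,
                **levels,
            }
        )
    cols = [
        "participant_id", "age", "vpa_min", "mpa_min", "wear_min", "study_id",
        "sex", "ethnicity", "maternal_education", "weight_status", "region",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# CSV round-tripping


def participants_frame(participants: Iterable[Participant]) -> pd.DataFrame:
    cols = [
        "participant_id", "study_id", "region", "age", "sex", "ethnicity",
        "maternal_education", "weight_status", "measurement_date",
    ]
    return pd.DataFrame([p.to_dict() for p in participants], columns=cols)


def write_metadata_csv(participants: Iterable[Participant], path) -> None:
    participants_frame(participants).to_csv(path, index=False)


def write_epochs_csv(traces: Iterable[EpochSeries], path) -> None:
    """Write traces as long-format CSV: participant_id, timestamp, counts."""
    frames = [
        pd.DataFrame(
            {
                "participant_id": s.participant_id,
                "timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                "counts": s.counts,
            }
        )
        for s in traces
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["participant_id", "timestamp", "counts"])
    )
    out.to_csv(path, index=False)


def read_epochs_csv(path) -> list[EpochSeries]:
    """Read a long-format epoch CSV back into per-participant series.

    Timestamps must be regularly spaced within each participant; the
    epoch length is inferred from the spacing.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    series = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        ts = grp["timestamp"].to_numpy()
        if len(ts) > 1:
            deltas = np.unique(np.diff(ts))
            if deltas.size != 1:
                raise ValueError(f"irregular timestamps for participant {pid!r}")
            epoch = int(deltas[0] / np.timedelta64(1, "s"))
        else:
            epoch = 60
        series.append(
            EpochSeries(
                participant_id=str(pid),
                start_clock=pd.Timestamp(ts[0]),
                epoch_length=epoch,
                counts=grp["counts"].to_numpy(np.int64),
            )
        )
    return series
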