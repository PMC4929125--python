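"""Epoch-level accelerometer processing: reintegration, non-wear
detection, cut-point classification and daily/person summaries.

The rules implemented here are the classic uniaxial-counts conventions:
60-s epochs, non-wear as >=60 min of consecutive zeros allowing up to
2 isolated nonzero interruption epochs, wear time tallied between 07:00
and midnight, valid days requiring >=500 wear minutes, and intensity
classes assigned by counts-per-minute cut-points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import EpochSeries
from .config import MINUTES_PER_DAY, ProcessingParams

CLASS_LABELS = ("sedentary", "light", "moderate", "vigorous")


@dataclass(frozen=True)
class NonWearBout:
    """A detected non-wear span, in 60-s epoch indices (half-open)."""

    start: int
    end: int
    n_interruptions: int

    @property
    def minutes(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DaySummary:
    participant_id: str
    date: pd.Timestamp
    wear_minutes: int
    sedentary_minutes: int
    light_minutes: int
    moderate_minutes: int
    vigorous_minutes: int
    valid: bool


@dataclass(frozen=True)
class PersonSummary:
    participant_id: str
    measurement_date: pd.Timestamp
    n_valid_days: int
    mean_wear_minutes: float
    mean_mpa_minutes: float
    mean_vpa_minutes: float
    mean_sedentary_minutes: float


def reintegrate(series: EpochSeries, target_epoch: int = 60) -> EpochSeries:
    """Re-sum counts from a finer epoch onto ``target_epoch`` seconds.

    Each output count is the sum of ``target_epoch / epoch_length``
    consecutive input counts.  A trailing block shorter than one full
    target epoch is dropped (with a warning), since partial minutes
    would bias counts-per-minute values.
    """
    if series.epoch_length == target_epoch:
        return series
    if target_epoch % series.epoch_length:
        raise ValueError(
            f"epoch length {series.epoch_length}s does not divide the "
            f"target epoch {target_epoch}s"
        )
    factor = target_epoch // series.epoch_length
    n_full = series.counts.size // factor
    remainder = series.counts.size - n_full * factor
    if remainder:
        warnings.warn(
            f"dropping trailing partial block of {remainder} epochs "
            f"({remainder * series.epoch_length}s) during reintegration",
            stacklevel=2,
        )
    summed = series.counts[: n_full * factor].reshape(n_full, factor).sum(axis=1)
    return replace(series, epoch_length=target_epoch, counts=summed)


def _require_60s(series: EpochSeries) -> None:
    if series.epoch_length != 60:
        raise ValueError(
            f"expected 60-s epochs, got {series.epoch_length}s; reintegrate first"
        )


def _zero_runs(mask: np.ndarray) -> np.ndarray:
    """Half-open [start, end) spans of maximal True runs, shape (k, 2)."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    return edges.reshape(-1, 2)


def detect_nonwear(
    series: EpochSeries, params: ProcessingParams | None = None
) -> list[NonWearBout]:
    """Find non-wear bouts by merging zero runs across isolated interruptions.

    A bout is a span starting and ending on zero epochs, containing at
    most ``params.nonwear_max_interrupt`` nonzero epochs, each a single
    isolated epoch; the span must reach ``params.nonwear_min_bout``
    minutes.  Scanning is greedy left-to-right: from each candidate
    start the bout is extended as far as the interruption budget allows,
    emitted if long enough, and the scan resumes after it.  A further
    interruption beyond the budget ends (but does not void) the bout.

    When ``params.interrupt_max_cpm`` is set, epochs exceeding that
    count cannot act as interruptions and always terminate a bout.
    """
    params = params or ProcessingParams()
    _require_60s(series)
    counts = series.counts
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be non-negative")
    min_epochs = params.nonwear_min_bout
    max_interrupt = params.nonwear_max_interrupt
    cap = params.interrupt_max_cpm

    runs = _zero_runs(counts == 0)
    bouts: list[NonWearBout] = []
    s = 0
    while s < len(runs):
        start, end = runs[s]
        k = s
        interruptions = 0
        while (
            k + 1 < len(runs)
            and runs[k + 1][0] - end == 1
            and interruptions < max_interrupt
            and (cap is None or counts[end] <= cap)
        ):
            interruptions += 1
            end = runs[k + 1][1]
            k += 1
        if end - start >= min_epochs:
            bouts.append(NonWearBout(int(start), int(end), interruptions))
            s = k + 1
        else:
            # a shorter merge starting at the next zero run may still
            # qualify with a fresh interruption budget
            s += 1
    return bouts


def nonwear_mask(series: EpochSeries, params: ProcessingParams | None = None) -> np.ndarray:
    mask = np.zeros(series.counts.size, dtype=bool)
    for bout in detect_nonwear(series, params):
        mask[bout.start : bout.end] = True
    return mask


def classify_epochs(
    series: EpochSeries, params: ProcessingParams | None = None
) -> np.ndarray:
    """Assign each epoch one intensity label from its counts-per-minute value."""
    params = params or ProcessingParams()
    _require_60s(series)
    counts = series.counts
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be non-negative")
    cp = params.cutpoints
    bins = np.array([cp.sedentary_upper, cp.moderate_lower, cp.vigorous_lower])
    return np.asarray(CLASS_LABELS)[np.searchsorted(bins, counts, side="right")]


def _split_days(series: EpochSeries) -> list[EpochSeries]:
    ts = series.timestamps
    dates = ts.normalize()
    out = []
    for date in dates.unique():
        sel = dates == date
        idx = np.flatnonzero(sel)
        out.append(
            replace(
                series,
                start_clock=ts[idx[0]],
                counts=series.counts[idx[0] : idx[-1] + 1],
            )
        )
    return out


def summarize_day(
    series: EpochSeries, params: ProcessingParams | None = None
) -> DaySummary:
    """Reduce one calendar day's trace to wear and intensity minutes.

    Only epochs whose clock time lies in the wear window (default
    [07:00, 24:00)) are considered; wear epochs are window epochs not
    inside any detected non-wear bout.  Intensity minutes are tallied
    over wear epochs only, so they always partition wear time.
    """
    params = params or ProcessingParams()
    _require_60s(series)
    ts = series.timestamps
    if ts.size == 0:
        raise ValueError("empty day series")
    if ts.normalize().nunique() != 1:
        raise ValueError("summarize_day expects epochs from a single calendar day")
    if ts.duplicated().any():
        raise ValueError("duplicate epoch timestamps")

    minute_of_day = ts.hour * 60 + ts.minute
    lo, hi = params.wear_window
    in_window = (minute_of_day >= lo) & (minute_of_day < hi)
    wear = np.asarray(in_window) & ~nonwear_mask(series, params)
    labels = classify_epochs(series, params)

    tally = {cls: int(np.sum(wear & (labels == cls))) for cls in CLASS_LABELS}
    wear_minutes = int(wear.sum())
    return DaySummary(
        participant_id=series.participant_id,
        date=ts[0].normalize(),
        wear_minutes=wear_minutes,
        sedentary_minutes=tally["sedentary"],
        light_minutes=tally["light"],
        moderate_minutes=tally["moderate"],
        vigorous_minutes=tally["vigorous"],
        valid=wear_minutes >= params.valid_day_min_wear,
    )


def summarize_person(
    day_summaries: Sequence[DaySummary], params: ProcessingParams | None = None
) -> PersonSummary | None:
    """Average valid days into a person summary; ``None`` means excluded.

    All days must belong to one measurement of one participant. Means
    are unweighted over valid days only.
    """
    params = params or ProcessingParams()
    if not day_summaries:
        return None
    pids = {d.participant_id for d in day_summaries}
    if len(pids) != 1:
        raise ValueError(f"day summaries span multiple participants: {sorted(pids)}")
    valid = [d for d in day_summaries if d.valid]
    if len(valid) < params.min_valid_days:
        return None
    return PersonSummary(
        participant_id=day_summaries[0].participant_id,
        measurement_date=min(d.date for d in day_summaries),
        n_valid_days=len(valid),
        mean_wear_minutes=float(np.mean([d.wear_minutes for d in valid])),
        mean_mpa_minutes=float(np.mean([d.moderate_minutes for d in valid])),
        mean_vpa_minutes=float(np.mean([d.vigorous_minutes for d in valid])),
        mean_sedentary_minutes=float(np.mean([d.sedentary_minutes for d in valid])),
    )


def process_traces(
    traces: Iterable[EpochSeries], params: ProcessingParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full processing chain over many traces.

    Returns ``(days, persons)`` data frames.  Finer-than-60s traces are
    reintegrated automatically; persons failing the minimum-valid-days
    rule are simply absent from ``persons``.
    """
    params = params or ProcessingParams()
    day_rows = []
    person_rows = []
    for series in traces:
        if series.epoch_length != params.target_epoch:
            series = reintegrate(series, params.target_epoch)
        summaries = [summarize_day(day, params) for day in _split_days(series)]
        day_rows.extend(vars(d) for d in summaries)
        person = summarize_person(summaries, params)
        if person is not None:
            person_rows.append(vars(person))
    days = pd.DataFrame(
        day_rows,
        columns=[
            "participant_id", "date", "wear_minutes", "sedentary_minutes",
            "light_minutes", "moderate_minutes", "vigorous_minutes", "valid",
        ],
    )
    persons = pd.DataFrame(
        person_rows,
        columns=[
            "participant_id", "measurement_date", "n_valid_days",
            "mean_wear_minutes", "mean_mpa_minutes", "mean_vpa_minutes",
            "mean_sedentary_minutes",
        ],
    )
    return days, persons
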