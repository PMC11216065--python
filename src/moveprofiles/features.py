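"""Daily movement-behaviour features from epoch-level acceleration series.

Thirteen features over six dimensions are computed per waking day and averaged
to one vector per participant:

===========================  ==================================================
Dimension                    Features
===========================  ==================================================
Overall activity level       average acceleration (mg)
Total duration               minutes/day in SB, LIPA, MVPA
Frequency                    number of SB, LIPA, MVPA bouts
Typical duration             mean SB, LIPA, MVPA bout length (min)
Intensity distribution       intensity constant and gradient (log-log fit)
Timing                       start hour of the most active 5 hours (M5)
===========================  ==================================================

States are assigned by epoch-mean acceleration cut-points: SB < 40 mg,
40 <= LIPA < 100 mg, MVPA >= 100 mg.  A bout is a maximal run of consecutive
epochs in one state (minimum one epoch).  Days are valid when worn for at
least 2/3 of the waking window; participants are included with >= 2 valid
weekdays and >= 2 valid weekend days, and features are aggregated with 5/7 -
2/7 weekday/weekend weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EpochDay

SB, LIPA, MVPA, NONWEAR = 0, 1, 2, -1
DEFAULT_CUTPOINTS = (40.0, 100.0)
DEFAULT_BIN_WIDTH = 25.0
M5_HOURS = 5.0
MIN_WEAR_FRACTION = 2.0 / 3.0

FEATURE_COLUMNS = [
    "Average acceleration (mg)",
    "Total duration of SB (min/day)",
    "Total duration of LIPA (min/day)",
    "Total duration of MVPA (min/day)",
    "Number of sedentary bouts",
    "Number of LIPA bouts",
    "Number of MVPA bouts",
    "Mean duration of sedentary bouts (min)",
    "Mean duration of LIPA bouts (min)",
    "Mean duration of MVPA bouts (min)",
    "Intensity constant",
    "Intensity gradient",
    "Timing of the most active 5 hours",
]


def classify_epochs(day: EpochDay, cutpoints: tuple[float, float] = DEFAULT_CUTPOINTS) -> np.ndarray:
    """Per-epoch state codes (0=SB, 1=LIPA, 2=MVPA, -1=non-wear)."""
    lo, hi = cutpoints
    if not (0 < lo < hi):
        raise ValueError("cutpoints must be strictly increasing and positive")
    a = np.asarray(day.accel_mg, float)
    if np.any(~np.isfinite(a)) or np.any(a < 0):
        raise ValueError("acceleration must be finite and >= 0")
    state = np.where(a >= hi, MVPA, np.where(a >= lo, LIPA, SB)).astype(np.int8)
    state[~day.wear] = NONWEAR
    return state


def bouts(seq: np.ndarray) -> dict[int, np.ndarray]:
    """Run lengths of maximal same-state runs, keyed by state code.

    Non-wear runs are returned under ``NONWEAR`` and break bouts of the worn
    states.
    """
    seq = np.asarray(seq)
    if seq.size == 0:
        raise ValueError("empty state sequence")
    change = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [seq.size])))
    run_states = seq[starts]
    return {s: lengths[run_states == s] for s in (SB, LIPA, MVPA, NONWEAR)}


def fit_intensity_loglog(bin_minutes: np.ndarray, bin_midpoints_mg: np.ndarray) -> tuple[float, float]:
    """OLS of ln(minutes per bin) on ln(bin midpoint): (constant, gradient)."""
    m = np.asarray(bin_minutes, float)
    x = np.asarray(bin_midpoints_mg, float)
    keep = m > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 non-empty intensity bins")
    slope, intercept = np.polyfit(np.log(x[keep]), np.log(m[keep]), 1)
    return float(intercept), float(slope)


def intensity_regression(
    day: EpochDay, bin_width: float = DEFAULT_BIN_WIDTH
) -> tuple[float, float]:
    """Intensity (constant, gradient) of one day.

    Worn-epoch accelerations are binned in ``bin_width``-mg bins from 0 mg;
    the log of the minutes accumulated in each non-empty bin is regressed on
    the log of the bin midpoint.  A more negative gradient means time is
    concentrated at the low end of the intensity spectrum.
    """
    a = day.accel_mg[day.wear]
    if a.size == 0:
        raise ValueError("no worn epochs")
    n_bins = int(np.floor(a.max() / bin_width)) + 1
    counts = np.bincount(np.minimum((a / bin_width).astype(int), n_bins - 1), minlength=n_bins)
    minutes = counts * day.epoch_seconds / 60.0
    mid = (np.arange(n_bins) + 0.5) * bin_width
    return fit_intensity_loglog(minutes, mid)


def m5_timing(day: EpochDay) -> float:
    """Clock start hour of the most active contiguous 5-hour window.

    The window advances in 1-epoch steps; ties go to the earliest start.
    Returns NaN when the day is shorter than 5 h.
    """
    w = int(M5_HOURS * 3600 / day.epoch_seconds)
    a = np.asarray(day.accel_mg, float)
    if a.size < w:
        return float("nan")
    windows = np.lib.stride_tricks.sliding_window_view(a, w)
    means = windows.mean(axis=1)
    idx = int(np.argmax(means))  # first maximum = earliest start
    return day.waking_start_hour + idx * day.epoch_seconds / 3600.0


def impute_nonwear(day: EpochDay, other_days: list[EpochDay]) -> EpochDay:
    """Replace non-wear epochs by the same-clock-epoch mean of other days.

    Alignment is on absolute clock epoch index (time of day); where no other
    day covers that clock epoch, the day's own worn-epoch mean is used.  Wear
    flags are preserved so the pre-imputation wear fraction stays available.
    """
    if day.wear.all():
        return day
    step = day.epoch_seconds
    base = int(round(day.waking_start_hour * 3600 / step))
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for od in other_days:
        ob = int(round(od.waking_start_hour * 3600 / od.epoch_seconds))
        worn = np.flatnonzero(od.wear)
        for i in worn:
            k = ob + int(i)
            sums[k] = sums.get(k, 0.0) + float(od.accel_mg[i])
            counts[k] = counts.get(k, 0) + 1
    accel = day.accel_mg.copy()
    fallback = float(day.accel_mg[day.wear].mean()) if day.wear.any() else 0.0
    for i in np.flatnonzero(~day.wear):
        k = base + int(i)
        accel[i] = sums[k] / counts[k] if counts.get(k) else fallback
    out = EpochDay(
        participant_id=day.participant_id,
        date=day.date,
        day_type=day.day_type,
        waking_start_hour=day.waking_start_hour,
        epoch_seconds=day.epoch_seconds,
        accel_mg=accel,
        wear=day.wear.copy(),
    )
    return out


@dataclass
class DayFeatures:
    """The 13 features of one (imputed) valid day plus bookkeeping."""

    day_type: str
    wear_fraction: float
    valid: bool
    avg_accel_mg: float = np.nan
    dur_min: tuple[float, float, float] = (np.nan,) * 3
    n_bouts: tuple[float, float, float] = (np.nan,) * 3
    mean_bout_min: tuple[float, float, float] = (np.nan,) * 3
    intensity_constant: float = np.nan
    intensity_gradient: float = np.nan
    m5_start_hour: float = np.nan

    def as_row(self) -> dict[str, float]:
        vals = [
            self.avg_accel_mg,
            *self.dur_min,
            *self.n_bouts,
            *self.mean_bout_min,
            self.intensity_constant,
            self.intensity_gradient,
            self.m5_start_hour,
        ]
        return dict(zip(FEATURE_COLUMNS, vals))


def day_features(
    day: EpochDay,
    cutpoints: tuple[float, float] = DEFAULT_CUTPOINTS,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DayFeatures:
    """All 13 features of one day (assumed already non-wear-imputed).

    The identity ``dur_state = n_bouts_state * mean_bout_state`` holds exactly
    by construction; a state absent from the day has zero duration/bouts and a
    missing (NaN) mean bout duration.
    """
    wear_fraction = day.wear_fraction
    valid = wear_fraction >= MIN_WEAR_FRACTION
    # features are computed on the imputed series: treat every epoch as worn
    full = EpochDay(
        participant_id=day.participant_id,
        date=day.date,
        day_type=day.day_type,
        waking_start_hour=day.waking_start_hour,
        epoch_seconds=day.epoch_seconds,
        accel_mg=day.accel_mg,
        wear=np.ones(day.n_epochs, dtype=bool),
    )
    state = classify_epochs(full, cutpoints)
    runs = bouts(state)
    ep_min = day.epoch_seconds / 60.0
    dur = tuple(float(np.sum(state == s)) * ep_min for s in (SB, LIPA, MVPA))
    nb = tuple(float(len(runs[s])) for s in (SB, LIPA, MVPA))
    mean_bout = tuple(d / n if n > 0 else np.nan for d, n in zip(dur, nb))
    try:
        const, grad = intensity_regression(full, bin_width)
    except ValueError:
        const, grad = np.nan, np.nan
    return DayFeatures(
        day_type=day.day_type,
        wear_fraction=wear_fraction,
        valid=valid,
        avg_accel_mg=float(np.mean(full.accel_mg)),
        dur_min=dur,
        n_bouts=nb,
        mean_bout_min=mean_bout,
        intensity_constant=const,
        intensity_gradient=grad,
        m5_start_hour=m5_timing(full),
    )


def validity_and_inclusion(days: list[EpochDay]) -> tuple[bool, list[bool]]:
    """Apply the wear-time rule.

    A day is valid iff worn >= 2/3 of the waking window; a participant is
    included iff they have >= 2 valid weekdays and >= 2 valid weekend days.
    """
    valid = [d.wear_fraction >= MIN_WEAR_FRACTION for d in days]
    n_wd = sum(v for v, d in zip(valid, days) if d.day_type == "weekday")
    n_we = sum(v for v, d in zip(valid, days) if d.day_type == "weekend")
    return (n_wd >= 2 and n_we >= 2), valid


def aggregate(day_feats: list[DayFeatures]) -> dict[str, float]:
    """Weighted weekday/weekend average of valid-day features.

    feature = (5 * mean over valid weekdays + 2 * mean over valid weekend
    days) / 7, computed per feature over the days where it is defined.  With
    5 valid weekdays and 2 valid weekend days this equals the plain 7-day
    mean.
    """
    valid = [f for f in day_feats if f.valid]
    if not valid:
        raise ValueError("no valid days to aggregate")
    rows_wd = pd.DataFrame([f.as_row() for f in valid if f.day_type == "weekday"])
    rows_we = pd.DataFrame([f.as_row() for f in valid if f.day_type == "weekend"])
    if len(rows_wd) == 0 or len(rows_we) == 0:
        raise ValueError("aggregation requires valid days of both types")
    mean_wd = rows_wd.mean(skipna=True)
    mean_we = rows_we.mean(skipna=True)
    # a feature missing on all days of one type falls back to the other type
    combined = (5.0 * mean_wd + 2.0 * mean_we) / 7.0
    combined = combined.where(~(mean_wd.isna() & ~mean_we.isna()), mean_we)
    combined = combined.where(~(mean_we.isna() & ~mean_wd.isna()), mean_wd)
    return combined.to_dict()


def participant_features(days: list[EpochDay]) -> dict[str, float] | None:
    """One participant: validity rule, non-wear imputation, 13-feature vector.

    Returns None when the participant fails the inclusion rule.  The returned
    dict carries the 13 feature columns plus valid-day counts and a flag for
    any feature that stayed missing on every valid day.
    """
    included, valid = validity_and_inclusion(days)
    feats_meta = {
        "n_valid_weekdays": sum(v for v, d in zip(valid, days) if d.day_type == "weekday"),
        "n_valid_weekend_days": sum(v for v, d in zip(valid, days) if d.day_type == "weekend"),
        "included_flag": included,
    }
    if not included:
        return None
    valid_days = [d for d, v in zip(days, valid) if v]
    imputed = [
        impute_nonwear(d, [o for o in valid_days if o is not d]) for d in valid_days
    ]
    dfeats = [day_features(d) for d in imputed]
    row = aggregate(dfeats)
    row.update(feats_meta)
    row["any_feature_missing"] = any(not np.isfinite(row[c]) for c in FEATURE_COLUMNS)
    return row


def extract_features(days_by_participant: dict[str, list[EpochDay]]) -> pd.DataFrame:
    """Feature table over a cohort: one row per *included* participant."""
    rows = {}
    for pid, days in days_by_participant.items():
        row = participant_features(days)
        if row is not None:
            rows[pid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "participant_id"
    return out
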