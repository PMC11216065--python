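"""Feature extraction: cut-points, bouts, log-log regression, M5, validity."""

import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moveprofiles import features
from moveprofiles.cohort import EpochDay
from moveprofiles.features import (
    FEATURE_COLUMNS,
    LIPA,
    MVPA,
    SB,
    aggregate,
    bouts,
    classify_epochs,
    day_features,
    fit_intensity_loglog,
    impute_nonwear,
    intensity_regression,
    m5_timing,
    participant_features,
    validity_and_inclusion,
)


def make_day(accel, wear=None, start=7.0, day_type="weekday", epoch_seconds=60, pid="p0"):
    accel = np.asarray(accel, float)
    wear = np.ones(accel.size, bool) if wear is None else np.asarray(wear, bool)
    return EpochDay(
        participant_id=pid,
        date=datetime.date(2013, 1, 7),
        day_type=day_type,
        waking_start_hour=start,
        epoch_seconds=epoch_seconds,
        accel_mg=accel,
        wear=wear,
    )


# ---------------------------------------------------------------- cut-points

@pytest.mark.parametrize(
    "mg,expected",
    [(0.0, SB), (39.999, SB), (40.0, LIPA), (99.999, LIPA), (100.0, MVPA), (250.0, MVPA)],
)
def test_cutpoint_boundaries(mg, expected):
    day = make_day([mg] * 3)
    assert np.all(classify_epochs(day) == expected)


def test_nonwear_epochs_flagged():
    day = make_day([10, 50, 150], wear=[True, False, True])
    np.testing.assert_array_equal(classify_epochs(day), [SB, features.NONWEAR, MVPA])


def test_negative_acceleration_rejected():
    with pytest.raises(ValueError):
        classify_epochs(make_day([-1.0, 5.0]))


@settings(max_examples=50, derandomize=True)
@given(
    base=st.lists(st.floats(0, 300, allow_nan=False), min_size=2, max_size=50),
    idx=st.integers(0, 49),
    bump=st.floats(0, 200, allow_nan=False),
)
def test_classification_monotone_in_acceleration(base, idx, bump):
    """Raising one epoch's acceleration never demotes its state."""
    a = np.asarray(base)
    idx = idx % a.size
    s0 = classify_epochs(make_day(a))[idx]
    a2 = a.copy()
    a2[idx] += bump
    s1 = classify_epochs(make_day(a2))[idx]
    assert s1 >= s0


# --------------------------------------------------------------------- bouts

def _bouts_oracle(seq):
    """Independent linear scan comparing neighbours."""
    out = {s: [] for s in (SB, LIPA, MVPA, features.NONWEAR)}
    run_state, run_len = seq[0], 1
    for s in seq[1:]:
        if s == run_state:
            run_len += 1
        else:
            out[run_state].append(run_len)
            run_state, run_len = s, 1
    out[run_state].append(run_len)
    return out


def test_bouts_hand_example():
    runs = bouts(np.array([SB, SB, LIPA, SB]))
    assert runs[SB].tolist() == [2, 1]
    assert runs[LIPA].tolist() == [1]
    assert runs[MVPA].tolist() == []


def test_uniform_day_single_bout():
    runs = bouts(np.zeros(960, dtype=np.int8))
    assert runs[SB].tolist() == [960]


def test_bouts_match_scan_oracle_on_random_sequences():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        seq = rng.choice([SB, LIPA, MVPA], size=rng.integers(1, 80))
        got = bouts(seq)
        want = _bouts_oracle(list(seq))
        for s in (SB, LIPA, MVPA):
            assert got[s].tolist() == want[s]


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        bouts(np.array([], dtype=np.int8))


# -------------------------------------------------------- intensity gradient

def test_loglog_fit_recovers_planted_coefficients():
    mid = (np.arange(12) + 0.5) * 25.0
    minutes = np.exp(12.4 - 2.10 * np.log(mid))
    const, grad = fit_intensity_loglog(minutes, mid)
    assert const == pytest.approx(12.4, abs=1e-9)
    assert grad == pytest.approx(-2.10, abs=1e-9)


def test_two_bins_exact_interpolation():
    mid = np.array([12.5, 37.5])
    minutes = np.array([400.0, 30.0])
    const, grad = fit_intensity_loglog(minutes, mid)
    x, y = np.log(mid), np.log(minutes)
    slope = (y[1] - y[0]) / (x[1] - x[0])
    assert grad == pytest.approx(slope, abs=1e-12)
    assert const == pytest.approx(y[0] - slope * x[0], abs=1e-12)


def test_tail_time_makes_gradient_less_negative():
    mid = (np.arange(10) + 0.5) * 25.0
    minutes = np.exp(12.0 - 2.0 * np.log(mid))
    _, g0 = fit_intensity_loglog(minutes, mid)
    bumped = minutes.copy()
    bumped[-1] *= 3.0
    _, g1 = fit_intensity_loglog(bumped, mid)
    assert g1 > g0


def test_degenerate_single_bin_errors():
    day = make_day([10.0] * 600)  # every epoch in the first 25-mg bin
    with pytest.raises(ValueError):
        intensity_regression(day)


# ------------------------------------------------------------------ M5 timing

def test_m5_exhaustive_scan_equivalence():
    rng = np.random.default_rng(1)
    for _ in range(500):
        n = int(rng.integers(300, 1100))
        day = make_day(rng.gamma(2.0, 15.0, n), start=float(rng.uniform(5, 8)))
        got = m5_timing(day)
        w = 300
        means = np.array([day.accel_mg[i : i + w].mean() for i in range(n - w + 1)])
        idx = int(np.argmax(means))
        assert got == pytest.approx(day.waking_start_hour + idx / 60.0, abs=1e-12)


def test_m5_constant_day_earliest_start():
    day = make_day(np.full(900, 25.0), start=7.0)
    assert m5_timing(day) == pytest.approx(7.0)


def test_m5_spike_window_placement():
    """A single spike at 14:00 pulls the tie-broken window to cover it first."""
    n = 960
    day = make_day(np.full(n, 20.0), start=7.0)
    spike = int((14.0 - 7.0) * 60)
    day.accel_mg[spike] = 5000.0
    got = m5_timing(day)
    # earliest 5-h window containing the spike starts 299 epochs before it
    expect = 7.0 + (spike - 299) / 60.0
    assert got == pytest.approx(expect, abs=1e-12)
    assert got <= 14.0 <= got + 5.0


def test_m5_short_day_missing():
    assert np.isnan(m5_timing(make_day(np.ones(100))))


# ------------------------------------------------------------- day features

def test_duration_conservation_and_identity():
    accel = np.concatenate([np.full(600, 10.0), np.full(300, 60.0), np.full(60, 150.0)])
    day = make_day(accel)
    f = day_features(day)
    assert f.dur_min == (600.0, 300.0, 60.0)
    assert sum(f.dur_min) == day.waking_minutes
    for d, n, m in zip(f.dur_min, f.n_bouts, f.mean_bout_min):
        if n > 0:
            assert d == pytest.approx(n * m, abs=1e-12)


def test_random_day_identities(rng):
    for _ in range(20):
        day = make_day(rng.gamma(2.0, 20.0, int(rng.integers(400, 1000))))
        f = day_features(day)
        assert sum(f.dur_min) == pytest.approx(day.waking_minutes, abs=1e-9)
        for d, n, m in zip(f.dur_min, f.n_bouts, f.mean_bout_min):
            if n > 0:
                assert d == pytest.approx(n * m, abs=1e-9)
            else:
                assert d == 0.0 and np.isnan(m)


# ---------------------------------------------------------- validity & weights

def _day_with_wear(n_worn, n_total, day_type):
    wear = np.zeros(n_total, bool)
    wear[:n_worn] = True
    return make_day(np.full(n_total, 20.0), wear=wear, day_type=day_type)


def test_inclusion_requires_two_of_each_day_type():
    five_two = [_day_with_wear(900, 900, "weekday") for _ in range(5)] + [
        _day_with_wear(900, 900, "weekend") for _ in range(2)
    ]
    assert validity_and_inclusion(five_two)[0]
    seven_one = [_day_with_wear(900, 900, "weekday") for _ in range(7)] + [
        _day_with_wear(900, 900, "weekend")
    ]
    assert not validity_and_inclusion(seven_one)[0]
    two_two = (
        [_day_with_wear(900, 900, "weekday")] * 2
        + [_day_with_wear(100, 900, "weekday")] * 3
        + [_day_with_wear(900, 900, "weekend")] * 2
    )
    assert validity_and_inclusion(two_two)[0]


def test_wear_fraction_boundary_is_two_thirds():
    ok, valid = validity_and_inclusion([_day_with_wear(666, 1000, "weekday")])
    assert valid == [False]  # 0.666 < 2/3
    ok, valid = validity_and_inclusion([_day_with_wear(667, 1000, "weekday")])
    assert valid == [True]  # 0.667 >= 2/3
    ok, valid = validity_and_inclusion([_day_with_wear(600, 900, "weekday")])
    assert valid == [True]  # exactly 2/3 counts as valid


def test_weekday_weekend_weighting():
    days = [day_features(make_day(np.full(900, 10.0), day_type="weekday")) for _ in range(5)]
    days += [day_features(make_day(np.full(900, 17.0), day_type="weekend")) for _ in range(2)]
    agg = aggregate(days)
    assert agg["Average acceleration (mg)"] == pytest.approx((5 * 10 + 2 * 17) / 7)


def test_aggregate_bounded_by_daily_extremes(rng):
    days = []
    for i in range(7):
        accel = rng.gamma(2.0, 15.0 + 3 * i, 900)
        days.append(day_features(make_day(accel, day_type="weekday" if i < 5 else "weekend")))
    agg = aggregate(days)
    for col in FEATURE_COLUMNS:
        vals = [d.as_row()[col] for d in days if np.isfinite(d.as_row()[col])]
        if vals:
            assert min(vals) - 1e-9 <= agg[col] <= max(vals) + 1e-9


# ------------------------------------------------------------------ imputation

def test_impute_noop_without_nonwear():
    day = make_day(np.full(900, 30.0))
    out = impute_nonwear(day, [])
    np.testing.assert_array_equal(out.accel_mg, day.accel_mg)


def test_impute_uses_same_clock_epoch_mean():
    wear = np.ones(900, bool)
    wear[420:480] = False  # 14:00-15:00 for a 07:00 start
    day = make_day(np.full(900, 99.0), wear=wear, start=7.0)
    others = [make_day(np.full(900, 30.0), start=7.0) for _ in range(3)]
    out = impute_nonwear(day, others)
    np.testing.assert_allclose(out.accel_mg[420:480], 30.0)
    np.testing.assert_allclose(out.accel_mg[:420], 99.0)


def test_impute_fallback_day_mean():
    wear = np.ones(600, bool)
    wear[100:160] = False
    day = make_day(np.full(600, 44.0), wear=wear)
    out = impute_nonwear(day, [])  # no other days cover the gap
    np.testing.assert_allclose(out.accel_mg[100:160], 44.0)


def test_imputed_day_durations_still_sum_to_waking(rng):
    wear = np.ones(900, bool)
    wear[500:560] = False
    day = make_day(rng.gamma(2.0, 20.0, 900), wear=wear)
    others = [make_day(rng.gamma(2.0, 20.0, 900)) for _ in range(2)]
    f = day_features(impute_nonwear(day, others))
    assert sum(f.dur_min) == pytest.approx(900.0)


def test_participant_excluded_returns_none():
    days = [_day_with_wear(900, 900, "weekday") for _ in range(7)]
    assert participant_features(days) is None
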