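"""Synthetic accelerometer cohorts with planted movement-behaviour archetypes.

Generates epoch-level (default 60 s) wrist-acceleration series, in milligravity
(mg), for a cohort of older adults over a 7-day week (5 weekdays + 2 weekend
days), together with a linked survival table.  Each participant belongs to one
of a set of behaviour *archetypes*; an archetype fixes the semi-Markov bout
process (sedentary behaviour SB / light activity LIPA / moderate-to-vigorous
activity MVPA), the per-state acceleration-intensity distributions, the diurnal
placement of activity, and a log hazard ratio for all-cause mortality.

Because the archetype of every participant is known, every downstream stage
(feature extraction, clustering, Cox regression) can be tested as a
planted-truth recovery problem.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STATES = ("SB", "LIPA", "MVPA")

#: amplitude of the multiplicative raised-cosine diurnal modulation applied to
#: non-sedentary epoch intensities.
DIURNAL_AMPLITUDE = 0.30

#: between-participant heterogeneity (lognormal coefficients of variation):
#: participants of one archetype are not identical, they jitter around the
#: archetype parameters.
PARTICIPANT_CV_BOUT = 0.10
PARTICIPANT_CV_INTENSITY = 0.08
PARTICIPANT_SD_WAKING_MIN = 25.0

#: day-to-day jitter of the waking-window length (minutes).
DAY_SD_WAKING_MIN = 20.0

#: conditional log hazard ratios of the simulated covariates (the archetype
#: log_hazard values are *conditional* effects on top of these).
COVARIATE_LOG_HR = {
    "female": -0.35,
    "smoker": 0.45,
    "diabetes": 0.30,
    "obese": 0.20,
    "hypertension": 0.15,
    "morbidity_count": 0.25,
}

SOCIODEMOGRAPHIC = ["female", "nonwhite", "married", "higher_edu", "low_occupation"]
LIFESTYLE = ["smoker", "alcohol_gt14", "fruitveg_daily"]
HEALTH = ["obese", "hypertension", "hyperlipidaemia", "diabetes", "morbidity_count"]
COVARIATE_COLUMNS = SOCIODEMOGRAPHIC + LIFESTYLE + HEALTH

# Covariate prevalences by archetype (column fractions; morbidity_count is a
# Poisson mean).  Loosely calibrated to the sociodemographic gradient across
# profiles seen in wrist-accelerometer cohorts of older adults, so that the
# sequential confounder adjustment in the association stage is exercised.
_PREVALENCES = {
    #                 active  act.sit  light   prol.   most.sed
    "female":        (0.295, 0.152, 0.325, 0.240, 0.315),
    "nonwhite":      (0.058, 0.044, 0.071, 0.091, 0.152),
    "married":       (0.773, 0.766, 0.767, 0.735, 0.603),
    "higher_edu":    (0.302, 0.387, 0.271, 0.306, 0.255),
    "low_occupation": (0.510, 0.424, 0.544, 0.517, 0.609),
    "smoker":        (0.040, 0.046, 0.048, 0.064, 0.113),
    "alcohol_gt14":  (0.273, 0.261, 0.226, 0.213, 0.136),
    "fruitveg_daily": (0.806, 0.835, 0.798, 0.756, 0.752),
    "obese":         (0.087, 0.121, 0.185, 0.250, 0.334),
    "hypertension":  (0.395, 0.435, 0.508, 0.624, 0.722),
    "hyperlipidaemia": (0.424, 0.453, 0.523, 0.565, 0.603),
    "diabetes":      (0.068, 0.076, 0.126, 0.188, 0.238),
    "morbidity_count": (0.40, 0.40, 0.60, 0.60, 0.90),
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters of one planted movement-behaviour profile.

    ``state_entry_probs`` drives a semi-Markov chain over (SB, LIPA, MVPA) with
    no immediate self-transition (so a bout is a well-defined maximal run);
    bout durations are lognormal with per-state mean ``bout_mean_minutes`` and
    log-scale SD ``bout_dispersion``; epoch accelerations are lognormal with
    per-state median ``intensity_median_mg`` and log-scale SD
    ``intensity_sigma``, modulated diurnally so that the start of the most
    active 5 hours recovers ``diurnal_peak_hour``.  ``log_hazard`` is the
    conditional log hazard ratio for mortality versus the reference archetype.
    """

    name: str
    mix_fraction: float
    state_entry_probs: tuple[float, float, float]
    bout_mean_minutes: tuple[float, float, float]
    bout_dispersion: tuple[float, float, float]
    intensity_median_mg: tuple[float, float, float]
    intensity_sigma: tuple[float, float, float]
    diurnal_peak_hour: float
    waking_minutes: float
    log_hazard: float

    def validate(self, cutpoints: tuple[float, float] = (40.0, 100.0)) -> None:
        p = np.asarray(self.state_entry_probs, float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: state_entry_probs must be a probability vector")
        if min(self.bout_mean_minutes) <= 0:
            raise ValueError(f"{self.name}: bout_mean_minutes must be > 0")
        sb, lipa, mvpa = self.intensity_median_mg
        lo, hi = cutpoints
        if not (sb < lipa < mvpa):
            raise ValueError(f"{self.name}: intensity medians must be ordered SB < LIPA < MVPA")
        if not (sb < lo and lo <= lipa < hi and mvpa >= hi):
            raise ValueError(
                f"{self.name}: intensity medians must fall inside the state cut-point intervals"
            )
        if not 0.0 <= self.mix_fraction <= 1.0:
            raise ValueError(f"{self.name}: mix_fraction outside [0, 1]")


def default_archetypes() -> list[ArchetypeSpec]:
    """The five default archetypes.

    Entry probabilities are proportional to the per-profile daily bout counts,
    bout means / waking lengths are the per-profile means, and intensity
    medians are set so that the implied overall activity level spans the
    observed 17-45 mg range across profiles.  Hazards span 1x to 3.25x.
    """
    rows = [
        # name, mix, (nSB,nLIPA,nMVPA), (SB,LIPA,MVPA bout mins), medians, m5, waking, HR
        ("active", 0.182, (84.3, 112.6, 42.1), (7.3, 2.6, 2.5), (18.0, 60.0, 135.0), 10.4, 986.6, 1.0),
        ("active_sitters", 0.223, (68.0, 83.1, 26.6), (11.2, 2.3, 3.2), (14.0, 60.0, 150.0), 10.3, 981.1, 1.57),
        ("light_movers", 0.259, (82.8, 96.7, 22.4), (8.9, 2.6, 1.9), (15.0, 60.0, 140.0), 10.2, 989.7, 1.75),
        ("prolonged_sitters", 0.260, (63.4, 70.7, 13.5), (13.5, 2.3, 2.0), (14.0, 55.0, 135.0), 10.1, 981.2, 1.67),
        ("most_sedentary", 0.076, (44.7, 46.4, 4.5), (24.4, 2.0, 1.4), (13.0, 52.0, 125.0), 10.2, 980.0, 3.25),
    ]
    specs = []
    for name, mix, counts, bouts, med, peak, waking, hr in rows:
        counts = np.asarray(counts, float)
        specs.append(
            ArchetypeSpec(
                name=name,
                mix_fraction=mix,
                state_entry_probs=tuple(counts / counts.sum()),
                bout_mean_minutes=bouts,
                bout_dispersion=(1.0, 0.6, 0.6),
                intensity_median_mg=med,
                intensity_sigma=(0.35, 0.18, 0.22),
                diurnal_peak_hour=peak,
                waking_minutes=waking,
                log_hazard=float(np.log(hr)),
            )
        )
    for s in specs:
        s.validate()
    return specs


@dataclass
class CohortConfig:
    """Cohort-level simulation settings (plumbing around the archetypes)."""

    n_participants: int = 1000
    n_days: int = 7
    epoch_seconds: int = 60
    seed: int = 0
    archetypes: list[ArchetypeSpec] = field(default_factory=default_archetypes)
    entry_age_mean: float = 69.4
    entry_age_sd: float = 5.7
    followup_horizon_years: float = 8.1
    baseline_hazard: float = 0.00607  # events / person-year for the reference archetype
    nonwear_prob: float = 0.08
    nonwear_minutes: float = 90.0
    waking_start_hour: float = 6.5
    covariate_hazards: bool = True

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if 3600 % self.epoch_seconds != 0:
            raise ValueError("epoch_seconds must divide 3600")
        if self.followup_horizon_years <= 0:
            raise ValueError("followup_horizon_years must be > 0")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be >= 0")
        mix = sum(a.mix_fraction for a in self.archetypes)
        if abs(mix - 1.0) > 1e-6:
            raise ValueError(f"archetype mix_fractions sum to {mix}, expected 1")
        for a in self.archetypes:
            a.validate()


@dataclass
class EpochDay:
    """One participant-day of epoch accelerations within the waking window."""

    participant_id: str
    date: _dt.date
    day_type: str  # "weekday" | "weekend"
    waking_start_hour: float
    epoch_seconds: int
    accel_mg: np.ndarray
    wear: np.ndarray

    @property
    def n_epochs(self) -> int:
        return int(self.accel_mg.size)

    @property
    def waking_minutes(self) -> float:
        return self.n_epochs * self.epoch_seconds / 60.0

    @property
    def clock_hours(self) -> np.ndarray:
        """Clock hour at the midpoint of each epoch."""
        step = self.epoch_seconds / 3600.0
        return self.waking_start_hour + (np.arange(self.n_epochs) + 0.5) * step

    @property
    def wear_fraction(self) -> float:
        return float(np.mean(self.wear))


def _bout_states(rng: np.random.Generator, probs: np.ndarray, n: int, last: int) -> np.ndarray:
    """Draw ``n`` categorical states and collapse consecutive repeats.

    Keeping the first draw of every run of an i.i.d. categorical sequence
    yields exactly the no-self-transition chain with transition probabilities
    p_j / (1 - p_i).
    """
    s = rng.choice(len(probs), size=n, p=probs)
    keep = np.empty(n, dtype=bool)
    keep[0] = s[0] != last
    keep[1:] = s[1:] != s[:-1]
    return s[keep]


def simulate_day(
    archetype: ArchetypeSpec,
    day_type: str,
    rng: np.random.Generator,
    *,
    epoch_seconds: int = 60,
    nonwear_prob: float = 0.0,
    nonwear_minutes: float = 90.0,
    waking_start_hour: float = 6.5,
    participant_id: str = "p0",
    date: _dt.date | None = None,
) -> EpochDay:
    """Simulate one waking day as alternating SB/LIPA/MVPA bouts.

    The waking window is tiled exactly by bouts of a semi-Markov chain (state
    from ``state_entry_probs`` with no immediate self-transition; lognormal
    duration rounded up to whole epochs, last bout truncated at the window
    end).  Epoch accelerations are lognormal per state; non-SB epochs are
    multiplied by a raised-cosine diurnal factor whose maximum sits 2.5 h after
    ``diurnal_peak_hour``, so that the most-active-5-hours start is a
    recoverable planted parameter.  With probability ``nonwear_prob`` one
    contiguous block is flagged as non-wear.
    """
    epochs_per_minute = 60.0 / epoch_seconds
    if archetype.waking_minutes * epochs_per_minute < 2:
        raise ValueError("waking window must span at least 2 epochs")

    waking_min = archetype.waking_minutes + rng.normal(0.0, DAY_SD_WAKING_MIN)
    n_epochs = max(int(round(waking_min * epochs_per_minute)), 2)
    start_hour = waking_start_hour + (0.75 if day_type == "weekend" else 0.0) + rng.normal(0.0, 0.25)

    probs = np.asarray(archetype.state_entry_probs, float)
    means = np.asarray(archetype.bout_mean_minutes, float)
    sigmas = np.asarray(archetype.bout_dispersion, float)
    # continuity correction: ceil-discretisation adds ~0.5 epoch on average,
    # so target the continuous mean at (mean - 0.5) to honour the
    # bout_mean_minutes contract after rounding.
    cont_mean = np.maximum(means - 0.5 / epochs_per_minute, 0.25)
    mu = np.log(cont_mean) - sigmas**2 / 2.0

    exp_bout_epochs = float(probs @ (means * epochs_per_minute))
    states_parts: list[np.ndarray] = []
    dur_parts: list[np.ndarray] = []
    total = 0
    last = -1
    while total < n_epochs:
        m = max(16, int(1.6 * (n_epochs - total) / exp_bout_epochs) + 8)
        s = _bout_states(rng, probs, m, last)
        if s.size == 0:  # degenerate single-state chain: continue the run
            s = np.array([last])
        d = np.ceil(
            np.exp(mu[s] + sigmas[s] * rng.standard_normal(s.size)) * epochs_per_minute
        ).astype(np.int64)
        states_parts.append(s)
        dur_parts.append(d)
        total += int(d.sum())
        last = int(s[-1])
    states = np.concatenate(states_parts)
    durs = np.concatenate(dur_parts)
    epoch_state = np.repeat(states, durs)[:n_epochs]

    med = np.asarray(archetype.intensity_median_mg, float)
    isig = np.asarray(archetype.intensity_sigma, float)
    accel = med[epoch_state] * np.exp(isig[epoch_state] * rng.standard_normal(n_epochs))

    step = epoch_seconds / 3600.0
    clock = start_hour + (np.arange(n_epochs) + 0.5) * step
    centre = archetype.diurnal_peak_hour + 2.5
    factor = 1.0 + DIURNAL_AMPLITUDE * np.cos(2.0 * np.pi * (clock - centre) / 24.0)
    nonsb = epoch_state != 0
    accel[nonsb] *= factor[nonsb]

    wear = np.ones(n_epochs, dtype=bool)
    if nonwear_prob > 0 and rng.random() < nonwear_prob:
        block = min(int(round(nonwear_minutes * epochs_per_minute)), n_epochs - 1)
        if block > 0:
            start = int(rng.integers(0, n_epochs - block + 1))
            wear[start : start + block] = False

    return EpochDay(
        participant_id=participant_id,
        date=date or _dt.date(2013, 1, 7),
        day_type=day_type,
        waking_start_hour=float(start_hour),
        epoch_seconds=epoch_seconds,
        accel_mg=accel,
        wear=wear,
    )


def _personalize(archetype: ArchetypeSpec, rng: np.random.Generator) -> ArchetypeSpec:
    """Jitter archetype parameters per participant (mean-one lognormal)."""
    def ln(cv: float, size: int) -> np.ndarray:
        s = np.sqrt(np.log1p(cv**2))
        return np.exp(rng.normal(-s**2 / 2.0, s, size))

    bm = tuple(np.asarray(archetype.bout_mean_minutes) * ln(PARTICIPANT_CV_BOUT, 3))
    im = np.asarray(archetype.intensity_median_mg) * ln(PARTICIPANT_CV_INTENSITY, 3)
    # keep medians inside their cut-point intervals so the spec invariant holds
    im = np.clip(im, [1.0, 40.0, 100.0], [39.0, 99.0, np.inf])
    return replace(
        archetype,
        bout_mean_minutes=bm,
        intensity_median_mg=tuple(im),
        waking_minutes=max(archetype.waking_minutes + rng.normal(0.0, PARTICIPANT_SD_WAKING_MIN), 330.0),
        diurnal_peak_hour=archetype.diurnal_peak_hour + rng.normal(0.0, 0.5),
    )


def simulate_covariates(
    archetype_names: pd.Series, archetypes: list[ArchetypeSpec], rng: np.random.Generator
) -> pd.DataFrame:
    """Binary/count covariates with archetype-dependent prevalences."""
    # rank archetypes by implied overall activity (descending) to index the
    # prevalence table; unknown names fall back to the cohort-average column.
    order = sorted(
        range(len(archetypes)),
        key=lambda i: -(np.asarray(archetypes[i].state_entry_probs) @ np.asarray(archetypes[i].intensity_median_mg)),
    )
    rank_of = {archetypes[i].name: r for r, i in enumerate(order)}
    n = len(archetype_names)
    out = {}
    for cov, prev in _PREVALENCES.items():
        prev = np.asarray(prev, float)
        idx = np.array([rank_of.get(a, -1) for a in archetype_names])
        p = np.where(idx >= 0, prev[np.clip(idx, 0, len(prev) - 1)], prev.mean())
        if cov == "morbidity_count":
            out[cov] = np.minimum(rng.poisson(p), 4)
        else:
            out[cov] = (rng.random(n) < p).astype(np.int64)
    return pd.DataFrame(out, index=archetype_names.index)


def simulate_survival(
    participants: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential age-scale survival with administrative censoring.

    The hazard for a participant is ``baseline_hazard * exp(archetype
    log_hazard + covariate effects)``, constant in age; follow-up starts at
    ``entry_age_years`` (left truncation downstream) and is censored at
    ``entry_age + followup_horizon_years``.
    """
    config.validate()
    log_hr = {a.name: a.log_hazard for a in config.archetypes}
    eta = participants["true_archetype"].map(log_hr).to_numpy(float)
    if config.covariate_hazards:
        for cov, beta in COVARIATE_LOG_HR.items():
            if cov in participants:
                eta = eta + beta * participants[cov].to_numpy(float)
    rate = config.baseline_hazard * np.exp(eta)
    if np.any(rate < 0):
        raise ValueError("negative hazard")
    t = rng.exponential(1.0, size=len(participants)) / np.maximum(rate, 1e-300)
    horizon = config.followup_horizon_years
    event = t < horizon
    out = participants.copy()
    out["event_flag"] = event.astype(np.int64)
    out["event_age_years"] = out["entry_age_years"] + np.minimum(t, horizon)
    return out


def simulate_cohort(config: CohortConfig) -> tuple[dict[str, list[EpochDay]], pd.DataFrame]:
    """Simulate a full cohort: epoch days per participant plus a truth table.

    Returns ``(days, truth)`` where ``days`` maps participant id to its list of
    ``n_days`` EpochDay objects (5 weekday + 2 weekend labels per week) and
    ``truth`` has one row per participant with the planted archetype, entry and
    event ages, event flag and simulated covariates.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(config.n_participants + 2)

    mix = np.array([a.mix_fraction for a in config.archetypes])
    arch_idx = master.choice(len(config.archetypes), size=config.n_participants, p=mix)
    entry_age = np.clip(
        master.normal(config.entry_age_mean, config.entry_age_sd, config.n_participants),
        60.0,
        83.0,
    )

    monday = _dt.date(2013, 1, 7)
    day_types = ["weekday"] * 5 + ["weekend"] * 2
    days: dict[str, list[EpochDay]] = {}
    pids = [f"p{i:05d}" for i in range(config.n_participants)]
    for i, pid in enumerate(pids):
        rng = np.random.default_rng(child_seeds[i])
        person = _personalize(config.archetypes[arch_idx[i]], rng)
        days[pid] = [
            simulate_day(
                person,
                day_types[d % 7],
                rng,
                epoch_seconds=config.epoch_seconds,
                nonwear_prob=config.nonwear_prob,
                nonwear_minutes=config.nonwear_minutes,
                waking_start_hour=config.waking_start_hour,
                participant_id=pid,
                date=monday + _dt.timedelta(days=d),
            )
            for d in range(config.n_days)
        ]

    truth = pd.DataFrame(
        {
            "participant_id": pids,
            "true_archetype": [config.archetypes[j].name for j in arch_idx],
            "entry_age_years": entry_age,
        }
    ).set_index("participant_id")
    cov_rng = np.random.default_rng(child_seeds[-2])
    truth = truth.join(simulate_covariates(truth["true_archetype"], config.archetypes, cov_rng))
    surv_rng = np.random.default_rng(child_seeds[-1])
    truth = simulate_survival(truth, config, surv_rng)
    return days, truth


def simulate_survival_cohort(config: CohortConfig) -> pd.DataFrame:
    """Truth table only (no epoch data): archetypes, covariates, survival.

    Fast path for studying the association stage in isolation; the returned
    frame carries a ``profile`` column equal to the true archetype.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    mix = np.array([a.mix_fraction for a in config.archetypes])
    idx = master.choice(len(config.archetypes), size=config.n_participants, p=mix)
    entry_age = np.clip(
        master.normal(config.entry_age_mean, config.entry_age_sd, config.n_participants),
        60.0,
        83.0,
    )
    truth = pd.DataFrame(
        {
            "participant_id": [f"p{i:05d}" for i in range(config.n_participants)],
            "true_archetype": [config.archetypes[j].name for j in idx],
            "entry_age_years": entry_age,
        }
    ).set_index("participant_id")
    cov_rng, surv_rng = (np.random.default_rng(s) for s in ss.spawn(3)[1:])
    truth = truth.join(simulate_covariates(truth["true_archetype"], config.archetypes, cov_rng))
    truth = simulate_survival(truth, config, surv_rng)
    truth["profile"] = truth["true_archetype"]
    return truth


# ---------------------------------------------------------------------------
# CSV interchange

def epochs_to_frame(days: dict[str, list[EpochDay]]) -> pd.DataFrame:
    """Long epoch table: one row per epoch (the on-disk dialect)."""
    frames = []
    for pid, dlist in days.items():
        for day in dlist:
            n = day.n_epochs
            t0 = day.waking_start_hour * 3600.0
            secs = t0 + np.arange(n) * day.epoch_seconds
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "date": day.date.isoformat(),
                        "day_type": day.day_type,
                        "epoch_index": np.arange(n),
                        "epoch_start_clock_time": [
                            f"{int(s // 3600):02d}:{int(s % 3600 // 60):02d}:{int(s % 60):02d}"
                            for s in secs
                        ],
                        "accel_mg": np.round(day.accel_mg, 3),
                        "wear_flag": day.wear.astype(int),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def frame_to_days(frame: pd.DataFrame) -> dict[str, list[EpochDay]]:
    """Inverse of :func:`epochs_to_frame`."""
    days: dict[str, list[EpochDay]] = {}
    for (pid, date), g in frame.groupby(["participant_id", "date"], sort=True):
        g = g.sort_values("epoch_index")
        h, m, s = (int(x) for x in str(g["epoch_start_clock_time"].iloc[0]).split(":"))
        start_hour = h + m / 60.0 + s / 3600.0
        times = [str(t) for t in g["epoch_start_clock_time"]]
        t0 = h * 3600 + m * 60 + s
        h1, m1, s1 = (int(x) for x in times[1].split(":")) if len(times) > 1 else (h, m, s + 60)
        epoch_seconds = (h1 * 3600 + m1 * 60 + s1) - t0 if len(times) > 1 else 60
        days.setdefault(str(pid), []).append(
            EpochDay(
                participant_id=str(pid),
                date=_dt.date.fromisoformat(str(date)),
                day_type=str(g["day_type"].iloc[0]),
                waking_start_hour=start_hour,
                epoch_seconds=int(epoch_seconds),
                accel_mg=g["accel_mg"].to_numpy(float),
                wear=g["wear_flag"].to_numpy().astype(bool),
            )
        )
    return days
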