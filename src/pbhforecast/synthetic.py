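"""Synthetic post-bariatric-hypoglycaemia CGM cohorts with ground-truth events.

Clinical PBH datasets are rarely shareable, so the pipeline ships a
generator that emulates the statistical fingerprint of a PBH cohort: a
stable basal glucose near 100 mg/dL, rapid meal-induced excursions (rises of
60-140 mg/dL peaking 30-60 min after intake), and — after a fraction of
meals — the hallmark sharp drop below 54 mg/dL occurring 90-150 min
post-meal and lasting tens of minutes.  AR(1) sensor noise and random data
gaps reproduce the real-world nuisances the preprocessing stage must handle.

Each simulated subject comes with a ground-truth log (meal times and the
hypoglycaemic intervals present in the noise-free signal) so that episode
detection, alarm matching and the end-to-end pipeline can be tested against
a known answer.  All randomness derives from ``(config.seed, subject_seed)``;
there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .cgm_data import MISSING, OBSERVED, CGMTrace
from .forecasters import MAX_HORIZON_STEPS, ForecastVector

SLOTS_PER_DAY = 288
STEP_MIN = 5.0

# Default daytime meal windows (minutes of day): breakfast, lunch, snack, dinner.
MEAL_WINDOWS_MIN = ((420, 540), (660, 780), (900, 1020), (1110, 1230))


@dataclass
class SimConfig:
    """Parameters of the synthetic PBH-CGM generator.

    Rates and ranges mirror the published cohort: ~4 Level-2 episodes per 10
    subject-days (4 meals/day x 0.10 dip probability), dips 90-150 min
    post-meal reaching 5-15 mg/dL below the 54 mg/dL threshold for 15-35 min,
    basal glucose ~100 mg/dL and ~39 monitoring days per subject.
    """

    n_subjects: int = 47
    days_per_subject: float = 39.0
    meals_per_day: int = 4
    pbh_prob_per_meal: float = 0.10
    basal_mean: float = 100.0
    basal_sd: float = 7.0
    basal_halflife_min: float = 120.0
    rise_amplitude: tuple[float, float] = (60.0, 140.0)
    time_to_peak_min: tuple[float, float] = (30.0, 60.0)
    fall_time_min: float = 45.0  # post-peak return time for uneventful meals
    dip_delay_min: tuple[float, float] = (90.0, 150.0)
    dip_depth: tuple[float, float] = (5.0, 15.0)
    dip_duration_min: tuple[float, float] = (15.0, 35.0)
    dip_entry_min: float = 15.0
    dip_exit_min: float = 20.0
    noise_sd: float = 3.0
    noise_ar1: float = 0.7
    gap_rate_per_day: float = 0.3
    gap_length_min: tuple[float, float] = (10.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pbh_prob_per_meal <= 1.0:
            raise ValueError("pbh_prob_per_meal must lie in [0, 1]")
        for name in ("days_per_subject", "dip_entry_min", "dip_exit_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Generator-side truth: meal times and pre-noise hypoglycaemic intervals."""

    meal_times_min: list[float]
    intended_episodes: list[tuple[int, int]]  # (onset, end) grid indices


def _subject_rng(config: SimConfig, subject_seed: int) -> np.random.Generator:
    # (cohort seed, subject seed) fully determine the stream; subject order
    # in the cohort is irrelevant.
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, int(subject_seed)])
    )


def _meal_excursion(
    t_min: np.ndarray, start: float, amplitude: float, tp: float, fall: float
) -> np.ndarray:
    """Half-cosine rise to ``amplitude`` over ``tp`` min, half-cosine fall."""
    x = t_min - start
    out = np.zeros_like(t_min)
    rise = (x >= 0) & (x < tp)
    out[rise] = amplitude * 0.5 * (1 - np.cos(np.pi * x[rise] / tp))
    falling = (x >= tp) & (x < tp + fall)
    out[falling] = amplitude * 0.5 * (1 + np.cos(np.pi * (x[falling] - tp) / fall))
    return out


def simulate_subject(config: SimConfig, subject_seed: int) -> tuple[CGMTrace, GroundTruth]:
    """One subject's trace: basal process + meal kernels + PBH dips + noise + gaps.

    The deterministic signal (basal mean-reversion, meal excursions, dip
    overwrites) is built first and thresholded at 54 mg/dL to log the
    intended episodes; AR(1) sensor noise and gap masking are applied
    afterwards, so the ground truth refers to the pre-noise trajectory.
    """
    rng = _subject_rng(config, subject_seed)
    n = int(round(config.days_per_subject * SLOTS_PER_DAY))
    t_min = np.arange(n) * STEP_MIN

    # Basal: first-order mean-reverting process around basal_mean.
    signal = np.full(n, config.basal_mean)
    if config.basal_sd > 0:
        a = float(np.exp(-STEP_MIN * np.log(2.0) / config.basal_halflife_min))
        innov = rng.normal(0.0, config.basal_sd * np.sqrt(1 - a * a), size=n)
        basal = lfilter([1.0], [1.0, -a], innov)
        signal = signal + basal

    # Meals and their excursions; a fraction of meals carry a delayed dip.
    n_days = int(np.ceil(config.days_per_subject))
    meal_times: list[float] = []
    dips: list[tuple[float, float, float]] = []  # (start_min, depth, duration)
    for day in range(n_days):
        if config.meals_per_day == len(MEAL_WINDOWS_MIN):
            windows = MEAL_WINDOWS_MIN
        else:
            windows = tuple(
                (420.0 + k * 840.0 / max(config.meals_per_day, 1),) * 2
                for k in range(config.meals_per_day)
            )
        for win in windows[: config.meals_per_day]:
            start = day * 1440.0 + rng.uniform(win[0], win[1])
            if start >= t_min[-1]:
                continue
            meal_times.append(start)
            amplitude = rng.uniform(*config.rise_amplitude)
            tp = rng.uniform(*config.time_to_peak_min)
            is_pbh = rng.random() < config.pbh_prob_per_meal
            if is_pbh:
                delay = rng.uniform(*config.dip_delay_min)
                fall = max(30.0, delay - tp)
                depth = rng.uniform(*config.dip_depth)
                duration = rng.uniform(*config.dip_duration_min)
                dips.append((start + delay, depth, duration))
            else:
                fall = config.fall_time_min
            lo = max(0, int(start / STEP_MIN))
            hi = min(n, int(np.ceil((start + tp + fall) / STEP_MIN)) + 1)
            signal[lo:hi] += _meal_excursion(t_min[lo:hi], start, amplitude, tp, fall)

    # Dips overwrite the trajectory: cosine descent to (54 - depth), hold,
    # cosine recovery back to the surrounding signal.
    for start, depth, duration in dips:
        nadir = 54.0 - depth
        d0 = int(round(start / STEP_MIN))
        entry = int(round(config.dip_entry_min / STEP_MIN))
        # the ramps spend ~1 slot below threshold, so shorten the hold to keep
        # the total sub-54 time tracking the drawn duration; never go below the
        # 15-min episode minimum (drawn durations are always >= 15 min)
        hold = max(3, int(round(duration / STEP_MIN)) - 1)
        exit_ = int(round(config.dip_exit_min / STEP_MIN))
        end = d0 + entry + hold + exit_
        if d0 < 1 or end >= n:
            continue
        top_in = signal[d0]
        top_out = max(signal[end], 70.0)
        for k in range(1, entry + 1):
            frac = 0.5 * (1 - np.cos(np.pi * k / entry))
            signal[d0 + k] = top_in + (nadir - top_in) * frac
        signal[d0 + entry : d0 + entry + hold] = nadir
        for k in range(1, exit_ + 1):
            frac = 0.5 * (1 - np.cos(np.pi * k / exit_))
            signal[d0 + entry + hold - 1 + k] = nadir + (top_out - nadir) * frac

    signal = np.clip(signal, 40.0, 400.0)

    # Ground-truth hypoglycaemic intervals on the pre-noise signal.
    below = signal < 54.0
    episodes: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            episodes.append((i, j - 1))
            i = j
        else:
            i += 1

    # AR(1) sensor noise with stationary SD noise_sd.
    values = signal.copy()
    if config.noise_sd > 0:
        rho = config.noise_ar1
        w = rng.normal(0.0, config.noise_sd * np.sqrt(1 - rho * rho), size=n)
        noise = lfilter([1.0], [1.0, -rho], w)
        values = np.clip(values + noise, 40.0, 400.0)

    status = np.full(n, OBSERVED, dtype=np.uint8)
    n_gaps = rng.poisson(config.gap_rate_per_day * config.days_per_subject)
    for _ in range(n_gaps):
        g0 = int(rng.integers(0, n))
        g_len = int(np.ceil(rng.uniform(*config.gap_length_min) / STEP_MIN))
        status[g0 : g0 + g_len] = MISSING
    values = values.copy()
    values[status == MISSING] = np.nan

    trace = CGMTrace(
        subject_id=f"sim-{subject_seed:04d}",
        t0=0.0,
        values=values,
        status=status,
    )
    return trace, GroundTruth(meal_times_min=meal_times, intended_episodes=episodes)


def simulate_cohort(config: SimConfig) -> list[tuple[CGMTrace, GroundTruth]]:
    """Independent subjects with per-subject seeds 0..n-1 (order-invariant)."""
    return [simulate_subject(config, i) for i in range(config.n_subjects)]


def clairvoyant_forecaster(
    trace: CGMTrace, steps: int = MAX_HORIZON_STEPS
) -> list[ForecastVector]:
    """Oracle forecaster: yhat(t + 5k | t) = y(t + 5k), for end-to-end tests.

    Requires a fully observed trace; forecasts exist at every origin whose
    whole horizon lies inside the trace.
    """
    if trace.missing_mask.any():
        raise ValueError("clairvoyant forecasts require a fully observed trace")
    out = []
    for t in range(len(trace) - steps):
        out.append(
            ForecastVector(origin_index=t, predicted=trace.values[t + 1 : t + steps + 1])
        )
    return out
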