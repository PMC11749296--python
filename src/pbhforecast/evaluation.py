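"""Event extraction, alarm-event matching and all reported performance metrics.

Evaluation is *event-based*: what matters clinically is whether an episode of
Level-2 hypoglycaemia (sensor glucose < 54 mg/dL) was announced in time, not
point-wise prediction accuracy.  The matching rule:

* an alarm is a **true positive** if an episode onset occurs within the 45 min
  following it, a **false positive** otherwise;
* an episode is a **false negative** if no alarm was raised in the 45 min
  before its onset;
* the **time gain** of a detected episode is the interval between its onset
  and the earliest alarm in that 45-min pre-window — the time available for
  preventive action (fast carbohydrates, mini-dose glucagon).

Precision counts alarms, Recall counts episodes; the two denominators differ
by design and the asymmetry is intentional.  Forecast accuracy is summarized
separately by the mean absolute error at each prediction horizon, and cohort
descriptive statistics (time-in-range, MAGE, episode counts) are provided for
characterizing datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .alarm_engine import LEVEL2_THRESHOLD_MGDL, AlarmRecord
from .cgm_data import GRID_STEP_MIN, OBSERVED, CGMTrace
from .forecasters import ForecastVector

MATCH_WINDOW_MIN = 45.0


@dataclass(frozen=True)
class HypoEpisode:
    """A Level-2 hypoglycaemic event: onset/end grid indices (inclusive)."""

    onset: int
    end: int

    @property
    def duration_min(self) -> float:
        return (self.end - self.onset + 1) * GRID_STEP_MIN

    @property
    def onset_min(self) -> float:
        return self.onset * GRID_STEP_MIN


@dataclass
class MatchResult:
    """Outcome of alarm-event matching over one evaluated segment."""

    tp_alarms: int
    fp_alarms: int
    fn_events: int
    detected_events: int
    time_gains: list[float] = field(default_factory=list)
    monitored_days: float = float("nan")

    @property
    def total_alarms(self) -> int:
        return self.tp_alarms + self.fp_alarms

    @property
    def total_events(self) -> int:
        return self.detected_events + self.fn_events

    def merged_with(self, other: "MatchResult") -> "MatchResult":
        """Pool counts across subjects/segments (population-level metrics)."""
        days = np.nansum([self.monitored_days, other.monitored_days])
        return MatchResult(
            tp_alarms=self.tp_alarms + other.tp_alarms,
            fp_alarms=self.fp_alarms + other.fp_alarms,
            fn_events=self.fn_events + other.fn_events,
            detected_events=self.detected_events + other.detected_events,
            time_gains=self.time_gains + other.time_gains,
            monitored_days=float(days),
        )


def detect_episodes(
    trace: CGMTrace,
    threshold: float = LEVEL2_THRESHOLD_MGDL,
    min_duration_min: float = 15.0,
    merge_gap_min: float = 15.0,
) -> list[HypoEpisode]:
    """Extract Level-2 episodes as maximal runs of samples below ``threshold``.

    Missing samples never count as hypoglycaemic.  Runs separated by less
    than ``merge_gap_min`` of at-or-above-threshold samples are merged into
    one event (brief sensor rebounds do not end an episode), and merged
    events whose total span is shorter than ``min_duration_min`` are
    discarded.  Note a merged episode may contain >= threshold samples
    inside its span.
    """
    below = np.where(np.isfinite(trace.values), trace.values < threshold, False)
    runs: list[list[int]] = []
    i, n = 0, len(trace)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            runs.append([i, j - 1])
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) * GRID_STEP_MIN < merge_gap_min:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [
        HypoEpisode(onset=a, end=b)
        for a, b in merged
        if (b - a + 1) * GRID_STEP_MIN >= min_duration_min
    ]


def match_alarms(
    alarms: Sequence[AlarmRecord],
    episodes: Sequence[HypoEpisode],
    window_min: float = MATCH_WINDOW_MIN,
    monitored_days: float = float("nan"),
) -> MatchResult:
    """Label alarms TP/FP and episodes detected/missed under the 45-min window.

    An alarm at time s is TP iff some onset lies in (s, s + window]; an
    episode is detected iff some alarm lies in [onset - window, onset); its
    time gain is onset minus the *earliest* such alarm.  Labels are written
    onto the alarm records in place (each exactly once).
    """
    onset_min = np.array([e.onset_min for e in episodes])
    tp = fp = 0
    for alarm in sorted(alarms, key=lambda a: a.time):
        s = alarm.time_min
        hit = bool(np.any((onset_min > s) & (onset_min <= s + window_min)))
        alarm.label = "TP" if hit else "FP"
        tp += hit
        fp += not hit
    alarm_min = np.array(sorted(a.time_min for a in alarms))
    detected = 0
    gains: list[float] = []
    for o in onset_min:
        in_win = alarm_min[(alarm_min >= o - window_min) & (alarm_min < o)]
        if in_win.size:
            detected += 1
            gains.append(float(o - in_win.min()))
    return MatchResult(
        tp_alarms=int(tp),
        fp_alarms=int(fp),
        fn_events=len(episodes) - detected,
        detected_events=detected,
        time_gains=gains,
        monitored_days=monitored_days,
    )


class PRF1(NamedTuple):
    precision: float
    recall: float
    f1: float
    degenerate: bool  # some denominator was zero and the metric was set to 0


def precision_recall_f1(match: MatchResult) -> PRF1:
    """Precision/Recall/F1 in percent.

    Precision is alarm-wise (TP alarms over all alarms); Recall is event-wise
    (detected episodes over all episodes); F1 is their harmonic mean.  Any
    zero denominator yields 0 with the ``degenerate`` flag set.
    """
    degenerate = False
    if match.total_alarms:
        precision = 100.0 * match.tp_alarms / match.total_alarms
    else:
        precision, degenerate = 0.0, True
    if match.total_events:
        recall = 100.0 * match.detected_events / match.total_events
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return PRF1(precision, recall, f1, degenerate)


def fp_per_day(match: MatchResult) -> float:
    """False alarms per monitored day (calendar span, regardless of gaps)."""
    if not match.monitored_days > 0:
        raise ValueError("monitored_days must be positive")
    return match.fp_alarms / match.monitored_days


class TimeGainSummary(NamedTuple):
    median: float
    q25: float
    q75: float
    n: int


def time_gain_summary(match: MatchResult) -> TimeGainSummary | None:
    """Median [25th-75th] of per-event time gains, nearest-rank quartiles.

    Returns ``None`` (undefined, not zero) when no event was detected.
    """
    if not match.time_gains:
        return None
    tg = np.asarray(match.time_gains)
    q25, med, q75 = np.percentile(tg, [25, 50, 75], method="inverted_cdf")
    return TimeGainSummary(float(med), float(q25), float(q75), tg.size)


def mae(
    actual: CGMTrace,
    forecasts: Sequence[ForecastVector],
    ph_min: float,
) -> float:
    """Mean absolute error |y(t+PH) - yhat(t+PH|t)| at one prediction horizon.

    Origins whose target sample is missing are skipped.  (The absolute value
    sits inside the mean; a published variant typesets it outside the
    summation, which would be a signed-bias magnitude, not an error.)
    """
    steps = int(round(ph_min / GRID_STEP_MIN))
    errs = []
    for fv in forecasts:
        tgt = fv.origin_index + steps
        if fv.horizon_steps < steps or tgt >= len(actual):
            continue
        y = actual.values[tgt]
        if not np.isfinite(y):
            continue
        errs.append(abs(y - fv.predicted[steps - 1]))
    if not errs:
        raise ValueError("no valid forecast origins at this PH")
    return float(np.mean(errs))


def mage(values: np.ndarray, sd: float | None = None) -> float:
    """Mean amplitude of glycaemic excursions.

    Turning points are located by sign changes of consecutive differences
    (plateaus collapsed); the MAGE is the mean of absolute peak-to-nadir
    amplitudes between successive turning points that exceed one SD of the
    whole series.  Returns 0 when no excursion exceeds one SD.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        return 0.0
    sd = float(np.std(v, ddof=1)) if sd is None else sd
    if sd == 0:
        return 0.0
    # collapse plateaus so each difference carries a sign
    keep = np.concatenate([[True], np.diff(v) != 0])
    w = v[keep]
    if w.size < 3:
        return 0.0
    sign = np.sign(np.diff(w))
    turning = np.where(sign[1:] != sign[:-1])[0] + 1
    idx = np.concatenate([[0], turning, [w.size - 1]])
    amplitudes = np.abs(np.diff(w[idx]))
    excursions = amplitudes[amplitudes > sd]
    return float(excursions.mean()) if excursions.size else 0.0


@dataclass
class GlucoMetrics:
    """Descriptive glucometrics of one trace over sensor-observed samples."""

    mean: float
    sd: float
    mage: float
    pct_below_54: float
    pct_below_70: float
    pct_in_70_180: float
    pct_above_180: float
    n_episodes: int
    episode_durations_min: list[float]

    @property
    def episode_duration_median_min(self) -> float | None:
        if not self.episode_durations_min:
            return None
        return float(
            np.percentile(self.episode_durations_min, 50, method="inverted_cdf")
        )


def glucometrics(trace: CGMTrace) -> GlucoMetrics:
    """Summary statistics over observed samples only (fills excluded)."""
    obs = trace.values[trace.observed_mask]
    if obs.size * GRID_STEP_MIN < 1440:
        raise ValueError("glucometrics needs at least one day of observed data")
    episodes = detect_episodes(trace)
    return GlucoMetrics(
        mean=float(obs.mean()),
        sd=float(obs.std(ddof=1)),
        mage=mage(obs),
        pct_below_54=100.0 * float(np.mean(obs < 54)),
        pct_below_70=100.0 * float(np.mean(obs < 70)),
        pct_in_70_180=100.0 * float(np.mean((obs >= 70) & (obs <= 180))),
        pct_above_180=100.0 * float(np.mean(obs > 180)),
        n_episodes=len(episodes),
        episode_durations_min=[e.duration_min for e in episodes],
    )


def monitored_days(trace: CGMTrace) -> float:
    """Calendar span of a trace in days (the FP/day denominator)."""
    return trace.span_days()
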