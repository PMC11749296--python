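"""Predictive hypoglycaemia alarms with a shut-off mechanism.

An alarm is raised at grid origin t when the forecast at the prediction
horizon PH falls below the triggering threshold (AlarmLevel).  Because
repeated alerts cause burden and frustration, a shut-off suppresses a new
alarm (a) within PH minutes of a previous one and (b) while the *current*
CGM reading is already below the clinical hypoglycaemia threshold (54 mg/dL
for Level-2 events) — an ongoing low needs treatment, not another prediction.

The AlarmLevel is a tuned hyperparameter distinct from the 54 mg/dL clinical
threshold: it may sit below it (compensating models that over-shoot lows) or
above it (compensating models with a positive bias).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cgm_data import GRID_STEP_MIN, ZOH_FILLED, CGMTrace
from .forecasters import ForecastVector

LEVEL2_THRESHOLD_MGDL = 54.0


@dataclass
class AlarmConfig:
    """Prediction horizon, triggering threshold and shut-off rule.

    ``shutoff_min`` defaults to the prediction horizon; ``trigger_any_step``
    switches from the default single-point test (forecast at exactly PH) to
    triggering when any step up to PH falls below the AlarmLevel.
    """

    ph_min: int = 25
    alarm_level: float = 42.0
    hypo_threshold: float = LEVEL2_THRESHOLD_MGDL
    shutoff_min: float | None = None
    trigger_any_step: bool = False

    def __post_init__(self) -> None:
        if self.ph_min % GRID_STEP_MIN != 0 or not 5 <= self.ph_min <= 45:
            raise ValueError("PH must be a multiple of 5 min within [5, 45]")
        if not 20.0 <= self.alarm_level <= 500.0:
            raise ValueError("alarm_level must be a plausible glucose value")

    @property
    def ph_steps(self) -> int:
        return self.ph_min // GRID_STEP_MIN

    @property
    def effective_shutoff_min(self) -> float:
        return self.ph_min if self.shutoff_min is None else self.shutoff_min


@dataclass
class AlarmRecord:
    """A raised alarm: grid index, the predicted value that triggered it, and
    the TP/FP label assigned later by event matching."""

    time: int
    predicted_value: float
    label: str | None = None
    from_held: bool = False  # origin sample was zero-order-hold filled

    @property
    def time_min(self) -> float:
        return self.time * GRID_STEP_MIN


def generate_alarms(
    forecasts: Sequence[ForecastVector],
    trace: CGMTrace,
    config: AlarmConfig,
) -> list[AlarmRecord]:
    """Turn a causal forecast stream into alarms under the shut-off rule.

    An alarm is raised at origin t iff

    a. the forecast at PH is strictly below ``alarm_level`` (or any step up
       to PH with ``trigger_any_step``),
    b. no alarm was raised within the preceding ``shutoff_min`` minutes, and
    c. the concurrent CGM reading is at or above ``hypo_threshold`` —
       suppression lifts as soon as the sensor recovers to >= 54 mg/dL.

    Forecasts issued while the current sample is ZOH-held are allowed (a
    real-time system must act on held values); such alarms carry
    ``from_held=True`` so runs can report how many alerts stem from held data.
    """
    steps = config.ph_steps
    alarms: list[AlarmRecord] = []
    last_alarm_min = -np.inf
    for fv in sorted(forecasts, key=lambda f: f.origin_index):
        if fv.horizon_steps < steps:
            raise ValueError(
                f"forecast at origin {fv.origin_index} has {fv.horizon_steps} "
                f"steps; PH={config.ph_min} min needs {steps}"
            )
        if config.trigger_any_step:
            triggered = bool(np.min(fv.predicted[:steps]) < config.alarm_level)
            value = float(np.min(fv.predicted[:steps]))
        else:
            value = fv.predicted[steps - 1]
            triggered = value < config.alarm_level
        if not triggered:
            continue
        t_min = fv.origin_index * GRID_STEP_MIN
        if t_min - last_alarm_min < config.effective_shutoff_min:
            continue
        current = trace.values[fv.origin_index]
        if not np.isfinite(current) or current < config.hypo_threshold:
            continue
        alarms.append(
            AlarmRecord(
                time=fv.origin_index,
                predicted_value=float(value),
                from_held=bool(trace.status[fv.origin_index] == ZOH_FILLED),
            )
        )
        last_alarm_min = t_min
    return alarms
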