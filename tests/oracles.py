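"""Independent brute-force oracles used to cross-check the implementation.

Every function here recomputes a quantity by direct enumeration or closed
form, deliberately sharing no code path with the package internals it
checks.
"""

from __future__ import annotations

import numpy as np

GRID_STEP_MIN = 5.0


def batch_weighted_ar1(
    y: np.ndarray, mu: float, a0: float = 1.0, p0: float = 1e3
) -> list[float]:
    """Exact batch solution of the exponentially discounted AR(1) problem.

    After observing pairs (y[i-1], y[i]) for i=1..t the recursive estimator
    minimizes  sum_i mu^(t-i) (y[i] - a y[i-1])^2 + mu^t (a - a0)^2 / p0,
    whose minimizer is a weighted-sum ratio with a geometrically decaying
    prior term.  Returns the estimate after each update.
    """
    out = []
    for t in range(1, len(y)):
        idx = np.arange(1, t + 1)
        w = mu ** (t - idx)
        sxx = float(np.sum(w * y[idx - 1] ** 2))
        sxy = float(np.sum(w * y[idx - 1] * y[idx]))
        prior = mu**t / p0
        out.append((sxy + prior * a0) / (sxx + prior))
    return out


def batch_weighted_ar1_no_prior(y: np.ndarray, mu: float, t: int) -> float:
    """Prior-free weighted-sum ratio sum mu^(t-i) y[i-1] y[i] / sum mu^(t-i) y[i-1]^2."""
    idx = np.arange(1, t + 1)
    w = mu ** (t - idx)
    return float(np.sum(w * y[idx - 1] * y[idx]) / np.sum(w * y[idx - 1] ** 2))


def replay_alarms(
    forecasts,
    values: np.ndarray,
    ph_min: int,
    alarm_level: float,
    hypo_threshold: float = 54.0,
    shutoff_min: float | None = None,
) -> list[int]:
    """Direct re-statement of the alarm rule as a literal replay loop."""
    shutoff = ph_min if shutoff_min is None else shutoff_min
    steps = ph_min // 5
    raised: list[int] = []
    for fv in sorted(forecasts, key=lambda f: f.origin_index):
        t = fv.origin_index
        pred = fv.predicted[steps - 1]
        if not pred < alarm_level:
            continue
        if raised and (t - raised[-1]) * GRID_STEP_MIN < shutoff:
            continue
        cur = values[t]
        if not np.isfinite(cur) or cur < hypo_threshold:
            continue
        raised.append(t)
    return raised


def brute_force_match(
    alarm_times_min: list[float], onset_times_min: list[float], window: float = 45.0
):
    """Exhaustive pairwise TP/FP/FN/TG computation on small instances."""
    tp = fp = 0
    for s in alarm_times_min:
        if any(s < o <= s + window for o in onset_times_min):
            tp += 1
        else:
            fp += 1
    detected = 0
    gains = []
    for o in onset_times_min:
        hits = [s for s in alarm_times_min if o - window <= s < o]
        if hits:
            detected += 1
            gains.append(o - min(hits))
    fn = len(onset_times_min) - detected
    return tp, fp, fn, detected, sorted(gains)


def mae_loop(values: np.ndarray, forecasts, ph_min: int) -> float:
    """Definition-loop MAE at one horizon, skipping missing targets."""
    steps = ph_min // 5
    errs = []
    for fv in forecasts:
        tgt = fv.origin_index + steps
        if tgt < len(values) and np.isfinite(values[tgt]):
            errs.append(abs(values[tgt] - fv.predicted[steps - 1]))
    return sum(errs) / len(errs)


def nearest_rank_quartiles(xs) -> tuple[float, float, float]:
    """Type-1 (nearest-rank) 25/50/75 percentiles via explicit sorting."""
    s = sorted(xs)
    n = len(s)

    def q(p: float) -> float:
        rank = int(np.ceil(p * n))
        return s[max(rank, 1) - 1]

    return q(0.25), q(0.50), q(0.75)


def iterate_arma_forecast(
    phi: np.ndarray, theta: np.ndarray, w_hist: np.ndarray, e_hist: np.ndarray, steps: int
) -> np.ndarray:
    """Hand-rolled iterated one-step ARMA forecast on the differenced scale."""
    w = list(w_hist)
    e = list(e_hist)
    out = []
    for _ in range(steps):
        pred = sum(phi[i] * w[-1 - i] for i in range(len(phi)))
        pred += sum(theta[j] * e[-1 - j] for j in range(len(theta)))
        w.append(pred)
        e.append(0.0)
        out.append(pred)
    return np.asarray(out)
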