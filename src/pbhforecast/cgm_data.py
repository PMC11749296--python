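"""Reading, grid alignment, gap handling and chronological splitting of CGM traces.

Continuous glucose monitoring (CGM) sensors report interstitial glucose in
mg/dL at a nominal 5-min period, but real-world traces carry jitter,
duplicated timestamps and gaps from transmission failures or sensor swaps.
Every downstream stage of the hypoglycaemia-forecasting pipeline assumes a
uniform 5-min grid, so this module:

* reads delimited-text trace files into raw (timestamp, glucose) samples,
* snaps samples onto the 5-min grid (nearest sample within half a grid step),
* fills short interior gaps by linear interpolation (training data only),
* fills gaps causally by zero-order hold (validation/test data, where no
  future sample may ever be consulted), and
* splits each subject chronologically into train/validation/test segments.

Each grid sample carries a provenance flag (``observed``, ``interpolated``,
``zoh_filled`` or ``missing``) so that evaluation can restrict itself to
sensor-observed samples while forecasting operates on the filled series.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

GRID_STEP_S = 300
GRID_STEP_MIN = 5

#: Plausibility bounds for a CGM reading (mg/dL); readers reject values outside.
GLUCOSE_MIN = 20.0
GLUCOSE_MAX = 500.0

# Per-sample provenance codes.
OBSERVED = np.uint8(0)
INTERPOLATED = np.uint8(1)
ZOH_FILLED = np.uint8(2)
MISSING = np.uint8(3)

STATUS_LABELS = {
    int(OBSERVED): "observed",
    int(INTERPOLATED): "interpolated",
    int(ZOH_FILLED): "zoh_filled",
    int(MISSING): "missing",
}
LABEL_CODES = {v: np.uint8(k) for k, v in STATUS_LABELS.items()}


class TraceFormatError(ValueError):
    """Raised when a trace file cannot be parsed or violates plausibility bounds."""


class RawSample(NamedTuple):
    """One raw CGM reading: seconds since trace start and glucose in mg/dL."""

    timestamp: float
    glucose: float


@dataclass
class CGMTrace:
    """A subject's glucose series on a uniform 5-min grid.

    ``values`` holds glucose in mg/dL with NaN at missing slots; ``status``
    records the provenance of every slot.  ``t0`` is the absolute time of the
    first grid slot in seconds (opaque to the pipeline; only differences
    matter).
    """

    subject_id: str
    t0: float
    values: np.ndarray
    status: np.ndarray
    grid_step_s: int = GRID_STEP_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.status = np.asarray(self.status, dtype=np.uint8)
        if self.values.shape != self.status.shape or self.values.ndim != 1:
            raise ValueError("values and status must be 1-D arrays of equal length")
        miss = self.status == MISSING
        if not np.all(np.isnan(self.values[miss])):
            raise ValueError("missing slots must hold NaN")
        present = self.values[~miss]
        if np.any(np.isnan(present)):
            raise ValueError("non-missing slots must hold finite glucose")
        if present.size and (present.min() < GLUCOSE_MIN or present.max() > GLUCOSE_MAX):
            raise ValueError(
                f"glucose outside plausibility bounds [{GLUCOSE_MIN}, {GLUCOSE_MAX}] mg/dL"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def missing_mask(self) -> np.ndarray:
        return self.status == MISSING

    @property
    def observed_mask(self) -> np.ndarray:
        return self.status == OBSERVED

    def times_min(self) -> np.ndarray:
        """Grid times in minutes relative to the trace start."""
        return np.arange(len(self)) * (self.grid_step_s / 60.0)

    def span_days(self) -> float:
        """Calendar span of the grid in days, regardless of missingness."""
        return len(self) * self.grid_step_s / 86400.0

    def slice(self, start: int, stop: int) -> "CGMTrace":
        return CGMTrace(
            subject_id=self.subject_id,
            t0=self.t0 + start * self.grid_step_s,
            values=self.values[start:stop].copy(),
            status=self.status[start:stop].copy(),
            grid_step_s=self.grid_step_s,
        )

    def copy(self) -> "CGMTrace":
        return replace(self, values=self.values.copy(), status=self.status.copy())


@dataclass
class SubjectSplit:
    """Chronological, contiguous train/validation/test segments of one subject."""

    train: CGMTrace
    validation: CGMTrace
    test: CGMTrace


def read_trace(path: str | Path) -> list[RawSample]:
    """Read a delimited-text CGM file into sorted raw samples.

    The file must have a header naming a timestamp column (``timestamp``,
    ``time`` or ``t``; ISO-8601 strings or numeric seconds) and a glucose
    column (``glucose_mgdl``, ``glucose`` or ``sgv``) in mg/dL.  Rows sharing
    a timestamp are collapsed to their mean.  Timestamps are returned as
    seconds since the first sample.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise TraceFormatError(f"{path}: cannot parse file: {exc}") from exc
    if df.empty:
        raise TraceFormatError(f"{path}: file contains no samples")

    cols = {c.strip().lower(): c for c in df.columns}
    t_col = next((cols[c] for c in ("timestamp", "time", "t") if c in cols), None)
    g_col = next((cols[c] for c in ("glucose_mgdl", "glucose", "sgv") if c in cols), None)
    if t_col is None or g_col is None:
        raise TraceFormatError(
            f"{path}: header must name a timestamp and a glucose column "
            f"(found {list(df.columns)})"
        )

    t_num = pd.to_numeric(df[t_col], errors="coerce")
    if t_num.isna().any():
        t_dt = pd.to_datetime(df[t_col], errors="coerce", format="ISO8601")
        t_sec = (t_dt - t_dt.iloc[0]).dt.total_seconds() if t_dt.notna().all() else None
        if t_sec is None:
            bad = sorted(
                set(df.index[t_num.isna()].tolist())
                & set(df.index[t_dt.isna()].tolist())
            )
            rows = [i + 2 for i in bad]  # +2: header line and 1-based numbering
            raise TraceFormatError(f"{path}: unparsable timestamps at rows {rows}")
        t_vals = t_sec.to_numpy(dtype=float)
    else:
        t_vals = t_num.to_numpy(dtype=float)

    g_vals = pd.to_numeric(df[g_col], errors="coerce").to_numpy(dtype=float)
    bad_rows = [
        i + 2
        for i, g in enumerate(g_vals)
        if not np.isfinite(g) or g < GLUCOSE_MIN or g > GLUCOSE_MAX
    ]
    if bad_rows:
        raise TraceFormatError(
            f"{path}: glucose outside [{GLUCOSE_MIN:g}, {GLUCOSE_MAX:g}] mg/dL "
            f"or unparsable at rows {bad_rows}"
        )

    order = np.argsort(t_vals, kind="stable")
    t_sorted, g_sorted = t_vals[order], g_vals[order]
    # Collapse duplicated timestamps to their mean reading.
    uniq_t, inverse = np.unique(t_sorted, return_inverse=True)
    sums = np.bincount(inverse, weights=g_sorted)
    counts = np.bincount(inverse)
    g_mean = sums / counts
    t_rel = uniq_t - uniq_t[0]
    return [RawSample(float(t), float(g)) for t, g in zip(t_rel, g_mean)]


def align_to_grid(
    samples: Sequence[RawSample],
    subject_id: str = "subject",
    t0: float = 0.0,
) -> CGMTrace:
    """Snap raw samples onto the 5-min grid.

    Each raw sample is assigned to its nearest grid slot (ties broken toward
    the earlier slot, so a sample exactly mid-way belongs to the slot before
    it); each slot keeps the nearest assigned sample, ties again toward the
    earlier sample.  Slots with no sample within half a grid step are flagged
    missing.
    """
    if len(samples) < 2:
        raise ValueError("grid alignment requires at least 2 samples")
    rel = np.array([s.timestamp for s in samples], dtype=float)
    base = np.floor(rel / GRID_STEP_S).astype(int)
    rem = rel - base * GRID_STEP_S
    slots = base + (rem > GRID_STEP_S / 2)

    offset = int(slots.min())  # anchor the grid at the first occupied slot
    slots = slots - offset
    t0 = t0 + offset * GRID_STEP_S
    n = int(slots.max()) + 1
    values = np.full(n, np.nan)
    status = np.full(n, MISSING, dtype=np.uint8)
    best = np.full(n, np.inf)
    for s, slot in zip(samples, slots):
        dist = abs(s.timestamp - (slot + offset) * GRID_STEP_S)
        if dist < best[slot]:  # strict: earlier sample wins ties
            best[slot] = dist
            values[slot] = s.glucose
            status[slot] = OBSERVED
    return CGMTrace(subject_id=subject_id, t0=t0, values=values, status=status)


def _missing_runs(status: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) index ranges of consecutive missing slots."""
    miss = status == MISSING
    runs: list[tuple[int, int]] = []
    i = 0
    n = miss.size
    while i < n:
        if miss[i]:
            j = i
            while j < n and miss[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def interpolate_training_gaps(trace: CGMTrace, max_gap_min: float = 30.0) -> CGMTrace:
    """Linearly fill interior missing runs strictly shorter than ``max_gap_min``.

    A run of k missing slots represents a k x 5 min gap; it is interpolated
    between the flanking non-missing values only when k x 5 < ``max_gap_min``
    (a 30-min gap is *not* "shorter than 30 min").  Leading and trailing runs
    have no anchor on one side and stay missing.
    """
    out = trace.copy()
    for start, stop in _missing_runs(trace.status):
        if start == 0 or stop == len(trace):
            continue
        if (stop - start) * GRID_STEP_MIN >= max_gap_min:
            continue
        left, right = trace.values[start - 1], trace.values[stop]
        filled = np.linspace(left, right, stop - start + 2)[1:-1]
        out.values[start:stop] = filled
        out.status[start:stop] = INTERPOLATED
    return out


def causal_fill(trace: CGMTrace) -> CGMTrace:
    """Zero-order-hold fill: each missing slot repeats the latest earlier value.

    Strictly causal — a slot is filled only from samples at earlier indices,
    and slots before the first non-missing sample stay missing.
    """
    out = trace.copy()
    last = np.nan
    for i in range(len(out)):
        if out.status[i] == MISSING:
            if np.isfinite(last):
                out.values[i] = last
                out.status[i] = ZOH_FILLED
        else:
            last = out.values[i]
    return out


def split_subject(
    trace: CGMTrace, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
) -> SubjectSplit:
    """Chronological contiguous split with boundaries at floor(cumfrac * n)."""
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    n = len(trace)
    if n < 3:
        raise ValueError("trace shorter than 3 samples cannot be split")
    b1 = math.floor(fractions[0] * n)
    b2 = math.floor((fractions[0] + fractions[1]) * n)
    return SubjectSplit(
        train=trace.slice(0, b1),
        validation=trace.slice(b1, b2),
        test=trace.slice(b2, n),
    )


def eligible(trace: CGMTrace, min_days: float = 10.0) -> bool:
    """True iff sensor-observed coverage strictly exceeds ``min_days`` days."""
    observed_min = int(trace.observed_mask.sum()) * GRID_STEP_MIN
    return observed_min > min_days * 1440.0


def write_trace(trace: CGMTrace, path: str | Path) -> None:
    """Write a gridded trace as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "timestamp": trace.t0 + np.arange(len(trace)) * trace.grid_step_s,
            "glucose_mgdl": trace.values,
            "status": [STATUS_LABELS[int(s)] for s in trace.status],
        }
    )
    df.to_csv(path, index=False)
    counts = {
        label: int((trace.status == code).sum()) for label, code in LABEL_CODES.items()
    }
    meta = {
        "subject_id": trace.subject_id,
        "t0": trace.t0,
        "grid_step_s": trace.grid_step_s,
        "n_samples": len(trace),
        "status_counts": counts,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_gridded_trace(path: str | Path, subject_id: str | None = None) -> CGMTrace:
    """Read back a trace written by :func:`write_trace` (status column honoured)."""
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    status = np.array([LABEL_CODES[s] for s in df["status"]], dtype=np.uint8)
    values = df["glucose_mgdl"].to_numpy(dtype=float)
    values[status == MISSING] = np.nan
    return CGMTrace(
        subject_id=subject_id or meta.get("subject_id", path.stem),
        t0=float(meta.get("t0", df["timestamp"].iloc[0])),
        values=values,
        status=status,
        grid_step_s=int(meta.get("grid_step_s", GRID_STEP_S)),
    )
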