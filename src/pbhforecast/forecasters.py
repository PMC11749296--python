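"""Multi-step glucose forecasters behind one uniform, strictly causal contract.

Seven model families predict glucose up to 30 min ahead (6 steps of 5 min)
from past CGM only:

* **rAR** — the central model: a first-order autoregressive model whose single
  coefficient is re-estimated online by exponentially weighted recursive least
  squares ("run-to-run" adaptation).  The forgetting factor ``mu`` discounts a
  sample that is tau steps old by ``mu**tau``; samples older than the effective
  memory ``tau = 1/(1 - mu)`` barely influence the estimate.  With the default
  ``mu = 0.675`` the three most recent CGM samples dominate.
* **ARIMA(3,1,1)** — a population-wise linear model identified by the
  prediction-error method (minimizing the one-step-ahead prediction error,
  here as summed conditional least squares over contiguous segments) and
  forecast by iterating the one-step prediction.
* **NN / LSTM / CNN-LSTM / RF / LGB** — windowed sequence-to-sequence
  regressors mapping the last ``input_window`` samples (default 12 = 60 min)
  directly to the 6 future samples.

Every family implements ``forecast_stream(trace)``: one forecast per grid
index whose history requirement is met, computed from samples at indices
<= the origin only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import optimize, signal

from .cgm_data import GRID_STEP_MIN, MISSING, OBSERVED, ZOH_FILLED, CGMTrace

MAX_HORIZON_STEPS = 6  # 30-min maximum prediction horizon


class InsufficientHistoryError(RuntimeError):
    """Raised when a forecaster lacks the history required at an origin."""


class FitError(RuntimeError):
    """Raised when model identification fails or yields an invalid model."""


class MissingDependencyError(ImportError):
    """Raised when an optional deep-learning backend is not installed."""


@dataclass(frozen=True)
class ForecastVector:
    """Forecasts issued at one grid origin: entry k-1 is yhat(t + 5k | t)."""

    origin_index: int
    predicted: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "predicted", np.asarray(self.predicted, dtype=np.float64)
        )
        if not 1 <= self.predicted.size <= MAX_HORIZON_STEPS:
            raise ValueError("forecast length must be between 1 and 6 steps")
        if not np.all(np.isfinite(self.predicted)):
            raise ValueError("forecasts must be finite")

    @property
    def horizon_steps(self) -> int:
        return self.predicted.size

    def at_ph(self, ph_min: float) -> float:
        """Prediction at horizon ``ph_min`` minutes (must be a whole step)."""
        steps = int(round(ph_min / GRID_STEP_MIN))
        if not 1 <= steps <= self.horizon_steps:
            raise ValueError(f"forecast does not reach PH={ph_min} min")
        return float(self.predicted[steps - 1])


class Forecaster(Protocol):
    """Uniform contract: fit on training traces, forecast causally on a stream."""

    def fit(self, traces: Sequence[CGMTrace], val_traces: Sequence[CGMTrace] | None = None) -> "Forecaster": ...

    def forecast_stream(self, trace: CGMTrace, steps: int = MAX_HORIZON_STEPS) -> list[ForecastVector]: ...


# ---------------------------------------------------------------------------
# rAR: recursive AR(1) with exponential forgetting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RARState:
    """State of the recursive AR(1) estimator.

    ``a`` is the current AR coefficient, ``P`` the scalar estimation
    covariance, ``mu`` the forgetting factor in (0, 1), ``n_updates`` the
    number of update steps absorbed so far.
    """

    a: float
    P: float
    mu: float
    n_updates: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError("forgetting factor mu must lie in (0, 1)")
        if not self.P > 0:
            raise ValueError("covariance P must be positive")

    @property
    def effective_memory(self) -> float:
        """Effective memory tau = 1/(1-mu): samples older than tau carry weight mu**tau."""
        return 1.0 / (1.0 - self.mu)


def rar_update(state: RARState, y_prev: float, y_new: float) -> RARState:
    """One exponentially weighted recursive least-squares step for y_new ~ a*y_prev.

    gain  k = P*y_prev / (mu + y_prev^2 * P)
    a    <- a + k * (y_new - a*y_prev)
    P    <- (P - k*y_prev*P) / mu

    After any sequence of updates ``a`` is the exact minimizer of
    sum_i mu^(t-i) (y_i - a*y_{i-1})^2 + mu^t (a - a0)^2 / P0,
    the exponentially discounted one-step squared prediction error with a
    geometrically vanishing prior at the initial (a0, P0).
    """
    if not (np.isfinite(y_prev) and np.isfinite(y_new)):
        raise ValueError("rar_update requires finite glucose values")
    k = state.P * y_prev / (state.mu + y_prev * y_prev * state.P)
    a = state.a + k * (y_new - state.a * y_prev)
    P = (state.P - k * y_prev * state.P) / state.mu
    return replace(state, a=a, P=P, n_updates=state.n_updates + 1)


def rar_forecast(
    state: RARState,
    y_t: float,
    steps: int = MAX_HORIZON_STEPS,
    origin_index: int = 0,
    burn_in: int = 3,
) -> ForecastVector:
    """Iterated AR(1) forecast: entry k is a**k * y_t.

    Requires ``burn_in`` updates before the coefficient is trusted; below
    that an :class:`InsufficientHistoryError` is raised (no forecast at this
    origin).
    """
    if state.n_updates < burn_in:
        raise InsufficientHistoryError(
            f"rAR needs >= {burn_in} updates before forecasting "
            f"(have {state.n_updates})"
        )
    powers = np.power(state.a, np.arange(1, steps + 1))
    return ForecastVector(origin_index=origin_index, predicted=powers * y_t)


@dataclass
class RecursiveARForecaster:
    """Run-to-run AR(1) forecaster with exponential forgetting.

    The forgetting factor is fixed population-wise (default 0.675, i.e. an
    effective memory of ~3 samples) while the coefficient and covariance adapt
    online per subject as each CGM sample arrives.  The state is re-initialized
    after a data gap of at least ``reset_gap_min`` minutes; held (zero-order
    hold) samples inside shorter gaps do update the state.  Initialization is
    a persistence prior (a0=1) with diffuse covariance, the safe cold start
    for glucose.
    """

    mu: float = 0.675
    a0: float = 1.0
    p0: float = 1e3
    burn_in: int = 3
    reset_gap_min: float = 30.0

    def initial_state(self) -> RARState:
        return RARState(a=self.a0, P=self.p0, mu=self.mu)

    def fit(
        self,
        traces: Sequence[CGMTrace],
        val_traces: Sequence[CGMTrace] | None = None,
        mu_grid: Sequence[float] | None = None,
    ) -> "RecursiveARForecaster":
        """Optionally grid-search ``mu`` by one-step squared error on training data."""
        if mu_grid:
            best_mu, best_sse = self.mu, np.inf
            for mu in mu_grid:
                sse = 0.0
                cand = replace(self, mu=mu)
                for trace in traces:
                    state = cand.initial_state()
                    prev = np.nan
                    for v in trace.values:
                        if not np.isfinite(v):
                            prev = np.nan
                            continue
                        if np.isfinite(prev):
                            if state.n_updates >= cand.burn_in:
                                sse += (v - state.a * prev) ** 2
                            state = rar_update(state, prev, v)
                        prev = v
                if sse < best_sse:
                    best_mu, best_sse = mu, sse
            self.mu = best_mu
        return self

    def forecast_stream(
        self, trace: CGMTrace, steps: int = MAX_HORIZON_STEPS
    ) -> list[ForecastVector]:
        reset_slots = int(round(self.reset_gap_min / GRID_STEP_MIN))
        state = self.initial_state()
        out: list[ForecastVector] = []
        prev = np.nan
        held_run = 0  # consecutive non-observed slots (gap, possibly ZOH-filled)
        for i in range(len(trace)):
            v = trace.values[i]
            st = trace.status[i]
            if not np.isfinite(v):
                held_run += 1
                prev = np.nan
                continue
            if st == OBSERVED:
                if held_run >= reset_slots:
                    state = self.initial_state()
                    prev = np.nan
                held_run = 0
            else:
                held_run += 1
            if np.isfinite(prev):
                state = rar_update(state, prev, v)
            prev = v
            if state.n_updates >= self.burn_in:
                out.append(
                    rar_forecast(state, v, steps, origin_index=i, burn_in=self.burn_in)
                )
        return out


# ---------------------------------------------------------------------------
# ARIMA(p, d, q) identified by the prediction-error method
# ---------------------------------------------------------------------------

@dataclass
class ARIMAConfig:
    """Structure and fitted parameters of the population-wise ARIMA model."""

    p: int = 3
    d: int = 1
    q: int = 1
    ar: np.ndarray | None = None
    ma: np.ndarray | None = None

    @property
    def min_history(self) -> int:
        return self.p + self.d + self.q

    def coefficients(self) -> np.ndarray:
        if self.ar is None or self.ma is None:
            raise FitError("ARIMA model has not been fitted")
        return np.concatenate([self.ar, self.ma])


def _contiguous_segments(trace: CGMTrace, min_len: int = 2) -> list[np.ndarray]:
    """Non-missing contiguous runs of a trace (no values across a gap)."""
    segs: list[np.ndarray] = []
    vals = trace.values
    ok = np.isfinite(vals)
    i = 0
    n = vals.size
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i >= min_len:
                segs.append(vals[i:j].copy())
            i = j
        else:
            i += 1
    return segs


def _css_residuals(params: np.ndarray, w_segments: list[np.ndarray], p: int, q: int) -> np.ndarray:
    """Conditional one-step prediction errors, segments treated independently.

    Each differenced segment conditions on its own first ``p`` values with
    zero initial innovations — no term ever couples two segments, so fitting
    disjoint segments is exactly fitting independent realizations.
    """
    phi, theta = params[:p], params[p:]
    chunks = []
    for w in w_segments:
        if w.size <= p:
            continue
        r = w[p:].copy()
        for i in range(1, p + 1):
            r -= phi[i - 1] * w[p - i : w.size - i]
        # innovations recursion e_t = r_t - sum_j theta_j e_{t-j}
        e = signal.lfilter([1.0], np.concatenate([[1.0], theta]), r) if q else r
        chunks.append(e)
    if not chunks:
        return np.zeros(1)
    return np.concatenate(chunks)


def fit_arima(
    traces: Sequence[CGMTrace],
    config: ARIMAConfig | None = None,
    min_total_samples: int = 500,
) -> ARIMAConfig:
    """Identify one population-wise ARIMA by minimizing the one-step error.

    The training traces are cut into contiguous non-missing segments, each
    segment is differenced ``d`` times, and the pooled conditional sum of
    squared one-step prediction errors is minimized (prediction-error method).
    Causality and invertibility are enforced at the end (a non-invertible MA
    root is reflected inside the unit circle; a non-causal AR fit raises).
    """
    config = config or ARIMAConfig()
    p, d, q = config.p, config.d, config.q
    segments = []
    for trace in traces:
        if isinstance(trace, CGMTrace):
            segments.extend(_contiguous_segments(trace, min_len=p + d + q + 2))
        else:  # a bare array is one contiguous segment
            arr = np.asarray(trace, dtype=float)
            if arr.size >= p + d + q + 2:
                segments.append(arr)
    total = sum(s.size for s in segments)
    if total < min_total_samples:
        raise FitError(
            f"pooled training data has {total} usable samples; "
            f"need >= {min_total_samples}"
        )
    w_segments = [np.diff(s, n=d) if d else s for s in segments]
    w_segments = [w for w in w_segments if w.size > p]

    # Initialize the AR part by pooled ordinary least squares, MA at zero.
    rows, targets = [], []
    for w in w_segments:
        for t in range(p, w.size):
            rows.append(w[t - p : t][::-1])
            targets.append(w[t])
    X = np.asarray(rows)
    y = np.asarray(targets)
    phi0, *_ = np.linalg.lstsq(X, y, rcond=None)
    x0 = np.concatenate([phi0, np.zeros(q)])

    res = optimize.least_squares(
        _css_residuals, x0, args=(w_segments, p, q), method="lm",
        xtol=1e-12, max_nfev=5000,
    )
    cost0 = 0.5 * float(np.sum(_css_residuals(x0, w_segments, p, q) ** 2))
    improved = np.all(np.isfinite(res.x)) and res.cost <= cost0 + 1e-12
    if not improved and res.status <= 0:
        raise FitError(f"prediction-error minimization failed: {res.message}")
    phi, theta = res.x[:p].copy(), res.x[p:].copy()

    if p and np.any(np.abs(np.roots(np.concatenate([[1.0], -phi]))) >= 1.0):
        raise FitError(f"fitted AR polynomial is not causal (phi={phi})")
    if q:
        ma_roots = np.roots(np.concatenate([[1.0], theta])[::-1])
        if np.any(np.abs(ma_roots) <= 1.0 + 1e-12):
            if q == 1 and abs(theta[0]) > 1:
                theta[0] = 1.0 / theta[0]  # reflect to the invertible root
            else:
                raise FitError(f"fitted MA polynomial is not invertible (theta={theta})")
    return replace(config, ar=phi, ma=theta)


def arima_forecast(
    config: ARIMAConfig,
    history: Sequence[float],
    steps: int = MAX_HORIZON_STEPS,
    origin_index: int = 0,
) -> ForecastVector:
    """Iterated minimum-MSE multi-step forecast of the fitted ARIMA.

    Innovations over the supplied history are rebuilt by the same conditional
    recursion used at fit time; future innovations are set to their zero mean
    and the one-step prediction is iterated out to ``steps``.
    """
    hist = np.asarray(history, dtype=float)
    if hist.size < config.min_history:
        raise InsufficientHistoryError(
            f"ARIMA needs >= {config.min_history} samples of contiguous history"
        )
    if not np.all(np.isfinite(hist)):
        raise ValueError("history must be finite (gap-filled)")
    phi = config.ar if config.ar is not None else np.zeros(config.p)
    theta = config.ma if config.ma is not None else np.zeros(config.q)
    p, d, q = config.p, config.d, config.q

    w = np.diff(hist, n=d) if d else hist.copy()
    e = np.zeros(w.size)
    for t in range(w.size):
        pred = 0.0
        for i in range(1, p + 1):
            if t - i >= 0:
                pred += phi[i - 1] * w[t - i]
        for j in range(1, q + 1):
            if t - j >= 0:
                pred += theta[j - 1] * e[t - j]
        e[t] = w[t] - pred

    w_ext = list(w)
    e_ext = list(e)
    level = float(hist[-1])
    preds = np.empty(steps)
    for k in range(steps):
        pred = 0.0
        for i in range(1, p + 1):
            if len(w_ext) - i >= 0 and i <= len(w_ext):
                pred += phi[i - 1] * w_ext[-i]
        for j in range(1, q + 1):
            if j <= len(e_ext):
                pred += theta[j - 1] * e_ext[-j]
        w_ext.append(pred)
        e_ext.append(0.0)
        if d:
            level += pred
            preds[k] = level
        else:
            preds[k] = pred
    return ForecastVector(origin_index=origin_index, predicted=preds)


@dataclass
class ArimaForecaster:
    """Population-wise ARIMA forecaster behind the uniform streaming contract."""

    config: ARIMAConfig = field(default_factory=ARIMAConfig)
    warmup_cap: int = 48  # longest history (samples) used to rebuild innovations

    def fit(
        self,
        traces: Sequence[CGMTrace],
        val_traces: Sequence[CGMTrace] | None = None,
        min_total_samples: int = 500,
    ) -> "ArimaForecaster":
        self.config = fit_arima(traces, self.config, min_total_samples)
        return self

    def forecast_stream(
        self, trace: CGMTrace, steps: int = MAX_HORIZON_STEPS
    ) -> list[ForecastVector]:
        vals = trace.values
        ok = np.isfinite(vals)
        run_start = np.empty(len(trace), dtype=int)
        start = 0
        for i in range(len(trace)):
            if not ok[i]:
                start = i + 1
            run_start[i] = start
        out: list[ForecastVector] = []
        min_h = self.config.min_history
        for i in range(len(trace)):
            if not ok[i]:
                continue
            lo = max(run_start[i], i + 1 - self.warmup_cap)
            if i + 1 - lo < min_h:
                continue
            out.append(
                arima_forecast(self.config, vals[lo : i + 1], steps, origin_index=i)
            )
        return out


# ---------------------------------------------------------------------------
# Windowed sequence-to-sequence regressors (NN, LSTM, CNN-LSTM, RF, LGB)
# ---------------------------------------------------------------------------

WINDOWED_FAMILIES = ("nn", "lstm", "cnnlstm", "rf", "lgb")
DEEP_FAMILIES = ("lstm", "cnnlstm")


@dataclass
class WindowedRegressorConfig:
    """Configuration of a windowed seq2seq regressor.

    Final per-family structures: NN two hidden layers 32/16; LSTM layers
    24/12; CNN-LSTM two conv blocks (16 and 8 filters, batch-norm, pooling)
    over LSTM layers 12/6; RF 100 trees of max depth 15 with >= 10 samples
    per split; LGB 200 trees, 31 leaves, learning rate 0.02.  Network
    training runs at most 300 epochs with 30-epoch patience on validation
    loss and batch size 32.
    """

    family: str = "rf"
    input_window: int = 12  # samples (60 min), >= 2x the output span
    output_steps: int = MAX_HORIZON_STEPS
    seed: int = 0
    max_epochs: int = 300
    patience: int = 30
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.family not in WINDOWED_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {WINDOWED_FAMILIES}")
        if self.input_window < 3:
            raise ValueError("input_window must be >= 3 samples")
        if self.output_steps != MAX_HORIZON_STEPS:
            raise ValueError("output is fixed at 6 steps (30-min horizon)")


def make_supervised(
    traces: Sequence[CGMTrace], config: WindowedRegressorConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Build (window, 6-step target) pairs from training traces.

    A pair is emitted only when the ``input_window`` inputs and all 6 targets
    are contiguous non-missing samples of one subject; no pair straddles a
    missing run or a subject boundary.
    """
    w, h = config.input_window, config.output_steps
    X_rows, Y_rows = [], []
    for trace in traces:
        vals = trace.values
        ok = np.isfinite(vals)
        if len(trace) < w + h:
            continue
        # valid[t] == True iff slots t-w+1 .. t+h are all non-missing
        csum = np.concatenate([[0], np.cumsum(ok)])
        for t in range(w - 1, len(trace) - h):
            lo, hi = t - w + 1, t + h + 1
            if csum[hi] - csum[lo] == hi - lo:
                X_rows.append(vals[lo : t + 1])
                Y_rows.append(vals[t + 1 : hi])
    if not X_rows:
        return np.empty((0, w)), np.empty((0, h))
    return np.asarray(X_rows), np.asarray(Y_rows)


def _require_keras():
    try:  # pragma: no cover - exercised only when a deep backend exists
        import keras  # type: ignore

        return keras
    except ImportError as exc:
        raise MissingDependencyError(
            "the LSTM and CNN-LSTM families require the optional Keras "
            "deep-learning backend (pip install 'tensorflow' or 'keras'); "
            "all other families run without it"
        ) from exc


def _build_keras_model(config: WindowedRegressorConfig):  # pragma: no cover
    keras = _require_keras()
    layers = keras.layers
    inputs = keras.Input(shape=(config.input_window, 1))
    if config.family == "lstm":
        x = layers.LSTM(24, activation="elu", return_sequences=True)(inputs)
        x = layers.LSTM(12)(x)
    else:  # cnnlstm
        x = layers.Conv1D(16, kernel_size=3, padding="same")(inputs)
        x = layers.BatchNormalization()(x)
        x = layers.MaxPooling1D(pool_size=2)(x)
        x = layers.Conv1D(8, kernel_size=3, padding="same")(x)
        x = layers.BatchNormalization()(x)
        x = layers.MaxPooling1D(pool_size=2)(x)
        x = layers.LSTM(12, activation="elu", return_sequences=True)(x)
        x = layers.LSTM(6, activation="elu")(x)
    outputs = layers.Dense(config.output_steps)(x)
    model = keras.Model(inputs, outputs)
    model.compile(
        optimizer=keras.optimizers.RMSprop(learning_rate=1e-5), loss="mse"
    )
    return model


@dataclass
class WindowedModel:
    """A fitted windowed regressor plus its input/target standardization."""

    config: WindowedRegressorConfig
    predictors: list
    mean: float
    sd: float

    def predict(self, window: np.ndarray) -> np.ndarray:
        return self.predict_batch(np.asarray(window, dtype=float).reshape(1, -1))[0]

    def predict_batch(self, windows: np.ndarray) -> np.ndarray:
        """Predict 6 steps for many windows at once (rows of shape input_window)."""
        xs = (np.asarray(windows, dtype=float) - self.mean) / self.sd
        fam = self.config.family
        if fam in DEEP_FAMILIES:  # pragma: no cover - needs keras
            zs = self.predictors[0].predict(xs[..., None], verbose=0)
        elif fam == "nn":
            zs = self.predictors[0].predict(xs)
        else:  # rf / lgb: one model per output step
            zs = np.column_stack([m.predict(xs) for m in self.predictors])
        return zs * self.sd + self.mean


def fit_windowed(
    X: np.ndarray,
    Y: np.ndarray,
    config: WindowedRegressorConfig,
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
) -> WindowedModel:
    """Fit one windowed family on supervised pairs.

    Inputs and targets share glucose units, so both are standardized by the
    training-input mean/SD (stored with the model).  RF and LGB fit one
    independent single-output model per step; the feed-forward NN fits all 6
    outputs jointly; the deep families train with early stopping on the
    validation split when one is supplied.
    """
    if X.shape[0] == 0:
        raise FitError("empty training dataset")
    mean = float(X.mean())
    sd = float(X.std())
    sd = sd if sd > 1e-8 else 1e-8
    Xs, Ys = (X - mean) / sd, (Y - mean) / sd
    fam = config.family

    if fam == "rf":
        from sklearn.ensemble import RandomForestRegressor

        predictors = [
            RandomForestRegressor(
                n_estimators=100,
                max_depth=15,
                min_samples_split=10,
                random_state=config.seed + k,
                n_jobs=1,
            ).fit(Xs, Ys[:, k])
            for k in range(config.output_steps)
        ]
    elif fam == "lgb":
        from lightgbm import LGBMRegressor

        predictors = [
            LGBMRegressor(
                n_estimators=200,
                num_leaves=31,
                learning_rate=0.02,
                random_state=config.seed + k,
                n_jobs=1,
                verbose=-1,
            ).fit(Xs, Ys[:, k])
            for k in range(config.output_steps)
        ]
    elif fam == "nn":
        from sklearn.neural_network import MLPRegressor

        predictors = [
            MLPRegressor(
                hidden_layer_sizes=(32, 16),
                activation="relu",
                solver="adam",
                batch_size=min(config.batch_size, X.shape[0]),
                max_iter=config.max_epochs,
                n_iter_no_change=config.patience,
                random_state=config.seed,
                tol=1e-7,
            ).fit(Xs, Ys)
        ]
    else:  # pragma: no cover - deep families need the optional keras backend
        keras = _require_keras()
        model = _build_keras_model(config)
        fit_kwargs = dict(
            epochs=config.max_epochs, batch_size=config.batch_size, verbose=0
        )
        if X_val is not None and X_val.shape[0]:
            Xvs, Yvs = (X_val - mean) / sd, (Y_val - mean) / sd
            fit_kwargs["validation_data"] = (Xvs[..., None], Yvs)
            fit_kwargs["callbacks"] = [
                keras.callbacks.EarlyStopping(
                    monitor="val_loss",
                    patience=config.patience,
                    restore_best_weights=True,
                )
            ]
        model.fit(Xs[..., None], Ys, **fit_kwargs)
        predictors = [model]
    return WindowedModel(config=config, predictors=predictors, mean=mean, sd=sd)


@dataclass
class WindowedForecaster:
    """Streaming wrapper for the windowed seq2seq families."""

    config: WindowedRegressorConfig = field(default_factory=WindowedRegressorConfig)
    model: WindowedModel | None = None

    def fit(
        self,
        traces: Sequence[CGMTrace],
        val_traces: Sequence[CGMTrace] | None = None,
    ) -> "WindowedForecaster":
        X, Y = make_supervised(traces, self.config)
        if val_traces:
            X_val, Y_val = make_supervised(val_traces, self.config)
        else:
            X_val = Y_val = None
        self.model = fit_windowed(X, Y, self.config, X_val, Y_val)
        return self

    def forecast_stream(
        self, trace: CGMTrace, steps: int = MAX_HORIZON_STEPS
    ) -> list[ForecastVector]:
        if self.model is None:
            raise FitError("forecaster has not been fitted")
        w = self.config.input_window
        vals = trace.values
        ok = np.isfinite(vals)
        csum = np.concatenate([[0], np.cumsum(ok)])
        origins = [
            t
            for t in range(w - 1, len(trace))
            if csum[t + 1] - csum[t - w + 1] == w
        ]
        if not origins:
            return []
        windows = np.stack([vals[t - w + 1 : t + 1] for t in origins])
        preds = self.model.predict_batch(windows)
        return [
            ForecastVector(origin_index=t, predicted=preds[i, :steps])
            for i, t in enumerate(origins)
        ]


def make_forecaster(name: str, seed: int = 0, **kwargs) -> Forecaster:
    """Factory for the seven families: rar, arima, nn, lstm, cnnlstm, rf, lgb."""
    name = name.lower()
    if name == "rar":
        return RecursiveARForecaster(**kwargs)
    if name == "arima":
        return ArimaForecaster(**kwargs)
    if name in WINDOWED_FAMILIES:
        cfg = WindowedRegressorConfig(family=name, seed=seed, **kwargs)
        return WindowedForecaster(config=cfg)
    raise ValueError(f"unknown forecaster {name!r}")


def forecast_stream(
    model: Forecaster, trace: CGMTrace, steps: int = MAX_HORIZON_STEPS
) -> list[ForecastVector]:
    """Uniform entry point mirroring the per-family ``forecast_stream`` methods."""
    return model.forecast_stream(trace, steps)
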