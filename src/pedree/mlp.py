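"""Four-hidden-unit multilayer perceptron and the frozen-weights A/B–B/A protocol.

A deliberately small, classic network: one sigmoid hidden layer (default
four units), sigmoid output, inputs and target affinely mapped to
[0.1, 0.9] (the comfortable range of a logistic unit), online
backpropagation with momentum, uniform seeded initialisation. The capacity
is tiny by design — the scientific claim under test is that even four
hidden units capture the nonlinearity that linear weight/height equations
miss, not that depth helps.

The evaluation protocol mirrors a strict double cross-over: train on
subset A, save and *freeze* the weights, hand them to a virgin twin
network that scores subset B without ever learning from it; then repeat
with roles swapped. Every record receives exactly one out-of-sample
prediction, and accuracy is reported as the average of the two testing
runs.

The per-record update loop is JIT-compiled with numba; training is
deterministic given the seed (fixed record presentation order, no
shuffling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numba import njit

from .errors import DataContractError, InvalidConfigError
from .metrics import FitMetrics, fit_metrics

_SCALE_LO, _SCALE_HI = 0.1, 0.9


@dataclass(frozen=True)
class MlpSettings:
    """Architecture and training hyperparameters."""

    n_inputs: int
    n_hidden: int = 4
    learning_rate: float = 0.05
    momentum: float = 0.9
    max_epochs: int = 2000
    init_range: float = 0.3
    seed: int = 0
    early_stop_delta: float = 1e-7   # min MSE improvement ...
    early_stop_patience: int = 50    # ... over this many epochs

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_hidden < 1:
            raise InvalidConfigError("n_inputs and n_hidden must be >= 1")
        if self.learning_rate <= 0:
            raise InvalidConfigError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise InvalidConfigError("momentum must be in [0, 1)")


@njit(cache=False)
def _train_loop(x, t, w1, w2, lr, mom, max_epochs, delta, patience):  # pragma: no cover
    n, d = x.shape
    nh = w1.shape[1]
    vel1 = np.zeros_like(w1)
    vel2 = np.zeros_like(w2)
    history = np.empty(max_epochs)
    best = 1e300
    since_best = 0
    epochs_run = 0
    for ep in range(max_epochs):
        sse = 0.0
        for i in range(n):
            # forward
            a1 = np.empty(nh)
            for hju in range(nh):
                z = w1[d, hju]
                for k in range(d):
                    z += x[i, k] * w1[k, hju]
                a1[hju] = 1.0 / (1.0 + np.exp(-z))
            z2 = w2[nh]
            for hju in range(nh):
                z2 += a1[hju] * w2[hju]
            a2 = 1.0 / (1.0 + np.exp(-z2))
            err = a2 - t[i]
            sse += err * err
            # backward
            d2 = err * a2 * (1.0 - a2)
            for hju in range(nh):
                d1 = d2 * w2[hju] * a1[hju] * (1.0 - a1[hju])
                for k in range(d):
                    vel1[k, hju] = mom * vel1[k, hju] - lr * d1 * x[i, k]
                    w1[k, hju] += vel1[k, hju]
                vel1[d, hju] = mom * vel1[d, hju] - lr * d1
                w1[d, hju] += vel1[d, hju]
                vel2[hju] = mom * vel2[hju] - lr * d2 * a1[hju]
                w2[hju] += vel2[hju]
            vel2[nh] = mom * vel2[nh] - lr * d2
            w2[nh] += vel2[nh]
        mse = sse / n
        history[ep] = mse
        epochs_run = ep + 1
        if mse < best - delta:
            best = mse
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    return history[:epochs_run]


@dataclass
class AffineScaler:
    """Per-column affine map onto [0.1, 0.9], fitted on the training set."""

    mins: np.ndarray
    ranges: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "AffineScaler":
        x = np.atleast_2d(x)
        mins = x.min(axis=0)
        ranges = x.max(axis=0) - mins
        ranges[ranges == 0] = 1.0
        return cls(mins, ranges)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return _SCALE_LO + (_SCALE_HI - _SCALE_LO) * (x - self.mins) / self.ranges

    def inverse(self, s: np.ndarray) -> np.ndarray:
        return self.mins + (s - _SCALE_LO) * self.ranges / (_SCALE_HI - _SCALE_LO)


@dataclass
class MlpModel:
    """A trained (and freezable) perceptron with its scaling layers."""

    settings: MlpSettings
    w1: np.ndarray               # (n_inputs + 1, n_hidden), last row = bias
    w2: np.ndarray               # (n_hidden + 1,), last entry = bias
    input_scaler: AffineScaler
    target_scaler: AffineScaler
    frozen: bool = False
    training_error_history: list[float] = field(default_factory=list)

    def freeze(self) -> "MlpModel":
        self.frozen = True
        return self

    def clone_virgin(self) -> "MlpModel":
        """A twin network: same architecture and parameters, fresh object."""
        return MlpModel(
            settings=self.settings,
            w1=self.w1.copy(), w2=self.w2.copy(),
            input_scaler=AffineScaler(self.input_scaler.mins.copy(),
                                      self.input_scaler.ranges.copy()),
            target_scaler=AffineScaler(self.target_scaler.mins.copy(),
                                       self.target_scaler.ranges.copy()),
            frozen=self.frozen,
            training_error_history=list(self.training_error_history),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "settings": vars(self.settings),
            "w1": self.w1.tolist(), "w2": self.w2.tolist(),
            "input_mins": self.input_scaler.mins.tolist(),
            "input_ranges": self.input_scaler.ranges.tolist(),
            "target_mins": self.target_scaler.mins.tolist(),
            "target_ranges": self.target_scaler.ranges.tolist(),
            "frozen": self.frozen,
        })
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "MlpModel":
        p = Path(str(text_or_path))
        raw = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(raw)
        return cls(
            settings=MlpSettings(**d["settings"]),
            w1=np.array(d["w1"]), w2=np.array(d["w2"]),
            input_scaler=AffineScaler(np.array(d["input_mins"]), np.array(d["input_ranges"])),
            target_scaler=AffineScaler(np.array(d["target_mins"]), np.array(d["target_ranges"])),
            frozen=d["frozen"],
        )


def train_mlp(features, targets, settings: MlpSettings) -> MlpModel:
    """Train by online backpropagation; deterministic for a fixed seed."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if x.ndim != 2 or x.shape[1] != settings.n_inputs:
        raise DataContractError(
            f"expected {settings.n_inputs} feature columns, got {x.shape}"
        )
    if len(x) != len(y) or len(x) < 2:
        raise DataContractError("need >= 2 records with matching targets")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataContractError("non-finite values in features or targets")

    in_scaler = AffineScaler.fit(x)
    tg_scaler = AffineScaler.fit(y.reshape(-1, 1))
    xs = in_scaler.transform(x)
    ts = tg_scaler.transform(y.reshape(-1, 1)).ravel()

    rng = np.random.default_rng(settings.seed)
    w1 = rng.uniform(-settings.init_range, settings.init_range,
                     (settings.n_inputs + 1, settings.n_hidden))
    w2 = rng.uniform(-settings.init_range, settings.init_range,
                     settings.n_hidden + 1)
    history = _train_loop(
        xs, ts, w1, w2,
        settings.learning_rate, settings.momentum, settings.max_epochs,
        settings.early_stop_delta, settings.early_stop_patience,
    )
    return MlpModel(settings, w1, w2, in_scaler, tg_scaler,
                    training_error_history=[float(v) for v in history])


def predict(model: MlpModel, features) -> np.ndarray:
    """Forward pass + inverse target scaling; pure function of the model."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.settings.n_inputs:
        raise DataContractError(
            f"expected {model.settings.n_inputs} feature columns, got {x.shape}"
        )
    xs = model.input_scaler.transform(x)
    d = xs.shape[1]
    a1 = 1.0 / (1.0 + np.exp(-(xs @ model.w1[:d] + model.w1[d])))
    nh = a1.shape[1]
    a2 = 1.0 / (1.0 + np.exp(-(a1 @ model.w2[:nh] + model.w2[nh])))
    return model.target_scaler.inverse(a2.reshape(-1, 1)).ravel()


@dataclass
class TwoRunReport:
    """Outcome of the A/B–B/A frozen-weights protocol."""

    ids_a: list
    ids_b: list
    run_ab: np.ndarray          # predictions on B (model trained on A)
    run_ba: np.ndarray          # predictions on A (model trained on B)
    metrics_ab: FitMetrics
    metrics_ba: FitMetrics
    averaged_metrics: FitMetrics
    model_a: MlpModel
    model_b: MlpModel

    @property
    def combined(self) -> dict:
        """One out-of-sample prediction per record, keyed by id."""
        out = {i: float(p) for i, p in zip(self.ids_b, self.run_ab)}
        out.update({i: float(p) for i, p in zip(self.ids_a, self.run_ba)})
        return out


def two_run_protocol(
    features_a, targets_a, features_b, targets_b,
    settings: MlpSettings,
    ids_a=None, ids_b=None,
    method: str = "neural_network",
) -> TwoRunReport:
    """Run the six-step protocol: A→B then B→A with virgin twin networks.

    Subsets must be disjoint (checked when ids are given). Metrics are
    computed per testing run and averaged field-wise, matching how the
    accuracy of the two independent testing sets is reported.
    """
    fa = np.asarray(features_a, dtype=float)
    fb = np.asarray(features_b, dtype=float)
    ya = np.asarray(targets_a, dtype=float).ravel()
    yb = np.asarray(targets_b, dtype=float).ravel()
    ids_a = list(ids_a) if ids_a is not None else [f"A{i}" for i in range(len(fa))]
    ids_b = list(ids_b) if ids_b is not None else [f"B{i}" for i in range(len(fb))]
    if set(ids_a) & set(ids_b):
        raise DataContractError("subsets A and B overlap")

    model_a = train_mlp(fa, ya, settings).freeze()
    pred_b = predict(model_a.clone_virgin(), fb)   # virgin twin scores B

    model_b = train_mlp(fb, yb, replace(settings, seed=settings.seed + 1)).freeze()
    pred_a = predict(model_b.clone_virgin(), fa)

    m_ab = fit_metrics(pred_b, yb, method=f"{method}_ab")
    m_ba = fit_metrics(pred_a, ya, method=f"{method}_ba")
    return TwoRunReport(
        ids_a=ids_a, ids_b=ids_b,
        run_ab=pred_b, run_ba=pred_a,
        metrics_ab=m_ab, metrics_ba=m_ba,
        averaged_metrics=FitMetrics.average(m_ab, m_ba, method=method),
        model_a=model_a, model_b=model_b,
    )
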