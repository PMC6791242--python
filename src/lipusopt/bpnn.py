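"""Feed-forward neural network with back-propagation, written from first
principles.

The network has one hidden layer. The hidden output is
``y_j = f(sum_i w_ij x_i - a_j)`` with f the hidden activation (logistic
sigmoid by default) and a_j a trained threshold; the output is the plain
linear sum ``O_k = sum_j y_j w_jk - a_k`` with no output activation.
Training is sequential (per-sample) gradient descent on the squared-
error function ``E = 1/2 * sum_k (d_k - O_k)^2`` with a fixed learning
rate — the classic per-pattern delta rule, applied in a fixed
presentation order so epochs are deterministic; both weights and
thresholds are updated. Stopping is on a mean-squared-error goal or an
epoch cap.

All randomness flows through a seed, so training is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "NetworkTopology",
    "NetworkParameters",
    "TrainingConfig",
    "TrainingTrace",
    "Scaler",
    "fit_scaler",
    "forward",
    "backprop_epoch",
    "train",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _sigmoid_prime_from_y(y: np.ndarray) -> np.ndarray:
    return y * (1.0 - y)


def _identity(z: np.ndarray) -> np.ndarray:
    return z


def _identity_prime_from_y(y: np.ndarray) -> np.ndarray:
    return np.ones_like(y)


# activation -> (f, f' expressed through the activation's output)
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "sigmoid": (_sigmoid, _sigmoid_prime_from_y),
    "identity": (_identity, _identity_prime_from_y),
}


@dataclass(frozen=True)
class NetworkTopology:
    """Layer sizes; the study's surrogate uses 3 inputs, 8 hidden, 1 output."""

    n_input: int = 3
    n_hidden: int = 8
    n_output: int = 1

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError(f"all layer sizes must be >= 1, got {self}")

    @property
    def n_params(self) -> int:
        return (
            self.n_input * self.n_hidden
            + self.n_hidden * self.n_output
            + self.n_hidden
            + self.n_output
        )


@dataclass
class NetworkParameters:
    """All weights and thresholds: w_in_hidden[i, j], w_hidden_out[j, k],
    thresh_hidden[j] (a_j), thresh_out[k] (a_k)."""

    w_in_hidden: np.ndarray
    w_hidden_out: np.ndarray
    thresh_hidden: np.ndarray
    thresh_out: np.ndarray

    def __post_init__(self) -> None:
        self.w_in_hidden = np.asarray(self.w_in_hidden, dtype=float)
        self.w_hidden_out = np.asarray(self.w_hidden_out, dtype=float)
        self.thresh_hidden = np.asarray(self.thresh_hidden, dtype=float)
        self.thresh_out = np.asarray(self.thresh_out, dtype=float)
        t = self.topology
        if self.w_in_hidden.shape != (t.n_input, t.n_hidden):
            raise ValueError("w_in_hidden shape inconsistent")
        if self.w_hidden_out.shape != (t.n_hidden, t.n_output):
            raise ValueError("w_hidden_out shape inconsistent with hidden layer")
        for a in (self.w_in_hidden, self.w_hidden_out, self.thresh_hidden, self.thresh_out):
            if not np.all(np.isfinite(a)):
                raise ValueError("network parameters must be finite")

    @property
    def topology(self) -> NetworkTopology:
        n_in, n_hid = self.w_in_hidden.shape
        return NetworkTopology(n_in, n_hid, len(self.thresh_out))

    @classmethod
    def random(cls, topology: NetworkTopology, rng) -> "NetworkParameters":
        """Uniform [-1, 1] initialization, used when no GA seeds the weights."""
        rng = np.random.default_rng(rng)
        t = topology
        return cls(
            rng.uniform(-1, 1, (t.n_input, t.n_hidden)),
            rng.uniform(-1, 1, (t.n_hidden, t.n_output)),
            rng.uniform(-1, 1, t.n_hidden),
            rng.uniform(-1, 1, t.n_output),
        )

    # flat vector layout: w_in_hidden (row-major), w_hidden_out (row-major),
    # thresh_hidden, thresh_out — also the GA gene layout
    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.w_in_hidden.ravel(),
                self.w_hidden_out.ravel(),
                self.thresh_hidden,
                self.thresh_out,
            ]
        )

    @classmethod
    def from_vector(cls, topology: NetworkTopology, vec: Sequence[float]) -> "NetworkParameters":
        vec = np.asarray(vec, dtype=float)
        t = topology
        if vec.size != t.n_params:
            raise ValueError(f"expected {t.n_params} parameters, got {vec.size}")
        i = t.n_input * t.n_hidden
        j = i + t.n_hidden * t.n_output
        k = j + t.n_hidden
        return cls(
            vec[:i].reshape(t.n_input, t.n_hidden),
            vec[i:j].reshape(t.n_hidden, t.n_output),
            vec[j:k].copy(),
            vec[k:].copy(),
        )

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            self.w_in_hidden.copy(),
            self.w_hidden_out.copy(),
            self.thresh_hidden.copy(),
            self.thresh_out.copy(),
        )

    def to_json(self) -> str:
        t = self.topology
        doc = {
            "layout": "w_in_hidden(row-major),w_hidden_out(row-major),thresh_hidden,thresh_out",
            "topology": {"n_input": t.n_input, "n_hidden": t.n_hidden, "n_output": t.n_output},
            "values": self.to_vector().tolist(),
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NetworkParameters":
        doc = json.loads(text)
        t = NetworkTopology(**doc["topology"])
        return cls.from_vector(t, doc["values"])


@dataclass(frozen=True)
class TrainingConfig:
    """Back-propagation settings: learning rate in (0, 1), epoch cap and the
    mean-squared-error goal (on scaled targets) at which training stops."""

    learning_rate: float = 0.1
    max_epochs: int = 1000
    error_goal: float = 1e-4
    rng_seed: int | None = None
    hidden_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate < 1:
            raise ValueError(f"learning_rate must be in (0,1), got {self.learning_rate}")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.error_goal <= 0:
            raise ValueError("error_goal must be > 0")
        if self.hidden_activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.hidden_activation!r}")


@dataclass
class TrainingTrace:
    """Per-epoch training MSE (measured at epoch entry) and why training stopped."""

    mse: np.ndarray
    stop_reason: str  # "error_goal" | "max_epochs"

    @property
    def epochs_run(self) -> int:
        return len(self.mse)


def forward(
    params: NetworkParameters,
    x: np.ndarray,
    hidden_activation: str = "sigmoid",
) -> tuple[np.ndarray, np.ndarray]:
    """Compute hidden outputs and predictions for one sample or a batch.

    Returns ``(y, O)`` with ``y_j = f(sum_i w_ij x_i - a_j)`` and the
    linear output ``O_k = sum_j y_j w_jk - a_k``. A 1-D ``x`` yields 1-D
    outputs; a 2-D batch yields 2-D outputs.
    """
    f, _ = ACTIVATIONS[hidden_activation]
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.w_in_hidden.shape[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {params.w_in_hidden.shape[0]}"
        )
    Y = f(X @ params.w_in_hidden - params.thresh_hidden)
    O = Y @ params.w_hidden_out - params.thresh_out
    if single:
        return Y[0], O[0]
    return Y, O


def backprop_epoch(
    params: NetworkParameters,
    X: np.ndarray,
    D: np.ndarray,
    cfg: TrainingConfig,
) -> tuple[NetworkParameters, float]:
    """One training epoch: sequential per-sample gradient-descent updates.

    Each sample is presented in order and every weight and threshold is
    updated immediately from that sample's error: weights move by
    eta * e_k * y_j * f'(net_k) (with f'(net_k) = 1 at the linear output)
    and the hidden-layer analogue; thresholds enter the net input with a
    minus sign, so their updates carry the opposite sign. Presentation
    order is fixed, so an epoch is deterministic. Returns the new
    parameters and the epoch MSE — the mean over samples of
    E = 1/2 sum_k (d_k - O_k)^2, each term evaluated just before that
    sample's update.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if len(X) == 0:
        raise ValueError("batch must be nonempty")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(D))):
        raise ValueError("inputs and targets must be finite")
    f, fprime = ACTIVATIONS[cfg.hidden_activation]
    eta = cfg.learning_rate

    W1 = params.w_in_hidden.copy()
    W2 = params.w_hidden_out.copy()
    a1 = params.thresh_hidden.copy()
    a2 = params.thresh_out.copy()
    errors = np.empty(len(X))
    for i, (x, d) in enumerate(zip(X, D)):
        y = f(x @ W1 - a1)
        o = y @ W2 - a2
        e = d - o
        errors[i] = 0.5 * np.dot(e, e)
        delta_h = (W2 @ e) * fprime(y)
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(delta_h))):
            raise FloatingPointError(f"non-finite gradient at sample {i}")
        W2 += eta * np.outer(y, e)
        a2 -= eta * e
        W1 += eta * np.outer(x, delta_h)
        a1 -= eta * delta_h
    return NetworkParameters(W1, W2, a1, a2), float(np.mean(errors))


def train(
    params0: NetworkParameters,
    X: np.ndarray,
    D: np.ndarray,
    cfg: TrainingConfig,
) -> tuple[NetworkParameters, TrainingTrace]:
    """Run back-propagation epochs until the MSE goal is met or the epoch
    cap is reached. The recorded epoch MSE is the error at epoch entry, so
    a network that already meets the goal stops at epoch 1 unchanged (its
    gradient is zero)."""
    params = params0.copy()
    history: list[float] = []
    stop = "max_epochs"
    for _ in range(cfg.max_epochs):
        params, mse = backprop_epoch(params, X, D, cfg)
        history.append(mse)
        if mse <= cfg.error_goal:
            stop = "error_goal"
            break
    return params, TrainingTrace(np.asarray(history), stop)


# ---------------------------------------------------------------------------
# min–max scaling


@dataclass(frozen=True)
class Scaler:
    """Per-dimension min–max map to [0, 1]; constant dimensions map to 0.5.

    ``invert(apply(x)) == x`` to floating-point precision for
    non-degenerate dimensions.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mins", np.atleast_1d(np.asarray(self.mins, dtype=float)))
        object.__setattr__(self, "maxs", np.atleast_1d(np.asarray(self.maxs, dtype=float)))
        if self.mins.shape != self.maxs.shape:
            raise ValueError("mins and maxs must have the same shape")
        if np.any(self.maxs < self.mins):
            raise ValueError("each max must be >= its min")

    @property
    def span(self) -> np.ndarray:
        return np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(self.maxs > self.mins, (x - self.mins) / self.span, 0.5)

    def invert(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return np.where(self.maxs > self.mins, self.mins + z * self.span, self.mins)


def fit_scaler(bounds: np.ndarray, allow_degenerate: bool = False) -> Scaler:
    """Build a Scaler from per-dimension (lower, upper) bounds.

    Fully degenerate bounds (every dimension constant) are refused unless
    ``allow_degenerate`` is set.
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    if bounds.shape[-1] != 2:
        raise ValueError("bounds must be (n_dims, 2)")
    mins, maxs = bounds[:, 0], bounds[:, 1]
    if not allow_degenerate and np.all(maxs <= mins):
        raise ValueError("degenerate bounds: no dimension has max > min")
    return Scaler(mins, maxs)
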