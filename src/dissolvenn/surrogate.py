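"""Feedforward surrogate of the composition → release-profile map.

A single-hidden-layer perceptron (default 6-10-10: six excipient masses
in, ten release percentages out) with a tanh hidden layer and a linear
output layer is trained by the Levenberg–Marquardt algorithm on
min-max-normalized inputs and targets.  LM interpolates between
gradient descent and Gauss–Newton through an adaptive damping factor
mu: each step solves

    (JᵀJ + mu·I) Δθ = −Jᵀe

for the flattened weight vector θ, where J is the Jacobian of the
per-sample, per-output residuals e; a step is accepted only if it
reduces the training sum of squared errors, otherwise mu is escalated
and the step retried.  Samples are split 70/15/15 into training,
validation and test subsets; validation error drives early stopping.

The public surface is both a scikit-learn estimator
(:class:`MLPSurrogate`) and thin functional wrappers
(:func:`train_lm`, :func:`forward`, ...) over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .design import Formulation
from .profiles import DissolutionProfile

__all__ = [
    "SurrogateModel",
    "TrainConfig",
    "TrainReport",
    "EpochRecord",
    "MLPSurrogate",
    "split_data",
    "fit_norm",
    "normalize",
    "denormalize",
    "forward",
    "train_lm",
    "regression_metrics",
    "levenberg_marquardt",
    "save_model",
    "load_model",
    "study_matrices",
]


# ---------------------------------------------------------------------------
# configuration and report containers


@dataclass(frozen=True)
class TrainConfig:
    """Knobs of the LM training loop.

    The damping schedule (mu_init 0.001, ×10 up, ×0.1 down, cap 1e10)
    and the validation patience of 6 follow the long-standing MATLAB
    ``trainlm`` conventions for this architecture.
    """

    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    n_hidden: int = 10
    max_epochs: int = 1000
    mse_goal: float = 0.0
    mu_init: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    patience: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if min(fracs) <= 0:
            raise ValueError("split fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions sum to {sum(fracs)}, not 1")
        if min(self.mu_init, self.mu_increase, self.mu_decrease, self.mu_max) <= 0:
            raise ValueError("mu parameters must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    train_mse: float
    val_mse: float
    mu: float
    accepted: bool = True


@dataclass
class TrainReport:
    """Everything the training loop saw: per-epoch errors, stop reason,
    per-subset regression coefficients and the sample partition."""

    epochs: list[EpochRecord] = field(default_factory=list)
    stop_reason: str = ""
    final_epoch: int = 0
    r_values: dict[str, float | None] = field(default_factory=dict)
    partition: dict[str, list[int]] = field(default_factory=dict)

    @property
    def train_mse_path(self) -> np.ndarray:
        return np.array([e.train_mse for e in self.epochs])

    @property
    def val_mse_path(self) -> np.ndarray:
        return np.array([e.val_mse for e in self.epochs])


@dataclass(frozen=True)
class SurrogateModel:
    """Weights, biases and normalization ranges of a k-m-n network."""

    hidden_weights: np.ndarray  #: (m, k)
    hidden_biases: np.ndarray  #: (m,)
    output_weights: np.ndarray  #: (n, m)
    output_biases: np.ndarray  #: (n,)
    input_min: np.ndarray  #: (k,)
    input_max: np.ndarray  #: (k,)
    output_min: np.ndarray  #: (n,)
    output_max: np.ndarray  #: (n,)
    times: np.ndarray | None = None  #: output time grid (h), length n
    seed: int | None = None

    def __post_init__(self) -> None:
        m, k = np.shape(self.hidden_weights)
        n = np.shape(self.output_biases)[0]
        shapes = {
            "hidden_biases": (np.shape(self.hidden_biases), (m,)),
            "output_weights": (np.shape(self.output_weights), (n, m)),
            "input_min": (np.shape(self.input_min), (k,)),
            "input_max": (np.shape(self.input_max), (k,)),
            "output_min": (np.shape(self.output_min), (n,)),
            "output_max": (np.shape(self.output_max), (n,)),
        }
        for name, (got, want) in shapes.items():
            if got != want:
                raise ValueError(f"{name}: shape {got}, expected {want}")
        if np.any(self.input_min > self.input_max) or np.any(
            self.output_min > self.output_max
        ):
            raise ValueError("normalization min exceeds max")

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.output_weights.shape[0]


# ---------------------------------------------------------------------------
# data partition and normalization


def split_data(
    n_samples: int, cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive train/validation/test index sets.

    Validation and test sizes are the rounded fractions of ``n_samples``;
    every remaining sample goes to training.  The shuffle is seeded, so
    one seed gives one partition.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples to split")
    n_val = int(round(n_samples * cfg.val_frac))
    n_test = int(round(n_samples * cfg.test_frac))
    n_train = n_samples - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split of {n_samples} samples leaves an empty subset "
            f"(train {n_train}, val {n_val}, test {n_test}); use more "
            "samples or different fractions"
        )
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n_samples)
    return (
        np.sort(perm[:n_train]),
        np.sort(perm[n_train : n_train + n_val]),
        np.sort(perm[n_train + n_val :]),
    )


def fit_norm(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension (min, max) of a (samples, dims) matrix."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return data.min(axis=0), data.max(axis=0)


def normalize(
    data: np.ndarray, mins: np.ndarray, maxs: np.ndarray
) -> np.ndarray:
    """Map to [-1, 1] per dimension; degenerate dimensions map to 0."""
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)
    out = 2.0 * (data - mins) / safe - 1.0
    return np.where(span > 0, out, 0.0)


def denormalize(
    data: np.ndarray, mins: np.ndarray, maxs: np.ndarray
) -> np.ndarray:
    """Inverse of :func:`normalize`; degenerate dimensions return min."""
    span = maxs - mins
    out = (data + 1.0) / 2.0 * span + mins
    return np.where(span > 0, out, mins)


# ---------------------------------------------------------------------------
# forward pass


def forward(model: SurrogateModel, inputs: np.ndarray) -> np.ndarray:
    """Network output for one input vector or a batch of rows.

    hidden a = tanh(W1 · x_norm + b1); output y_norm = W2 · a + b2;
    the return value is denormalized to the target units.
    """
    x = np.asarray(inputs, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.n_inputs:
        raise ValueError(
            f"expected inputs with {model.n_inputs} features, got shape "
            f"{np.shape(inputs)}"
        )
    xn = normalize(x, model.input_min, model.input_max)
    a = np.tanh(xn @ model.hidden_weights.T + model.hidden_biases)
    yn = a @ model.output_weights.T + model.output_biases
    y = denormalize(yn, model.output_min, model.output_max)
    return y[0] if single else y


# ---------------------------------------------------------------------------
# Levenberg-Marquardt engine


def levenberg_marquardt(
    residual: Callable[[np.ndarray], np.ndarray],
    jacobian: Callable[[np.ndarray], np.ndarray],
    theta0: np.ndarray,
    *,
    mu_init: float = 1e-3,
    mu_increase: float = 10.0,
    mu_decrease: float = 0.1,
    mu_max: float = 1e10,
    max_epochs: int = 1000,
    sse_goal: float = 0.0,
    on_accept: Callable[[int, np.ndarray, float, float], str | None] = None,
) -> tuple[np.ndarray, list[tuple[int, float, float]], str]:
    """Damped Gauss–Newton minimisation of ||residual(θ)||².

    ``on_accept(epoch, theta, sse, mu)`` runs after every accepted step
    and may return a non-empty string to stop training (used for
    validation-based early stopping).  Returns the final parameters, the
    accepted-step trace ``(epoch, sse, mu)`` and the stop reason.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    e = residual(theta)
    sse = float(e @ e)
    if not np.isfinite(sse):
        raise FloatingPointError("non-finite loss at initialization")
    mu = mu_init
    trace: list[tuple[int, float, float]] = []
    stop = ""
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        J = jacobian(theta)
        g = J.T @ e
        JtJ = J.T @ J
        identity = np.eye(theta.size)
        accepted = False
        solved_once = False
        while mu <= mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * identity, -g)
                solved_once = True
            except np.linalg.LinAlgError:
                mu *= mu_increase
                continue
            theta_new = theta + delta
            e_new = residual(theta_new)
            sse_new = float(e_new @ e_new)
            if not np.isfinite(sse_new):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}"
                )
            if sse_new < sse:
                theta, e, sse = theta_new, e_new, sse_new
                mu = max(mu * mu_decrease, np.finfo(float).tiny)
                accepted = True
                break
            mu *= mu_increase
        if not accepted:
            if not solved_once:
                raise np.linalg.LinAlgError(
                    "J'J + mu*I singular for every damping value up to "
                    f"mu_max={mu_max:g}"
                )
            stop = "mu_max"
            break
        trace.append((epoch, sse, mu))
        if sse <= sse_goal:
            stop = "mse_goal"
            break
        if on_accept is not None:
            reason = on_accept(epoch, theta, sse, mu)
            if reason:
                stop = reason
                break
    if not stop:
        stop = "max_epochs"
    return theta, trace, stop


# ---------------------------------------------------------------------------
# MLP parameter packing and Jacobian


def _init_params(
    k: int, m: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform [-0.5, 0.5] weights scaled by 1/sqrt(fan-in); zero biases."""
    w1 = rng.uniform(-0.5, 0.5, size=(m, k)) / np.sqrt(k)
    b1 = np.zeros(m)
    w2 = rng.uniform(-0.5, 0.5, size=(n, m)) / np.sqrt(m)
    b2 = np.zeros(n)
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(theta: np.ndarray, k: int, m: int, n: int):
    o1 = m * k
    o2 = o1 + m
    o3 = o2 + n * m
    return (
        theta[:o1].reshape(m, k),
        theta[o1:o2],
        theta[o2:o3].reshape(n, m),
        theta[o3:],
    )


def _mlp_residual(theta, xn, tn, k, m, n):
    w1, b1, w2, b2 = _unpack(theta, k, m, n)
    a = np.tanh(xn @ w1.T + b1)
    return (a @ w2.T + b2 - tn).ravel()


def _mlp_jacobian(theta, xn, k, m, n):
    """Analytic Jacobian of the residuals by per-component backprop.

    Row order matches the residual raveling (sample-major, then output);
    column order matches the parameter packing (W1, b1, W2, b2).
    """
    w1, b1, w2, b2 = _unpack(theta, k, m, n)
    N = xn.shape[0]
    a = np.tanh(xn @ w1.T + b1)  # (N, m)
    d = 1.0 - a**2  # tanh'(z)
    # dr[i,j]/dW1[h,l] = W2[j,h] * d[i,h] * x[i,l]
    G = w2[None, :, :] * d[:, None, :]  # (N, n, m)
    J_w1 = (G[:, :, :, None] * xn[:, None, None, :]).reshape(N * n, m * k)
    J_b1 = G.reshape(N * n, m)
    eye = np.eye(n)
    # dr[i,j]/dW2[q,h] = delta(j=q) * a[i,h]
    J_w2 = (eye[None, :, :, None] * a[:, None, None, :]).reshape(N * n, n * m)
    J_b2 = np.tile(eye, (N, 1))
    return np.hstack([J_w1, J_b1, J_w2, J_b2])


# ---------------------------------------------------------------------------
# scikit-learn estimator


class MLPSurrogate(RegressorMixin, BaseEstimator):
    """Levenberg–Marquardt-trained single-hidden-layer MLP regressor.

    Parameters mirror :class:`TrainConfig`; ``random_state`` seeds the
    sample partition and the weight initialization.  After ``fit`` the
    trained network lives in ``model_`` (a :class:`SurrogateModel`) and
    the training history in ``report_`` (a :class:`TrainReport`).

    Examples
    --------
    >>> est = MLPSurrogate(n_hidden=10, random_state=0)
    >>> est.fit(X, Y).predict(X[:1])          # doctest: +SKIP
    """

    def __init__(
        self,
        n_hidden: int = 10,
        train_frac: float = 0.70,
        val_frac: float = 0.15,
        test_frac: float = 0.15,
        max_epochs: int = 1000,
        mse_goal: float = 0.0,
        mu_init: float = 1e-3,
        mu_increase: float = 10.0,
        mu_decrease: float = 0.1,
        mu_max: float = 1e10,
        patience: int = 6,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.train_frac = train_frac
        self.val_frac = val_frac
        self.test_frac = test_frac
        self.max_epochs = max_epochs
        self.mse_goal = mse_goal
        self.mu_init = mu_init
        self.mu_increase = mu_increase
        self.mu_decrease = mu_decrease
        self.mu_max = mu_max
        self.patience = patience
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            train_frac=self.train_frac,
            val_frac=self.val_frac,
            test_frac=self.test_frac,
            n_hidden=self.n_hidden,
            max_epochs=self.max_epochs,
            mse_goal=self.mse_goal,
            mu_init=self.mu_init,
            mu_increase=self.mu_increase,
            mu_decrease=self.mu_decrease,
            mu_max=self.mu_max,
            patience=self.patience,
            seed=self.random_state,
        )

    def fit(self, X, y, times: Sequence[float] | None = None):
        X = check_array(X, dtype=float)
        Y = check_array(y, dtype=float, ensure_2d=False)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} samples but y has {Y.shape[0]}"
            )
        cfg = self._config()
        k, m, n = X.shape[1], cfg.n_hidden, Y.shape[1]
        train_idx, val_idx, test_idx = split_data(X.shape[0], cfg)

        in_min, in_max = fit_norm(X[train_idx])
        out_min, out_max = fit_norm(Y[train_idx])
        xn = normalize(X, in_min, in_max)
        tn = normalize(Y, out_min, out_max)
        xn_tr, tn_tr = xn[train_idx], tn[train_idx]
        xn_val, tn_val = xn[val_idx], tn[val_idx]

        rng = np.random.default_rng(cfg.seed)
        theta0 = _init_params(k, m, n, rng)
        n_train_res = tn_tr.size

        report = TrainReport(
            partition={
                "train": train_idx.tolist(),
                "validation": val_idx.tolist(),
                "test": test_idx.tolist(),
            }
        )
        best = {"val": np.inf, "theta": theta0.copy(), "fails": 0}

        def val_mse(theta: np.ndarray) -> float:
            r = _mlp_residual(theta, xn_val, tn_val, k, m, n)
            return float(r @ r) / r.size

        def on_accept(epoch, theta, sse, mu):
            v = val_mse(theta)
            report.epochs.append(
                EpochRecord(
                    epoch=epoch,
                    train_mse=sse / n_train_res,
                    val_mse=v,
                    mu=mu,
                )
            )
            if v < best["val"]:
                best.update(val=v, theta=theta.copy(), fails=0)
                return None
            best["fails"] += 1
            if best["fails"] >= cfg.patience:
                return "validation_patience"
            return None

        theta, _, stop = levenberg_marquardt(
            lambda th: _mlp_residual(th, xn_tr, tn_tr, k, m, n),
            lambda th: _mlp_jacobian(th, xn_tr, k, m, n),
            theta0,
            mu_init=cfg.mu_init,
            mu_increase=cfg.mu_increase,
            mu_decrease=cfg.mu_decrease,
            mu_max=cfg.mu_max,
            max_epochs=cfg.max_epochs,
            sse_goal=cfg.mse_goal * n_train_res,
            on_accept=on_accept,
        )
        if stop == "validation_patience":
            theta = best["theta"]

        w1, b1, w2, b2 = _unpack(theta, k, m, n)
        self.model_ = SurrogateModel(
            hidden_weights=w1,
            hidden_biases=b1,
            output_weights=w2,
            output_biases=b2,
            input_min=in_min,
            input_max=in_max,
            output_min=out_min,
            output_max=out_max,
            times=None if times is None else np.asarray(times, dtype=float),
            seed=cfg.seed,
        )
        report.stop_reason = stop
        report.final_epoch = report.epochs[-1].epoch if report.epochs else 0
        report.r_values = regression_metrics(
            self.model_, X, Y, report.partition
        )
        self.report_ = report
        self.n_features_in_ = k
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        return forward(self.model_, X)


# ---------------------------------------------------------------------------
# functional wrappers


def study_matrices(
    data: Sequence[tuple[Formulation, DissolutionProfile]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a study into X (samples × excipients), Y (samples × times)
    and the shared time vector; errors if batches disagree on times."""
    if not len(data):
        raise ValueError("no samples")
    times = data[0][1].times
    for i, (_, prof) in enumerate(data):
        if not np.array_equal(prof.times, times):
            raise ValueError(f"batch {i} sampled on a different time grid")
    X = np.vstack([form.as_array() for form, _ in data])
    Y = np.vstack([prof.release for _, prof in data])
    return X, Y, times


def train_lm(
    data: Sequence[tuple[Formulation, DissolutionProfile]],
    cfg: TrainConfig | None = None,
) -> tuple[SurrogateModel, TrainReport]:
    """Train the surrogate on (formulation, profile) pairs."""
    cfg = cfg or TrainConfig()
    if len(data) < 3:
        raise ValueError("need at least 3 samples to train")
    X, Y, times = study_matrices(data)
    est = MLPSurrogate(
        n_hidden=cfg.n_hidden,
        train_frac=cfg.train_frac,
        val_frac=cfg.val_frac,
        test_frac=cfg.test_frac,
        max_epochs=cfg.max_epochs,
        mse_goal=cfg.mse_goal,
        mu_init=cfg.mu_init,
        mu_increase=cfg.mu_increase,
        mu_decrease=cfg.mu_decrease,
        mu_max=cfg.mu_max,
        patience=cfg.patience,
        random_state=cfg.seed,
    ).fit(X, Y, times=times)
    return est.model_, est.report_


def regression_metrics(
    model: SurrogateModel,
    X: np.ndarray,
    Y: np.ndarray,
    partition: dict[str, list[int]],
) -> dict[str, float | None]:
    """Pearson R between flattened predictions and targets per subset.

    Subsets whose flattened size is below 2, or with zero variance on
    either side, report ``None`` rather than a fabricated number.
    """
    pred = forward(model, np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    out: dict[str, float | None] = {}
    subsets = dict(partition)
    subsets["all"] = sorted(
        i for idx in partition.values() for i in idx
    )
    for name, idx in subsets.items():
        p = pred[list(idx)].ravel()
        t = Y[list(idx)].ravel()
        if p.size < 2 or np.std(p) == 0 or np.std(t) == 0:
            out[name] = None
            continue
        out[name] = float(np.corrcoef(p, t)[0, 1])
    return out


# ---------------------------------------------------------------------------
# serialization


def _model_to_dict(model: SurrogateModel) -> dict:
    doc = {
        "layer_sizes": [model.n_inputs, model.n_hidden, model.n_outputs],
        "seed": model.seed,
        "times": None if model.times is None else model.times.tolist(),
    }
    for name in (
        "hidden_weights",
        "hidden_biases",
        "output_weights",
        "output_biases",
        "input_min",
        "input_max",
        "output_min",
        "output_max",
    ):
        doc[name] = getattr(model, name).tolist()
    return doc


def save_model(model: SurrogateModel, path: str | Path) -> None:
    """Write the model as a portable JSON document (exact float round-trip)."""
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=1))


def load_model(path: str | Path) -> SurrogateModel:
    doc = json.loads(Path(path).read_text())
    times = doc.get("times")
    return SurrogateModel(
        hidden_weights=np.array(doc["hidden_weights"], dtype=float),
        hidden_biases=np.array(doc["hidden_biases"], dtype=float),
        output_weights=np.array(doc["output_weights"], dtype=float),
        output_biases=np.array(doc["output_biases"], dtype=float),
        input_min=np.array(doc["input_min"], dtype=float),
        input_max=np.array(doc["input_max"], dtype=float),
        output_min=np.array(doc["output_min"], dtype=float),
        output_max=np.array(doc["output_max"], dtype=float),
        times=None if times is None else np.array(times, dtype=float),
        seed=doc.get("seed"),
    )
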