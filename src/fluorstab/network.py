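"""Single-hidden-layer feedforward network trained by Levenberg–Marquardt.

Architecture: ``y = W2·tanh(W1·x + b1) + b2`` — one hidden layer of tanh
(sigmoid) units (default 20) and a linear output layer, the classic
shallow-regression network.  Inputs and targets are min–max scaled to
[−1, 1] column-wise, with scaling fitted on the training split only.

Training minimizes the sum of squared errors with the damped Gauss–Newton
update

    x_{k+1} = x_k − (JᵀJ + μI)⁻¹ Jᵀe,

where ``J`` is the analytic Jacobian of the per-sample, per-output errors
``e = target − prediction`` with respect to all weights and biases, and μ is
the damping scalar: μ → 0 gives the Gauss–Newton step, μ → ∞ a short
gradient-descent step.  μ is decreased after each accepted step and
increased when a tentative step would raise the error, so the training-set
error is non-increasing across epochs by construction.

Errors are expressed in *original* intensity units (scaled errors weighted
by each target column's half-range), so the performance goal — an MSE of
20,000 a.u.², anchored to a 1.5% error of the average fluorescence — is
meaningful, and early stopping monitors the validation MSE on the same
scale: training stops at the goal, at the epoch cap (1000), after 10
consecutive epochs without a new best validation MSE, or when μ exceeds its
ceiling.  The weights from the best-validation epoch are returned.  Test-set
MSE is recorded per epoch for reporting but never influences training or
model selection.

JᵀJ and Jᵀe are accumulated over sample blocks, so the full Jacobian
(30,240 × 840 at the study's default sizes) never has to be materialized;
the block accumulation is exactly equivalent to the monolithic product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.linalg

__all__ = [
    "MinMaxScaling",
    "NetworkModel",
    "LMState",
    "TrainOptions",
    "TrainHistory",
    "scale_fit",
    "scale_apply",
    "scale_invert",
    "initialize_network",
    "n_parameters",
    "flatten_params",
    "set_params",
    "forward_pass",
    "network_jacobian",
    "accumulate_normal_equations",
    "lm_step",
    "train_network",
    "predict",
    "model_to_json",
    "model_from_json",
]


# ---------------------------------------------------------------------------
# Min–max scaling
# ---------------------------------------------------------------------------

@dataclass
class MinMaxScaling:
    """Column-wise [−1, 1] scaling; constant columns map to 0."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.mins.shape != self.maxs.shape or self.mins.ndim != 1:
            raise ValueError("mins/maxs must be matching 1-D arrays")
        if np.any(self.maxs < self.mins):
            raise ValueError("max below min in scaling")

    @property
    def half_range(self) -> np.ndarray:
        return (self.maxs - self.mins) / 2.0


def scale_fit(X: np.ndarray) -> MinMaxScaling:
    """Fit per-column min/max.  Call on the *training* rows only."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return MinMaxScaling(mins=X.min(axis=0), maxs=X.max(axis=0))


def scale_apply(X: np.ndarray, scaling: Optional[MinMaxScaling]) -> np.ndarray:
    """Map columns to [−1, 1]: min → −1, max → +1; constant columns → 0."""
    if scaling is None:
        raise ValueError("scaling has not been fitted")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    span = scaling.maxs - scaling.mins
    out = np.zeros_like(X)
    nz = span > 0
    out[:, nz] = 2.0 * (X[:, nz] - scaling.mins[nz]) / span[nz] - 1.0
    return out


def scale_invert(Y: np.ndarray, scaling: Optional[MinMaxScaling]) -> np.ndarray:
    """Inverse of :func:`scale_apply`; constant columns restore their value."""
    if scaling is None:
        raise ValueError("scaling has not been fitted")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    span = scaling.maxs - scaling.mins
    out = np.empty_like(Y)
    nz = span > 0
    out[:, nz] = scaling.mins[nz] + (Y[:, nz] + 1.0) * span[nz] / 2.0
    out[:, ~nz] = scaling.mins[~nz]
    return out


# ---------------------------------------------------------------------------
# Network model
# ---------------------------------------------------------------------------

@dataclass
class NetworkModel:
    """Weights, biases and the I/O scalings of the 1-hidden-layer network."""

    W1: np.ndarray  # (n_hidden, n_in)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_out, n_hidden)
    b2: np.ndarray  # (n_out,)
    input_scaling: Optional[MinMaxScaling] = None
    output_scaling: Optional[MinMaxScaling] = None

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        h, i = self.W1.shape
        o, h2 = self.W2.shape
        if h2 != h or self.b1.shape != (h,) or self.b2.shape != (o,):
            raise ValueError("inconsistent layer shapes")

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_out(self) -> int:
        return self.W2.shape[0]

    def copy(self) -> "NetworkModel":
        return NetworkModel(self.W1.copy(), self.b1.copy(),
                            self.W2.copy(), self.b2.copy(),
                            self.input_scaling, self.output_scaling)


def initialize_network(n_in: int, n_hidden: int, n_out: int,
                       seed: int) -> NetworkModel:
    """Seeded uniform [−0.5, 0.5] initialization scaled by 1/√fan-in,
    keeping the tanh units unsaturated for inputs in [−1, 1]."""
    if min(n_in, n_hidden, n_out) < 1:
        raise ValueError("all layer sizes must be at least 1")
    rng = np.random.default_rng(seed)
    w1 = rng.uniform(-0.5, 0.5, size=(n_hidden, n_in)) / np.sqrt(n_in)
    b1 = rng.uniform(-0.5, 0.5, size=n_hidden) / np.sqrt(n_in)
    w2 = rng.uniform(-0.5, 0.5, size=(n_out, n_hidden)) / np.sqrt(n_hidden)
    b2 = rng.uniform(-0.5, 0.5, size=n_out) / np.sqrt(n_hidden)
    return NetworkModel(w1, b1, w2, b2)


def n_parameters(net: NetworkModel) -> int:
    return net.W1.size + net.b1.size + net.W2.size + net.b2.size


def flatten_params(net: NetworkModel) -> np.ndarray:
    """Parameter vector layout: [W1, b1, W2, b2], each C-ravelled."""
    return np.concatenate([net.W1.ravel(), net.b1, net.W2.ravel(), net.b2])


def set_params(net: NetworkModel, x: np.ndarray) -> NetworkModel:
    """Write a flat parameter vector back into (a copy of) the model."""
    h, i, o = net.n_hidden, net.n_in, net.n_out
    if x.size != n_parameters(net):
        raise ValueError("parameter vector length mismatch")
    out = net.copy()
    k = 0
    out.W1 = x[k:k + h * i].reshape(h, i).copy(); k += h * i
    out.b1 = x[k:k + h].copy(); k += h
    out.W2 = x[k:k + o * h].reshape(o, h).copy(); k += o * h
    out.b2 = x[k:].copy()
    return out


def forward_pass(net: NetworkModel, X: np.ndarray) -> np.ndarray:
    """Scaled-space forward evaluation: W2·tanh(W1·x + b1) + b2, row-wise."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.n_in:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {net.n_in}")
    hidden = np.tanh(X @ net.W1.T + net.b1)
    return hidden @ net.W2.T + net.b2


# ---------------------------------------------------------------------------
# Jacobian and LM step
# ---------------------------------------------------------------------------

@dataclass
class LMState:
    """One Levenberg–Marquardt iterate: parameters, error Jacobian, errors
    and the damping scalar μ."""

    x: np.ndarray
    J: np.ndarray  # (n_samples·n_out, n_params), ∂e/∂x
    e: np.ndarray  # (n_samples·n_out,), target − prediction
    mu: float

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.J.shape[0] != self.e.size or self.J.shape[1] != self.x.size:
            raise ValueError("J/e/x shapes inconsistent")


def _jacobian_block(net: NetworkModel, X: np.ndarray,
                    weights: Optional[np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    """Dense error-Jacobian rows for a sample block.

    Returns ``(J_block, pred)`` with ``J_block`` of shape
    (B·n_out, n_params); row order is sample-major, output-minor, matching
    ``e = (T − pred).ravel()``.  ``weights`` (per output column) multiply the
    error rows, expressing them in original intensity units.
    """
    B = X.shape[0]
    h, i, o = net.n_hidden, net.n_in, net.n_out
    z = X @ net.W1.T + net.b1
    hid = np.tanh(z)
    pred = hid @ net.W2.T + net.b2
    g = 1.0 - hid ** 2  # tanh'

    # ∂ŷ_k/∂W1_{m,j} = W2[k,m]·g[m]·x[j]
    d_w1 = np.einsum("km,bm,bj->bkmj", net.W2, g, X).reshape(B, o, h * i)
    # ∂ŷ_k/∂b1_m = W2[k,m]·g[m]
    d_b1 = np.einsum("km,bm->bkm", net.W2, g)
    # ∂ŷ_k/∂W2_{k',j} = δ_{kk'}·h_j
    d_w2 = np.einsum("kl,bj->bklj", np.eye(o), hid).reshape(B, o, o * h)
    # ∂ŷ_k/∂b2_{k'} = δ_{kk'}
    d_b2 = np.broadcast_to(np.eye(o), (B, o, o))

    d_pred = np.concatenate([d_w1, d_b1, d_w2, d_b2], axis=2)
    # e = (target − pred)·w  ⇒  J = ∂e/∂x = −w·∂ŷ/∂x
    if weights is not None:
        d_pred = d_pred * weights[None, :, None]
    J = -d_pred.reshape(B * o, n_parameters(net))
    return J, pred


def network_jacobian(net: NetworkModel, X: np.ndarray, T: np.ndarray,
                     weights: Optional[np.ndarray] = None,
                     mu: float = 1.0) -> LMState:
    """Analytic Jacobian of the errors ``e = target − prediction`` w.r.t.
    all weights and biases, as an :class:`LMState`.

    Row ``i·n_out + k`` of ``J`` differentiates the error of sample ``i``,
    output ``k``.  Intended for small problems and verification; training
    uses the block-accumulated normal equations instead.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if X.shape[0] != T.shape[0] or T.shape[1] != net.n_out:
        raise ValueError("input/target shapes inconsistent with the network")
    J, pred = _jacobian_block(net, X, weights)
    err = T - pred
    if weights is not None:
        err = err * weights[None, :]
    return LMState(x=flatten_params(net), J=J, e=err.ravel(), mu=mu)


def accumulate_normal_equations(net: NetworkModel, X: np.ndarray,
                                T: np.ndarray,
                                weights: Optional[np.ndarray] = None,
                                block_size: int = 256,
                                ) -> Tuple[np.ndarray, np.ndarray, float]:
    """JᵀJ, Jᵀe and the error sum of squares, accumulated in sample blocks.

    Identical (to rounding) to forming the monolithic Jacobian, without ever
    holding more than ``block_size`` samples' rows in memory.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    p = n_parameters(net)
    jtj = np.zeros((p, p))
    jte = np.zeros(p)
    sse = 0.0
    for start in range(0, X.shape[0], block_size):
        sl = slice(start, start + block_size)
        Jb, pred = _jacobian_block(net, X[sl], weights)
        err = T[sl] - pred
        if weights is not None:
            err = err * weights[None, :]
        eb = err.ravel()
        jtj += Jb.T @ Jb
        jte += Jb.T @ eb
        sse += float(eb @ eb)
    return jtj, jte, sse


def _solve_step(x: np.ndarray, jtj: np.ndarray, jte: np.ndarray,
                mu: float) -> np.ndarray:
    """x − (JᵀJ + μI)⁻¹ Jᵀe via Cholesky; raises LinAlgError if singular."""
    A = jtj + mu * np.eye(jtj.shape[0])
    c, low = scipy.linalg.cho_factor(A, check_finite=False)
    return x - scipy.linalg.cho_solve((c, low), jte, check_finite=False)


def lm_step(state: LMState) -> np.ndarray:
    """One damped Gauss–Newton candidate: x − (JᵀJ + μI)⁻¹ Jᵀe.

    For μ → 0 this approaches the Gauss–Newton step; for μ → ∞ a vanishing
    step along the gradient-descent direction.  A singular system (possible
    at μ = 0⁺ with a rank-deficient Jacobian) raises ``LinAlgError`` — the
    caller should increase μ and retry.
    """
    jtj = state.J.T @ state.J
    jte = state.J.T @ state.e
    return _solve_step(state.x, jtj, jte, state.mu)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainOptions:
    """Levenberg–Marquardt training schedule.

    ``goal_mse`` is in original intensity units (a.u.²); the 20,000 default
    corresponds to a 1.5% error of the study's average fluorescence signal.
    """

    max_epochs: int = 1000
    goal_mse: float = 20000.0
    max_validation_failures: int = 10
    mu_init: float = 1e-3
    mu_decrease: float = 0.1
    mu_increase: float = 10.0
    mu_max: float = 1e10
    seed: int = 0

    def __post_init__(self):
        if min(self.max_epochs, self.goal_mse, self.max_validation_failures,
               self.mu_init, self.mu_decrease, self.mu_increase,
               self.mu_max) <= 0:
            raise ValueError("all training options must be positive")
        if not (self.mu_decrease < 1.0 < self.mu_increase):
            raise ValueError("need mu_decrease < 1 < mu_increase")


@dataclass
class TrainHistory:
    """Per-epoch record of the training run, MSEs in original units."""

    train_mse: List[float] = field(default_factory=list)
    val_mse: List[float] = field(default_factory=list)
    test_mse: List[float] = field(default_factory=list)
    mu: List[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.train_mse)


def _mse_original(net: NetworkModel, Xs: np.ndarray, Ys_scaled: np.ndarray,
                  half_range: np.ndarray) -> float:
    """MSE in original intensity units from scaled arrays."""
    err = (Ys_scaled - forward_pass(net, Xs)) * half_range[None, :]
    return float(np.mean(err ** 2))


def train_network(net: NetworkModel,
                  train: Tuple[np.ndarray, np.ndarray],
                  val: Tuple[np.ndarray, np.ndarray],
                  test: Optional[Tuple[np.ndarray, np.ndarray]],
                  opts: TrainOptions,
                  block_size: int = 512,
                  ) -> Tuple[NetworkModel, TrainHistory]:
    """Train by Levenberg–Marquardt with validation-based early stopping.

    ``train``/``val``/``test`` are ``(X, Y)`` pairs in *original* units;
    input and output scalings are fitted here on the training pair only and
    stored on the model.  ``test`` may be ``None``; it is only ever used for
    the per-epoch reporting column.

    Returns the weights of the epoch with the lowest validation MSE,
    together with the full history.
    """
    X_tr, Y_tr = (np.atleast_2d(np.asarray(a, dtype=float)) for a in train)
    X_va, Y_va = (np.atleast_2d(np.asarray(a, dtype=float)) for a in val)
    if X_tr.shape[0] == 0 or X_va.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")

    net = net.copy()
    net.input_scaling = scale_fit(X_tr)
    net.output_scaling = scale_fit(Y_tr)
    half = net.output_scaling.half_range

    Xs_tr = scale_apply(X_tr, net.input_scaling)
    Ys_tr = scale_apply(Y_tr, net.output_scaling)
    Xs_va = scale_apply(X_va, net.input_scaling)
    Ys_va = scale_apply(Y_va, net.output_scaling)
    if test is not None:
        X_te, Y_te = (np.atleast_2d(np.asarray(a, dtype=float)) for a in test)
        Xs_te = scale_apply(X_te, net.input_scaling)
        Ys_te = scale_apply(Y_te, net.output_scaling)

    n_el = Y_tr.size  # samples × outputs

    def train_sse(model: NetworkModel) -> float:
        err = (Ys_tr - forward_pass(model, Xs_tr)) * half[None, :]
        return float(np.sum(err ** 2))

    history = TrainHistory()
    mu = opts.mu_init
    x = flatten_params(net)
    current = net
    sse = train_sse(current)
    best_val = np.inf
    best_net = current.copy()
    val_failures = 0

    for _epoch in range(opts.max_epochs):
        jtj, jte, sse = accumulate_normal_equations(
            current, Xs_tr, Ys_tr, weights=half, block_size=block_size)
        if not np.isfinite(sse):
            raise RuntimeError("non-finite training loss; aborting")

        # retry the tentative step with growing μ until it improves the SSE
        accepted = False
        while mu <= opts.mu_max:
            try:
                x_cand = _solve_step(x, jtj, jte, mu)
            except scipy.linalg.LinAlgError:
                mu *= opts.mu_increase
                continue
            cand = set_params(current, x_cand)
            sse_cand = train_sse(cand)
            if np.isfinite(sse_cand) and sse_cand < sse:
                x, current, sse = x_cand, cand, sse_cand
                mu = max(mu * opts.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= opts.mu_increase
        if not accepted:
            history.stop_reason = "mu_max"
            break

        train_mse = sse / n_el
        val_mse = _mse_original(current, Xs_va, Ys_va, half)
        test_mse = (_mse_original(current, Xs_te, Ys_te, half)
                    if test is not None else np.nan)
        history.train_mse.append(train_mse)
        history.val_mse.append(val_mse)
        history.test_mse.append(test_mse)
        history.mu.append(mu)

        if val_mse < best_val:
            best_val = val_mse
            best_net = current.copy()
            history.best_epoch = history.n_epochs - 1
            val_failures = 0
        else:
            val_failures += 1

        if train_mse <= opts.goal_mse:
            history.stop_reason = "goal"
            break
        if val_failures >= opts.max_validation_failures:
            history.stop_reason = "validation"
            break
    else:
        history.stop_reason = "max_epochs"

    return best_net, history


def predict(net: NetworkModel, X: np.ndarray) -> np.ndarray:
    """Descaled predictions in original intensity units."""
    Xs = scale_apply(X, net.input_scaling)
    return scale_invert(forward_pass(net, Xs), net.output_scaling)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def model_to_json(net: NetworkModel,
                  history: Optional[TrainHistory] = None,
                  options: Optional[TrainOptions] = None) -> str:
    """Serialize weights, scalings and (optionally) the training run."""
    doc = {
        "W1": net.W1.tolist(), "b1": net.b1.tolist(),
        "W2": net.W2.tolist(), "b2": net.b2.tolist(),
        "input_scaling": None if net.input_scaling is None else {
            "mins": net.input_scaling.mins.tolist(),
            "maxs": net.input_scaling.maxs.tolist()},
        "output_scaling": None if net.output_scaling is None else {
            "mins": net.output_scaling.mins.tolist(),
            "maxs": net.output_scaling.maxs.tolist()},
    }
    if options is not None:
        doc["options"] = vars(options).copy()
    if history is not None:
        doc["history"] = {
            "train_mse": history.train_mse, "val_mse": history.val_mse,
            "test_mse": history.test_mse, "mu": history.mu,
            "best_epoch": history.best_epoch,
            "stop_reason": history.stop_reason,
        }
    return json.dumps(doc)


def model_from_json(text: str) -> NetworkModel:
    doc = json.loads(text)
    net = NetworkModel(
        W1=np.array(doc["W1"]), b1=np.array(doc["b1"]),
        W2=np.array(doc["W2"]), b2=np.array(doc["b2"]),
    )
    for attr in ("input_scaling", "output_scaling"):
        blob = doc.get(attr)
        if blob is not None:
            setattr(net, attr, MinMaxScaling(np.array(blob["mins"]),
                                             np.array(blob["maxs"])))
    return net
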