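"""Back-propagation neural network trained by Levenberg-Marquardt.

A single-hidden-layer feed-forward network (tanh hidden units, linear
output) for the nonlinear fingerprint-efficacy relationship.  Training
follows the damped Gauss-Newton update

    x_{k+1} = x_k - (J'J + mu*I)^{-1} J' e

where J is the Jacobian of the residual vector e with respect to the flat
weight vector and mu the damping factor (decreased tenfold on an accepted
step, increased tenfold on a rejected one — the classical schedule).  Inputs
and outputs are standardized internally against the training split and
back-transformed for reporting.

Per-input contribution ratios use Garson's weight-partition algorithm by
default; the signed connection-weight (Olden) products are available behind
a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Network:
    """Weights of a (n_in -> n_hidden -> n_out) network as one flat vector.

    Flat order: W1 (n_hidden x n_in, row-major), b1 (n_hidden), W2
    (n_out x n_hidden, row-major), b2 (n_out).  ``x_mean/x_scale`` and
    ``y_mean/y_scale`` hold the internal standardization (identity until
    trained).
    """

    weights: np.ndarray
    n_in: int
    n_hidden: int
    n_out: int
    hidden_activation: str = "tanh"
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: np.ndarray | None = None
    y_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = (self.n_in + 1) * self.n_hidden + (self.n_hidden + 1) * self.n_out
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (expected,):
            raise ValueError(
                f"weight vector must have length {expected}, got {self.weights.shape}"
            )
        if self.x_mean is None:
            self.x_mean = np.zeros(self.n_in)
            self.x_scale = np.ones(self.n_in)
            self.y_mean = np.zeros(self.n_out)
            self.y_scale = np.ones(self.n_out)

    @property
    def n_weights(self) -> int:
        return self.weights.size

    def unpack(self):
        i = 0
        w1 = self.weights[i : i + self.n_hidden * self.n_in].reshape(
            self.n_hidden, self.n_in
        )
        i += w1.size
        b1 = self.weights[i : i + self.n_hidden]
        i += b1.size
        w2 = self.weights[i : i + self.n_out * self.n_hidden].reshape(
            self.n_out, self.n_hidden
        )
        i += w2.size
        b2 = self.weights[i:]
        return w1, b1, w2, b2

    def _activate(self, z: np.ndarray) -> np.ndarray:
        if self.hidden_activation == "tanh":
            return np.tanh(z)
        if self.hidden_activation == "identity":
            return z
        raise ValueError(f"unknown activation {self.hidden_activation!r}")

    def _activate_deriv(self, h: np.ndarray) -> np.ndarray:
        if self.hidden_activation == "tanh":
            return 1.0 - h**2
        return np.ones_like(h)


def init_network(n_in: int, n_hidden: int, n_out: int = 1, seed: int = 0,
                 hidden_activation: str = "tanh") -> Network:
    """Create a network with small seeded random weights."""
    if min(n_in, n_hidden, n_out) < 1:
        raise ValueError("layer sizes must all be >= 1")
    rng = np.random.default_rng(seed)
    n_w = (n_in + 1) * n_hidden + (n_hidden + 1) * n_out
    weights = rng.normal(0.0, 0.5 / np.sqrt(n_in), size=n_w)
    return Network(weights, n_in, n_hidden, n_out, hidden_activation)


def default_hidden_size(n_in: int, n_out: int = 1) -> int:
    """Default hidden-layer width: ceil((n_in + n_out) / 2)."""
    return int(np.ceil((n_in + n_out) / 2))


def forward(net: Network, X: np.ndarray) -> np.ndarray:
    """Network output in original (back-transformed) units."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    w1, b1, w2, b2 = net.unpack()
    Z = (X - net.x_mean) / net.x_scale
    H = net._activate(Z @ w1.T + b1)
    out = H @ w2.T + b2
    return out * net.y_scale + net.y_mean


def _residuals(net: Network, Xs: np.ndarray, Ys: np.ndarray) -> np.ndarray:
    """Residual vector (prediction - target) in standardized space, flattened."""
    w1, b1, w2, b2 = net.unpack()
    H = net._activate(Xs @ w1.T + b1)
    return (H @ w2.T + b2 - Ys).ravel()


def jacobian(net: Network, Xs: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the standardized residuals w.r.t. the flat weights.

    Rows run over (sample, output) pairs in the same order as the flattened
    residual vector; columns follow the network's flat weight order.
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    w1, b1, w2, b2 = net.unpack()
    n = Xs.shape[0]
    H = net._activate(Xs @ w1.T + b1)  # n x h
    dH = net._activate_deriv(H)  # n x h
    J = np.zeros((n * net.n_out, net.n_weights))
    i_w1 = 0
    i_b1 = net.n_hidden * net.n_in
    i_w2 = i_b1 + net.n_hidden
    i_b2 = i_w2 + net.n_out * net.n_hidden
    for o in range(net.n_out):
        rows = slice(o, n * net.n_out, net.n_out)  # row o of each sample block
        back = dH * w2[o]  # n x h, dout_o/dz_h
        # dW1[h, i] = back[:, h] * x[:, i]
        J[rows, i_w1 : i_w1 + net.n_hidden * net.n_in] = (
            back[:, :, None] * Xs[:, None, :]
        ).reshape(n, -1)
        J[rows, i_b1 : i_b1 + net.n_hidden] = back
        J[rows, i_w2 + o * net.n_hidden : i_w2 + (o + 1) * net.n_hidden] = H
        J[rows, i_b2 + o] = 1.0
    return J


def lm_update(J: np.ndarray, e: np.ndarray, mu: float) -> np.ndarray:
    """Solve the damped normal equations for the LM weight decrement.

    Returns delta with ``x_new = x - delta`` where
    ``delta = (J'J + mu*I)^{-1} J'e``.  As mu -> 0 this is the Gauss-Newton
    step (one-step exact for residuals linear in the parameters); as
    mu -> inf the direction approaches the scaled gradient J'e/mu.
    """
    if mu <= 0:
        raise ValueError("damping factor mu must be positive")
    A = J.T @ J + mu * np.eye(J.shape[1])
    try:
        return np.linalg.solve(A, J.T @ e)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"damped normal matrix singular at mu={mu:g}; escalate mu and retry"
        ) from err


def lm_step(net: Network, X: np.ndarray, Y: np.ndarray, mu: float
            ) -> tuple[Network, float]:
    """One LM weight update on (X, Y); returns the new network and residual norm."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.reshape(X.shape[0], -1)
    Xs = (X - net.x_mean) / net.x_scale
    Ys = (Y - net.y_mean) / net.y_scale
    e = _residuals(net, Xs, Ys)
    if np.allclose(e, 0.0):
        return net, 0.0
    J = jacobian(net, Xs)
    delta = lm_update(J, e, mu)
    new = replace(net, weights=net.weights - delta)
    new_e = _residuals(new, Xs, Ys)
    return new, float(np.linalg.norm(new_e))


@dataclass
class TrainResult:
    """Outcome of LM training: network, MSE triple, and the accepted-step trace."""

    network: Network
    mse_train: float
    mse_val: float
    mse_test: float
    train_mse_history: list = field(default_factory=list)
    n_iterations: int = 0

    @property
    def mse(self) -> tuple[float, float, float]:
        return (self.mse_train, self.mse_val, self.mse_test)


def train(net: Network, X: np.ndarray, Y: np.ndarray,
          split: tuple[float, float, float] = (0.70, 0.15, 0.15),
          max_iter: int = 200, patience: int = 20, seed: int = 0,
          mu0: float = 1e-3, mu_max: float = 1e10,
          tol: float = 1e-12) -> TrainResult:
    """Train by Levenberg-Marquardt with early stopping on validation MSE.

    Samples are partitioned into train/validation/test splits by a seeded
    random permutation.  Each iteration escalates mu until a step lowers the
    training MSE (accept: mu /= 10) or mu exceeds ``mu_max`` (stop); the
    accepted-step training-MSE sequence is therefore non-increasing.
    Training stops early when the validation MSE has not improved for
    ``patience`` accepted steps; the weights with the best validation MSE
    are restored.  Reported MSEs are in original response units.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).reshape(X.shape[0], -1)
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = X.shape[0]
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split {split} leaves an empty subset for n={n} samples"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]

    x_mean = X[idx_train].mean(axis=0)
    x_scale = X[idx_train].std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean = Y[idx_train].mean(axis=0)
    y_scale = Y[idx_train].std(axis=0)
    y_scale[y_scale == 0] = 1.0
    net = replace(net, x_mean=x_mean, x_scale=x_scale,
                  y_mean=y_mean, y_scale=y_scale)

    Xs = {k: (X[i] - x_mean) / x_scale
          for k, i in (("train", idx_train), ("val", idx_val), ("test", idx_test))}
    Ys = {k: (Y[i] - y_mean) / y_scale
          for k, i in (("train", idx_train), ("val", idx_val), ("test", idx_test))}

    def mse_std(w, key):
        probe = replace(net, weights=w)
        e = _residuals(probe, Xs[key], Ys[key])
        return float(np.mean(e**2))

    w = net.weights.copy()
    mu = mu0
    history = [mse_std(w, "train")]
    best_val = mse_std(w, "val")
    best_w = w.copy()
    stall = 0
    iterations = 0
    for _ in range(max_iter):
        e = _residuals(replace(net, weights=w), Xs["train"], Ys["train"])
        if np.mean(e**2) <= tol:
            break
        J = jacobian(replace(net, weights=w), Xs["train"])
        g = J.T @ e
        accepted = False
        while mu <= mu_max:
            try:
                delta = np.linalg.solve(J.T @ J + mu * np.eye(w.size), g)
            except np.linalg.LinAlgError:
                mu *= 10
                continue
            cand = w - delta
            if mse_std(cand, "train") <= history[-1]:
                accepted = True
                break
            mu *= 10
        if not accepted:
            break
        w = cand
        mu = max(mu / 10, 1e-15)
        iterations += 1
        history.append(mse_std(w, "train"))
        val = mse_std(w, "val")
        if val < best_val - 1e-15:
            best_val = val
            best_w = w.copy()
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
        if len(history) > 1 and history[-2] - history[-1] <= tol * max(history[-2], 1.0):
            break

    net = replace(net, weights=best_w)
    # report MSE in original response units
    scale2 = float(np.mean(net.y_scale**2))
    return TrainResult(
        network=net,
        mse_train=mse_std(best_w, "train") * scale2,
        mse_val=mse_std(best_w, "val") * scale2,
        mse_test=mse_std(best_w, "test") * scale2,
        train_mse_history=history,
        n_iterations=iterations,
    )


@dataclass(frozen=True)
class ContributionReport:
    """Per-input contribution ratios in percent (non-negative, summing to 100)."""

    ratios: np.ndarray
    method: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))


def save_network(net: Network, path) -> None:
    """Write a network as JSON.

    The ``weights`` list follows the documented flat order: W1 row-major,
    b1, W2 row-major, b2; the standardization parameters are stored so a
    reloaded network predicts identically.
    """
    import json

    payload = {
        "architecture": [net.n_in, net.n_hidden, net.n_out],
        "hidden_activation": net.hidden_activation,
        "weights": net.weights.tolist(),
        "x_mean": net.x_mean.tolist(),
        "x_scale": net.x_scale.tolist(),
        "y_mean": net.y_mean.tolist(),
        "y_scale": net.y_scale.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_network(path) -> Network:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    n_in, n_hidden, n_out = payload["architecture"]
    return Network(
        weights=np.asarray(payload["weights"], dtype=float),
        n_in=n_in,
        n_hidden=n_hidden,
        n_out=n_out,
        hidden_activation=payload["hidden_activation"],
        x_mean=np.asarray(payload["x_mean"], dtype=float),
        x_scale=np.asarray(payload["x_scale"], dtype=float),
        y_mean=np.asarray(payload["y_mean"], dtype=float),
        y_scale=np.asarray(payload["y_scale"], dtype=float),
    )


def contribution_ratios(net: Network, method: str = "garson") -> ContributionReport:
    """Per-input contribution to the network output.

    ``garson`` (default) partitions the absolute input-hidden weights within
    each hidden unit, weights the shares by the absolute hidden-output
    weights, and normalizes to 100%.  ``olden`` returns the signed
    connection-weight products rescaled so absolute values sum to 100%.
    """
    w1, _, w2, _ = net.unpack()
    if not np.any(w1) or not np.any(w2):
        raise ValueError("contribution undefined for an all-zero weight layer")
    if method == "garson":
        abs_w1 = np.abs(w1)  # h x i
        row_sums = abs_w1.sum(axis=1, keepdims=True)
        row_sums[row_sums == 0] = 1.0
        share = abs_w1 / row_sums  # per-hidden-unit input shares
        importance = np.abs(w2) @ share  # o x i
        total = importance.sum(axis=1, keepdims=True)
        if np.any(total == 0):
            raise ValueError("contribution undefined: zero total importance")
        ratios = (importance / total).mean(axis=0) * 100.0
    elif method == "olden":
        signed = w2 @ w1  # o x i
        ratios = signed.mean(axis=0)
        ratios = ratios / np.sum(np.abs(ratios)) * 100.0
    else:
        raise ValueError(f"unknown contribution method {method!r}")
    return ContributionReport(ratios=ratios, method=method)
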