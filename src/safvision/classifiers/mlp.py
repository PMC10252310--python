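"""Multilayer perceptron with sigmoid hidden units and the named trainers.

The network has sigmoid hidden layers, f(θ) = 1/(1+e^(−θ)), and a linear
output layer fitted to one-hot class targets by least squares.  Training
algorithm T1 is a full Levenberg-Marquardt loop on the residual Jacobian;
T2 is Levenberg-Marquardt under MacKay's Bayesian-regularization updates of
the weight-decay/noise hyperparameters; T3-T13 share the first-order
optimizer interface in :mod:`._opt`.

Output-layer weights start at zero so the training trajectory is exactly
equivariant under a permutation of the one-hot target columns.
"""

from __future__ import annotations

import numpy as np

from ._opt import TRAINING_ALGORITHMS, minimize_network
from .base import SpiceClassifier


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Net:
    """Weight bookkeeping for a layered sigmoid network with linear output."""

    def __init__(self, sizes: list[int]):
        self.sizes = sizes
        self.shapes = [(sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.n_params = sum(a * b + b for a, b in self.shapes)

    def init(self, rng: np.random.Generator) -> np.ndarray:
        chunks = []
        last = len(self.shapes) - 1
        for i, (a, b) in enumerate(self.shapes):
            if i == last:           # zero output layer: permutation equivariance
                chunks.append(np.zeros(a * b + b))
            else:
                chunks.append(np.concatenate([
                    rng.normal(0.0, 1.0 / np.sqrt(a), a * b), np.zeros(b)]))
        return np.concatenate(chunks)

    def unpack(self, w: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        layers = []
        pos = 0
        for a, b in self.shapes:
            W = w[pos:pos + a * b].reshape(a, b)
            pos += a * b
            bias = w[pos:pos + b]
            pos += b
            layers.append((W, bias))
        return layers

    def forward(self, w: np.ndarray, X: np.ndarray) -> list[np.ndarray]:
        layers = self.unpack(w)
        acts = [X]
        for i, (W, b) in enumerate(layers):
            z = acts[-1] @ W + b
            acts.append(z if i == len(layers) - 1 else _sigmoid(z))
        return acts

    def loss_grad(self, w: np.ndarray, X: np.ndarray,
                  T: np.ndarray) -> tuple[float, np.ndarray]:
        """0.5*SSE loss and its gradient via backpropagation."""
        layers = self.unpack(w)
        acts = self.forward(w, X)
        r = acts[-1] - T
        loss = 0.5 * float(np.sum(r * r))
        grads = []
        d = r
        for i in reversed(range(len(layers))):
            W, _ = layers[i]
            gW = acts[i].T @ d
            gb = d.sum(axis=0)
            grads.append(np.concatenate([gW.ravel(), gb]))
            if i > 0:
                d = (d @ W.T) * acts[i] * (1.0 - acts[i])
        return loss, np.concatenate(grads[::-1])

    def jacobian(self, w: np.ndarray, X: np.ndarray,
                 n_out: int) -> tuple[np.ndarray, np.ndarray]:
        """Residual-output Jacobian d out_k(x_n)/dw, flattened to
        (n_samples*n_out, n_params), plus the network outputs."""
        layers = self.unpack(w)
        acts = self.forward(w, X)
        n = X.shape[0]
        J = np.zeros((n, n_out, self.n_params))
        for k in range(n_out):
            d = np.zeros((n, n_out))
            d[:, k] = 1.0
            blocks = []
            for i in reversed(range(len(layers))):
                W, _ = layers[i]
                gW = acts[i][:, :, None] * d[:, None, :]    # (n, in, out)
                blocks.append(np.concatenate(
                    [gW.reshape(n, -1), d], axis=1))
                if i > 0:
                    d = (d @ W.T) * acts[i] * (1.0 - acts[i])
            J[:, k, :] = np.concatenate(blocks[::-1], axis=1)
        return J.reshape(n * n_out, self.n_params), acts[-1]


def _levenberg_marquardt(net: _Net, w: np.ndarray, X: np.ndarray,
                         T: np.ndarray, max_iter: int,
                         bayesian: bool) -> np.ndarray:
    n_out = T.shape[1]
    n_obs = T.size
    n_par = net.n_params
    lam = 1e-2
    alpha, beta = (1e-2, 1.0) if bayesian else (0.0, 1.0)

    def objective(wv: np.ndarray) -> float:
        r = net.forward(wv, X)[-1] - T
        return beta * 0.5 * float(np.sum(r * r)) + alpha * 0.5 * float(wv @ wv)

    current = objective(w)
    eye = np.eye(n_par)
    for _ in range(max_iter):
        J, out = net.jacobian(w, X, n_out)
        r = (out - T).ravel()
        g = beta * (J.T @ r) + alpha * w
        if np.linalg.norm(g, ord=np.inf) < 1e-9:
            break
        A = beta * (J.T @ J) + alpha * eye
        accepted = False
        for _try in range(12):
            try:
                delta = np.linalg.solve(A + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            w_new = w + delta
            new = objective(w_new)
            if new < current:
                w, current = w_new, new
                lam = max(lam * 0.1, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            break
        if bayesian:
            r = net.forward(w, X)[-1] - T
            ed = 0.5 * float(np.sum(r * r))
            ew = 0.5 * float(w @ w)
            try:
                h_inv_tr = float(np.trace(np.linalg.inv(A + lam * eye)))
            except np.linalg.LinAlgError:
                h_inv_tr = 0.0
            gamma = n_par - alpha * h_inv_tr
            gamma = min(max(gamma, 1e-6), n_par)
            alpha = gamma / (2.0 * ew + 1e-12)
            beta = max(n_obs - gamma, 1e-6) / (2.0 * ed + 1e-12)
            current = objective(w)
    return w


class MLPNetworkClassifier(SpiceClassifier):
    """Feed-forward sigmoid network trained by a named Table-style algorithm.

    Parameters
    ----------
    hidden_layout : tuple of int
        Hidden layer widths.
    training_algorithm : str
        One of the symbols T1..T13 (T1 Levenberg-Marquardt by default).
    max_iter : int
        Training iterations of the chosen optimizer.
    """

    def __init__(self, hidden_layout: tuple[int, ...] = (12,),
                 training_algorithm: str = "T1", max_iter: int = 60,
                 standardize: bool = True, random_state: int | None = None):
        super().__init__(standardize=standardize, random_state=random_state)
        self.hidden_layout = hidden_layout
        self.training_algorithm = training_algorithm
        self.max_iter = max_iter

    def _fit(self, X: np.ndarray, y_idx: np.ndarray) -> None:
        if self.training_algorithm not in TRAINING_ALGORITHMS:
            raise ValueError(
                f"unknown training algorithm {self.training_algorithm!r}")
        n_classes = self.classes_.size
        sizes = [X.shape[1], *self.hidden_layout, n_classes]
        net = _Net(sizes)
        T = np.eye(n_classes)[y_idx]
        w0 = net.init(self._rng_)
        if self.training_algorithm in ("T1", "T2"):
            w = _levenberg_marquardt(net, w0, X, T, self.max_iter,
                                     bayesian=self.training_algorithm == "T2")
        else:
            # mean-squared scale keeps first-order step sizes sample-count
            # independent (the scaling is irrelevant to the quasi-Newton/CG
            # methods and to the minimiser location)
            n = X.shape[0]

            def fun(wv: np.ndarray):
                loss, grad = net.loss_grad(wv, X, T)
                return loss / n, grad / n

            w = minimize_network(fun, w0, self.training_algorithm,
                                 self.max_iter)
        self.net_ = net
        self.weights_ = w

    def decision_function(self, X):
        from sklearn.utils.validation import check_array, check_is_fitted
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=np.float64)
        return self.net_.forward(self.weights_, self._transform(X))[-1]

    def _predict_indices(self, X: np.ndarray) -> np.ndarray:
        out = self.net_.forward(self.weights_, X)[-1]
        return np.argmax(out, axis=1)
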