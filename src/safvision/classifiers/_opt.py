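"""One interface over the named network training algorithms T1-T13.

T1 (Levenberg-Marquardt) and T2 (Bayesian regularization) are second-order
least-squares methods implemented in :mod:`.mlp` because they need the
residual Jacobian.  The remaining algorithms minimise a scalar loss from its
gradient and are dispatched here: Rprop and the gradient-descent family are
implemented directly; the conjugate-gradient and quasi-Newton variants map
onto the corresponding scipy optimisers.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import optimize

#: symbol -> human-readable name of the training algorithm
TRAINING_ALGORITHMS = {
    "T1": "Levenberg-Marquardt backpropagation",
    "T2": "Bayesian regularization",
    "T3": "Scaled conjugate gradient backpropagation",
    "T4": "Resilient backpropagation (Rprop)",
    "T5": "Variable learning rate backpropagation",
    "T6": "Gradient descent with momentum backpropagation",
    "T7": "Gradient descent with adaptive learning rate backpropagation",
    "T8": "Gradient descent backpropagation",
    "T9": "BFGS quasi-Newton backpropagation",
    "T10": "Powell-Beale conjugate gradient backpropagation",
    "T11": "Fletcher-Powell conjugate gradient backpropagation",
    "T12": "Polak-Ribiere conjugate gradient backpropagation",
    "T13": "One step secant backpropagation",
}

_SCIPY_METHOD = {"T3": "CG", "T9": "BFGS", "T10": "CG", "T11": "CG",
                 "T12": "CG", "T13": "L-BFGS-B"}

LossGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


def _rprop(fun: LossGrad, w: np.ndarray, max_iter: int) -> np.ndarray:
    step = np.full_like(w, 0.01)
    _, g_prev = fun(w)
    w = w - np.sign(g_prev) * step
    for _ in range(max_iter - 1):
        _, g = fun(w)
        sign = g * g_prev
        step = np.where(sign > 0, np.minimum(step * 1.2, 5.0),
                        np.where(sign < 0, np.maximum(step * 0.5, 1e-8), step))
        g = np.where(sign < 0, 0.0, g)
        w = w - np.sign(g) * step
        g_prev = g
        if np.abs(g).max() < 1e-8:
            break
    return w


def _gradient_descent(fun: LossGrad, w: np.ndarray, max_iter: int,
                      lr: float, momentum: float, adaptive: bool) -> np.ndarray:
    velocity = np.zeros_like(w)
    loss_prev, g = fun(w)
    for _ in range(max_iter):
        velocity = momentum * velocity - lr * g
        w_new = w + velocity
        loss_new, g_new = fun(w_new)
        if adaptive:
            if loss_new > loss_prev * 1.04:   # reject step, shrink rate
                lr *= 0.7
                velocity = np.zeros_like(w)
                continue
            lr *= 1.05
        w, loss_prev, g = w_new, loss_new, g_new
        if np.linalg.norm(g) < 1e-8:
            break
    return w


def minimize_network(fun: LossGrad, w0: np.ndarray, algorithm: str,
                     max_iter: int = 200) -> np.ndarray:
    """Minimise a network loss with the named first-order algorithm (T3-T13)."""
    if algorithm not in TRAINING_ALGORITHMS:
        raise ValueError(f"unknown training algorithm {algorithm!r}; "
                         f"expected one of {sorted(TRAINING_ALGORITHMS)}")
    if algorithm in ("T1", "T2"):
        raise ValueError("T1/T2 are second-order least-squares algorithms; "
                         "use the Levenberg-Marquardt path")
    if algorithm == "T4":
        return _rprop(fun, w0.copy(), max_iter)
    if algorithm == "T5":
        return _gradient_descent(fun, w0.copy(), max_iter, lr=0.05,
                                 momentum=0.9, adaptive=True)
    if algorithm == "T6":
        return _gradient_descent(fun, w0.copy(), max_iter, lr=0.05,
                                 momentum=0.9, adaptive=False)
    if algorithm == "T7":
        return _gradient_descent(fun, w0.copy(), max_iter, lr=0.05,
                                 momentum=0.0, adaptive=True)
    if algorithm == "T8":
        return _gradient_descent(fun, w0.copy(), max_iter, lr=0.05,
                                 momentum=0.0, adaptive=False)
    method = _SCIPY_METHOD[algorithm]
    options: dict = {"maxiter": max_iter}
    if method == "L-BFGS-B":
        options["maxcor"] = 1   # one-step secant flavour: memory-1 update
    res = optimize.minimize(fun, w0, jac=True, method=method, options=options)
    return res.x
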