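"""Bayesian-evidence neural network classifier.

A feedforward 3-h-1 network (tanh hidden layer, sigmoid output) is trained
under weight decay,

    M(w) = G(w) + alpha * E_W,   G = cross-entropy,   E_W = 0.5 * sum w^2,

which is the MAP objective under a zero-mean Gaussian weight prior with
precision alpha.  The evidence framework treats alpha and the hidden-layer
width h as hyperparameters to be compared by their Laplace-approximation
log model evidence,

    ln Ev = -G(w_MP) - alpha E_W(w_MP) - 1/2 ln det A + (W/2) ln alpha,

with A = H_G + alpha I the regularised Hessian at the weight posterior mode
(H_G in the positive-semidefinite Gauss-Newton outer-product form).  An
optional hidden-unit permutation/sign symmetry factor ln h! + h ln 2 can be
added; it is off by default because the multiplicity it counts collapses
whenever spare hidden units sit at the prior mode (the h! 2^h "copies" are
then not distinct Laplace modes), which would make the evidence grow
strictly with width instead of showing the interior maximum that motivates
evidence-based width selection.  The effective number of
well-determined parameters gamma = sum_i lambda_i / (lambda_i + alpha)
re-estimates alpha <- gamma / (2 E_W) between optimisation passes.

The positive class is UNHEALED throughout: the output is the predicted
probability that a wound will not have healed by week 12.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "BNNModel",
    "EvidenceResult",
    "init_network",
    "forward",
    "cost",
    "cost_gradient",
    "train",
    "log_evidence",
    "select_architecture",
    "predict",
]

N_INPUT = 3  # principal-component scores feeding the classifier

_CLIP = 1e-12


@dataclass
class BNNModel:
    """Weights of a 3-h-1 network plus its weight-decay precision alpha."""

    w1: np.ndarray  # (h, 3) input->hidden weights
    b1: np.ndarray  # (h,) hidden biases
    w2: np.ndarray  # (h,) hidden->output weights
    b2: float  # output bias
    alpha: float = 0.1
    trained: bool = False

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        h = self.h
        if self.w1.shape != (h, N_INPUT) or self.w2.shape != (h,):
            raise ValueError("inconsistent weight shapes")

    @property
    def h(self) -> int:
        return self.b1.shape[0]

    @property
    def n_params(self) -> int:
        # 3h + h input side, h + 1 output side = 5h + 1
        return 5 * self.h + 1

    def pack(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2, [self.b2]])

    def with_params(self, w: np.ndarray) -> "BNNModel":
        h = self.h
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n_params,):
            raise ValueError("parameter vector has the wrong length")
        return BNNModel(
            w1=w[: 3 * h].reshape(h, N_INPUT),
            b1=w[3 * h : 4 * h],
            w2=w[4 * h : 5 * h],
            b2=float(w[5 * h]),
            alpha=self.alpha,
            trained=self.trained,
        )

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        doc = {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "h": self.h,
            "alpha": self.alpha,
            "trained": self.trained,
        }
        if extra:
            doc.update(extra)
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "BNNModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            w1=np.asarray(doc["w1"]),
            b1=np.asarray(doc["b1"]),
            w2=np.asarray(doc["w2"]),
            b2=float(doc["b2"]),
            alpha=float(doc["alpha"]),
            trained=bool(doc["trained"]),
        )


@dataclass
class EvidenceResult:
    h: int
    log_evidence: float
    gamma: float  # effective number of parameters, in [0, 5h+1]
    alpha_final: float
    G: float  # cross-entropy at the mode
    E_W: float  # 0.5 * sum w^2 at the mode
    n_restarts: int = 1


def init_network(h: int, seed: int, alpha: float = 0.1) -> BNNModel:
    """Random Gaussian initialisation, SD 1/sqrt(fan-in); deterministic per seed."""
    if h < 1:
        raise ValueError("h must be >= 1")
    rng = np.random.default_rng(seed)
    sd_in = 1.0 / math.sqrt(N_INPUT)
    sd_out = 1.0 / math.sqrt(h)
    return BNNModel(
        w1=rng.normal(0.0, sd_in, size=(h, N_INPUT)),
        b1=rng.normal(0.0, sd_in, size=h),
        w2=rng.normal(0.0, sd_out, size=h),
        b2=float(rng.normal(0.0, sd_out)),
        alpha=alpha,
    )


def _pre_activation(model: BNNModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activations and output pre-sigmoid for a batch."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != N_INPUT:
        raise ValueError(f"expected {N_INPUT}-dimensional inputs")
    hid = np.tanh(X @ model.w1.T + model.b1)
    a = hid @ model.w2 + model.b2
    return hid, a


def forward(model: BNNModel, x: np.ndarray) -> np.ndarray | float:
    """Predicted probability of the positive (unhealed) class."""
    single = np.asarray(x).ndim == 1
    _, a = _pre_activation(model, x)
    y = expit(a)
    return float(y[0]) if single else y


def cost(
    model: BNNModel, X: np.ndarray, t: np.ndarray, alpha: float | None = None
) -> tuple[float, float, float]:
    """(M, G, E_W): regularised objective, cross-entropy, weight energy."""
    alpha = model.alpha if alpha is None else alpha
    t = np.asarray(t, dtype=float)
    y = np.clip(np.atleast_1d(forward(model, X)), _CLIP, 1.0 - _CLIP)
    G = float(-(t * np.log(y) + (1.0 - t) * np.log(1.0 - y)).sum())
    w = model.pack()
    E_W = float(0.5 * (w @ w))
    return G + alpha * E_W, G, E_W


def _output_jacobian(model: BNNModel, X: np.ndarray) -> np.ndarray:
    """d a_n / d w for every sample: (n, n_params), packing order of pack()."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    hid, _ = _pre_activation(model, X)
    dtanh = 1.0 - hid**2  # (n, h)
    back = dtanh * model.w2  # (n, h): da/d(pre-hidden)
    d_w1 = back[:, :, None] * X[:, None, :]  # (n, h, 3)
    d_b1 = back  # (n, h)
    d_w2 = hid  # (n, h)
    d_b2 = np.ones((X.shape[0], 1))
    return np.concatenate(
        [d_w1.reshape(X.shape[0], -1), d_b1, d_w2, d_b2], axis=1
    )


def cost_gradient(
    model: BNNModel, X: np.ndarray, t: np.ndarray, alpha: float | None = None
) -> np.ndarray:
    """Analytic gradient of M = G + alpha * E_W with respect to pack()."""
    alpha = model.alpha if alpha is None else alpha
    t = np.asarray(t, dtype=float)
    y = np.atleast_1d(forward(model, X))
    J = _output_jacobian(model, X)
    grad_G = J.T @ (y - t)  # dG/da = y - t for sigmoid + cross-entropy
    return grad_G + alpha * model.pack()


def _gauss_newton_hessian(model: BNNModel, X: np.ndarray) -> np.ndarray:
    """PSD outer-product approximation of the data-term Hessian:
    H_G = sum_n y_n (1 - y_n) g_n g_n^T with g_n = da_n/dw."""
    y = np.atleast_1d(forward(model, X))
    J = _output_jacobian(model, X)
    r = y * (1.0 - y)
    return (J * r[:, None]).T @ J


def train(
    model: BNNModel,
    X: np.ndarray,
    t: np.ndarray,
    alpha0: float | None = None,
    max_outer: int = 20,
    reestimate_alpha: bool = True,
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> BNNModel:
    """MAP-train under weight decay, re-estimating alpha from the evidence.

    Alternates (a) minimising M(w) with L-BFGS using the analytic gradient
    and (b) the evidence update alpha <- gamma / (2 E_W); stops when alpha
    moves by < 1% or ``max_outer`` is reached.  Deterministic for fixed
    (model, data, alpha0).
    """
    alpha = model.alpha if alpha0 is None else float(alpha0)
    if alpha <= 0:
        raise ValueError("alpha0 must be > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float)
    cur = model

    for _ in range(max_outer):
        def fun(w: np.ndarray) -> tuple[float, np.ndarray]:
            m = cur.with_params(w)
            M, _, _ = cost(m, X, t, alpha)
            return M, cost_gradient(m, X, t, alpha)

        res = minimize(
            fun,
            cur.pack(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
        )
        if not np.all(np.isfinite(res.x)):
            raise FloatingPointError("non-finite weights during optimisation")
        cur = cur.with_params(res.x)
        cur.alpha = alpha
        if not reestimate_alpha:
            break
        H = _gauss_newton_hessian(cur, X)
        lam = np.clip(np.linalg.eigvalsh(H), 0.0, None)
        gamma = float((lam / (lam + alpha)).sum())
        _, _, E_W = cost(cur, X, t, alpha)
        if E_W < 1e-12:
            break
        new_alpha = gamma / (2.0 * E_W)
        if new_alpha <= 0 or not np.isfinite(new_alpha):
            break
        if abs(new_alpha - alpha) < 0.01 * alpha:
            alpha = new_alpha
            cur.alpha = alpha
            break
        alpha = new_alpha
        cur.alpha = alpha
    cur.trained = True
    return cur


def log_evidence(
    model: BNNModel,
    X: np.ndarray,
    t: np.ndarray,
    alpha: float | None = None,
    include_symmetry: bool = False,
) -> EvidenceResult:
    """Laplace-approximation log evidence of a trained model.

    Uses the Gauss-Newton data Hessian; eigenvalues of A = H_G + alpha I are
    floored at 1e-10 before the log-determinant.  ``include_symmetry`` adds
    the ln h! + h ln 2 mode-multiplicity factor; see the module docstring
    for why it is off by default.
    """
    alpha = model.alpha if alpha is None else float(alpha)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float)
    _, G, E_W = cost(model, X, t, alpha)
    H = _gauss_newton_hessian(model, X)
    lam = np.clip(np.linalg.eigvalsh(H), 0.0, None)
    a_eig = np.maximum(lam + alpha, 1e-10)
    if np.any(a_eig <= 0):
        raise FloatingPointError("regularised Hessian not positive definite")
    gamma = float((lam / (lam + alpha)).sum())
    W = model.n_params
    h = model.h
    ln_ev = (
        -G
        - alpha * E_W
        - 0.5 * float(np.log(a_eig).sum())
        + 0.5 * W * math.log(alpha)
    )
    if include_symmetry:
        ln_ev += math.lgamma(h + 1) + h * math.log(2.0)
    if not np.isfinite(ln_ev):
        raise FloatingPointError("log evidence is not finite")
    return EvidenceResult(
        h=h, log_evidence=float(ln_ev), gamma=gamma, alpha_final=alpha,
        G=G, E_W=E_W,
    )


def select_architecture(
    X: np.ndarray,
    t: np.ndarray,
    h_range: Sequence[int] = range(1, 10),
    restarts: int = 5,
    seed: int = 0,
    alpha0: float = 0.1,
    max_outer: int = 20,
) -> tuple[int, BNNModel, list[EvidenceResult]]:
    """Train each width with random restarts and pick the evidence argmax.

    For each h, ``restarts`` models are trained from distinct derived seeds
    and the one with the highest log evidence is kept; the global winner is
    the h with maximal evidence, ties resolved toward the smaller h.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("training labels must contain both classes")
    seed_rng = np.random.default_rng(seed)
    results: list[EvidenceResult] = []
    best_models: dict[int, BNNModel] = {}
    for h in h_range:
        best: EvidenceResult | None = None
        n_ok = 0
        for _ in range(restarts):
            s = int(seed_rng.integers(0, 2**31 - 1))
            try:
                m = train(init_network(h, s, alpha0), X, t, alpha0, max_outer)
                ev = log_evidence(m, X, t)
            except FloatingPointError:
                continue
            n_ok += 1
            if best is None or ev.log_evidence > best.log_evidence:
                best = ev
                best_models[h] = m
        if best is None:
            warnings.warn(f"all restarts failed for h={h}; skipping", stacklevel=2)
            continue
        best.n_restarts = n_ok
        results.append(best)
    if not results:
        raise RuntimeError("architecture selection failed for every width")
    best_res = max(results, key=lambda r: (r.log_evidence, -r.h))
    return best_res.h, best_models[best_res.h], results


def predict(
    model: BNNModel, scores: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, probabilities); label 'unhealed' iff p >= threshold."""
    if not model.trained:
        raise ValueError("model is not trained")
    y = np.atleast_1d(forward(model, scores))
    labels = np.where(y >= threshold, "unhealed", "healed")
    return labels, y
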