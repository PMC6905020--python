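"""Soft-margin SVM trained by sequential minimal optimization (SMO) with the
Pearson VII universal kernel (PUK).

The kernel is

    K(x, y) = 1 / [1 + (2 ||x - y|| sqrt(2^(1/omega) - 1) / sigma)^2]^omega

which interpolates between Gaussian-like (large omega) and Lorentzian-like
(omega = 1) shapes; K(x, x) = 1 and K decreases strictly with distance.

The dual problem

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K_ij
    s.t.   0 <= a_i <= C,  sum_i a_i y_i = 0

is solved by Platt-style SMO: at each step two multipliers are optimized
analytically while all others are held fixed, with the usual first/second
choice heuristics and an error cache.  Convergence is declared when no
example violates the KKT conditions beyond the tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConvergenceError, ParameterError


@dataclass(frozen=True)
class PukParams:
    """Pearson VII kernel shape (omega, sigma), box constraint C, KKT tolerance."""

    omega: float = 1.0
    sigma: float = 1.0
    C: float = 1.0
    tolerance: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("omega", "sigma", "C", "tolerance"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"PukParams.{name} must be strictly positive")


def puk_kernel(x: np.ndarray, y: np.ndarray, params: PukParams) -> np.ndarray:
    """Pearson VII kernel between rows of ``x`` and ``y`` (or two vectors)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ParameterError(f"dimension mismatch: {x.shape[1]} vs {y.shape[1]}")
    dist = cdist(x, y)
    scale = 2.0 * np.sqrt(2.0 ** (1.0 / params.omega) - 1.0) / params.sigma
    k = 1.0 / (1.0 + (dist * scale) ** 2) ** params.omega
    return k[0, 0] if k.size == 1 else np.squeeze(k) if min(k.shape) == 1 else k


def gram_matrix(x: np.ndarray, params: PukParams) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    dist = cdist(x, x)
    scale = 2.0 * np.sqrt(2.0 ** (1.0 / params.omega) - 1.0) / params.sigma
    return 1.0 / (1.0 + (dist * scale) ** 2) ** params.omega


def dual_objective(alpha: np.ndarray, y: np.ndarray, gram: np.ndarray) -> float:
    """Dual objective W(a) = sum a - 1/2 a^T (yy' * K) a."""
    ay = alpha * y
    return float(alpha.sum() - 0.5 * ay @ gram @ ay)


class _Smo:
    """Platt SMO over a precomputed Gram matrix."""

    def __init__(self, gram, y, C, tol, seed, max_steps):
        self.K = gram
        self.y = y.astype(float)
        self.C = C
        self.tol = tol
        self.n = len(y)
        self.alpha = np.zeros(self.n)
        self.b = 0.0
        self.errors = -self.y.copy()  # f(x) = 0 initially, E = f - y
        self.rng = np.random.default_rng(seed)
        self.max_steps = max_steps
        self.steps = 0
        self.eps = 1e-12

    def take_step(self, i1: int, i2: int) -> bool:
        if i1 == i2:
            return False
        a1, a2 = self.alpha[i1], self.alpha[i2]
        y1, y2 = self.y[i1], self.y[i2]
        e1, e2 = self.errors[i1], self.errors[i2]
        s = y1 * y2
        if s > 0:
            lo, hi = max(0.0, a1 + a2 - self.C), min(self.C, a1 + a2)
        else:
            lo, hi = max(0.0, a2 - a1), min(self.C, self.C + a2 - a1)
        if hi - lo < self.eps:
            return False
        k11, k12, k22 = self.K[i1, i1], self.K[i1, i2], self.K[i2, i2]
        eta = k11 + k22 - 2.0 * k12
        if eta > self.eps:
            a2_new = np.clip(a2 + y2 * (e1 - e2) / eta, lo, hi)
        else:
            # flat or concave direction: the dual change along the constraint is
            # dW(d) = d y2 (e1 - e2) - eta d^2 / 2; take the better endpoint
            def dual_gain(d: float) -> float:
                return d * y2 * (e1 - e2) - 0.5 * eta * d * d

            gain_lo, gain_hi = dual_gain(lo - a2), dual_gain(hi - a2)
            if gain_lo > gain_hi + self.eps:
                a2_new = lo
            elif gain_hi > gain_lo + self.eps:
                a2_new = hi
            else:
                return False
            if max(gain_lo, gain_hi) <= self.eps:
                return False
        if abs(a2_new - a2) < self.eps * (a2_new + a2 + self.eps):
            return False
        a1_new = a1 + s * (a2 - a2_new)
        d1, d2 = a1_new - a1, a2_new - a2
        b1 = self.b - e1 - y1 * d1 * k11 - y2 * d2 * k12
        b2 = self.b - e2 - y1 * d1 * k12 - y2 * d2 * k22
        if 0.0 < a1_new < self.C:
            b_new = b1
        elif 0.0 < a2_new < self.C:
            b_new = b2
        else:
            b_new = 0.5 * (b1 + b2)
        self.errors += y1 * d1 * self.K[i1] + y2 * d2 * self.K[i2] + (b_new - self.b)
        self.alpha[i1], self.alpha[i2] = a1_new, a2_new
        self.b = b_new
        # keep cached errors exact on the two optimized points
        self.errors[i1] = self._f(i1) - y1
        self.errors[i2] = self._f(i2) - y2
        self.steps += 1
        if self.steps > self.max_steps:
            raise ConvergenceError(
                f"SMO exceeded {self.max_steps} pair updates",
                iterations=self.steps,
                n_changed=int(np.count_nonzero(self.alpha)),
            )
        return True

    def _f(self, i: int) -> float:
        return float((self.alpha * self.y) @ self.K[:, i] + self.b)

    def examine(self, i2: int) -> bool:
        y2, a2, e2 = self.y[i2], self.alpha[i2], self.errors[i2]
        r2 = e2 * y2
        if (r2 < -self.tol and a2 < self.C) or (r2 > self.tol and a2 > 0.0):
            non_bound = np.flatnonzero((self.alpha > 0.0) & (self.alpha < self.C))
            if non_bound.size > 1:
                i1 = int(non_bound[np.argmax(np.abs(self.errors[non_bound] - e2))])
                if self.take_step(i1, i2):
                    return True
            if non_bound.size:
                start = self.rng.integers(non_bound.size)
                for k in range(non_bound.size):
                    if self.take_step(int(non_bound[(start + k) % non_bound.size]), i2):
                        return True
            start = self.rng.integers(self.n)
            for k in range(self.n):
                if self.take_step(int((start + k) % self.n), i2):
                    return True
        return False

    def solve(self) -> None:
        num_changed = 0
        examine_all = True
        while num_changed > 0 or examine_all:
            num_changed = 0
            if examine_all:
                for i in range(self.n):
                    num_changed += self.examine(i)
            else:
                for i in np.flatnonzero((self.alpha > 0.0) & (self.alpha < self.C)):
                    num_changed += self.examine(int(i))
            if examine_all:
                examine_all = False
            elif num_changed == 0:
                examine_all = True


def train_smo(
    features: np.ndarray,
    labels: np.ndarray,
    params: PukParams | None = None,
    seed: int = 0,
    max_steps: int | None = None,
    gram: np.ndarray | None = None,
):
    """Solve the dual on (features, labels in {+1, -1}); returns (alpha, b, diagnostics).

    ``gram`` may carry a precomputed kernel matrix to avoid recomputation.
    Deterministic for a fixed seed.
    """
    params = params or PukParams()
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ParameterError("labels must be +1/-1")
    if np.unique(y).size < 2:
        raise ParameterError("training data must contain both classes")
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.isfinite(x).all():
        raise ParameterError("features must be finite")
    if gram is None:
        gram = gram_matrix(x, params)
    if max_steps is None:
        max_steps = 200 * len(y) + 10000
    smo = _Smo(gram, y, params.C, params.tolerance, seed, max_steps)
    smo.solve()
    return smo.alpha, smo.b, {"steps": smo.steps, "n_support": int(np.count_nonzero(smo.alpha))}


def kkt_violation(alpha: np.ndarray, y: np.ndarray, gram: np.ndarray, b: float, C: float) -> float:
    """Largest KKT violation of a dual solution (0 at exact optimality)."""
    margins = y * ((alpha * y) @ gram + b)
    viol = np.zeros_like(margins)
    at_zero = alpha <= 1e-10
    at_c = alpha >= C - 1e-10
    interior = ~(at_zero | at_c)
    viol[at_zero] = np.maximum(0.0, 1.0 - margins[at_zero])
    viol[at_c] = np.maximum(0.0, margins[at_c] - 1.0)
    viol[interior] = np.abs(margins[interior] - 1.0)
    return float(viol.max()) if viol.size else 0.0


@dataclass
class SvmModel:
    """A trained PUK-SVM: support vectors, dual coefficients (alpha*y), bias,
    kernel parameters, and the feature standardization fitted on training data."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    params: PukParams
    mean: np.ndarray
    scale: np.ndarray
    layout: dict = field(default_factory=dict)

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != self.support_vectors.shape[1]:
            raise ParameterError(
                f"feature dimension {x.shape[1]} != model dimension {self.support_vectors.shape[1]}"
            )
        z = (x - self.mean) / self.scale
        k = np.atleast_2d(puk_kernel(z, self.support_vectors, self.params))
        if k.shape != (z.shape[0], self.n_support):
            k = k.reshape(z.shape[0], self.n_support)
        return k @ self.dual_coef + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        """+1 / -1 labels; a decision value of exactly 0 is called positive."""
        return np.where(self.decision_function(features) >= 0.0, 1, -1)

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "params": {
                "omega": self.params.omega,
                "sigma": self.params.sigma,
                "C": self.params.C,
                "tolerance": self.params.tolerance,
            },
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "layout": self.layout,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "SvmModel":
        return cls(
            support_vectors=np.array(d["support_vectors"], dtype=float),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            bias=float(d["bias"]),
            params=PukParams(**d["params"]),
            mean=np.array(d["mean"], dtype=float),
            scale=np.array(d["scale"], dtype=float),
            layout=d.get("layout", {}),
        )

    @classmethod
    def load(cls, path) -> "SvmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension mean and standard deviation; zero variance maps to scale 1."""
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale < 1e-12] = 1.0
    return mean, scale


def fit_svm(
    features: np.ndarray,
    labels: np.ndarray,
    params: PukParams | None = None,
    seed: int = 0,
    standardize: bool = True,
    layout: dict | None = None,
) -> SvmModel:
    """Standardize, solve the dual by SMO, and package the support expansion."""
    params = params or PukParams()
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float)
    if standardize:
        mean, scale = standardize_fit(x)
    else:
        mean, scale = np.zeros(x.shape[1]), np.ones(x.shape[1])
    z = (x - mean) / scale
    alpha, b, _ = train_smo(z, y, params, seed=seed)
    sv = alpha > 1e-10
    return SvmModel(
        support_vectors=z[sv],
        dual_coef=(alpha * y)[sv],
        bias=b,
        params=params,
        mean=mean,
        scale=scale,
        layout=layout or {},
    )
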