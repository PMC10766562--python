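"""Gaussian-process regression primitives.

The mixture components of the trajectory model are GPs with a negative
linear mean function m(t) = b + s·t (s ≤ 0, encoding the expectation of
monotonic functional decline) and either a squared-exponential kernel

    k(t, t') = σ_f² · exp(−(t − t')² / (2 ℓ²))

for smooth, possibly nonlinear trajectories, or a homogeneous linear
kernel k(t, t') = σ_f² · t · t' for the linear-kernel benchmark.  The
linear kernel passes through the onset origin, consistent with
trajectories anchored at (0, y_max).

Hyperparameters (signal variance σ_f², length-scale ℓ, observation-noise
variance σ_n², mean slope s) are optimized by type-II maximum likelihood
on the log scale with analytic gradients, optionally penalized by
log-normal priors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

__all__ = [
    "GPHyperparams",
    "GPPosterior",
    "HyperPriors",
    "se_kernel",
    "linear_kernel",
    "kernel_matrix",
    "linear_mean",
    "gp_posterior",
    "log_marginal_likelihood",
    "optimize_hyperparams",
    "default_bounds",
]

LENGTH_SCALE_FLOOR = 0.05  # years; below the resolution of clinic visit spacing


@dataclass(frozen=True)
class GPHyperparams:
    """Hyperparameters of one GP mixture component.

    Units: variances in score-points², length_scale in years, mean_slope
    in points/year (non-positive), mean_intercept in points.
    """

    signal_variance: float
    length_scale: float
    noise_variance: float
    mean_slope: float = 0.0
    mean_intercept: float = 0.0

    def __post_init__(self) -> None:
        for name in ("signal_variance", "length_scale", "noise_variance"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if self.length_scale < LENGTH_SCALE_FLOOR:
            raise ValueError(
                f"length_scale {self.length_scale} below floor {LENGTH_SCALE_FLOOR}"
            )
        if not (np.isfinite(self.mean_slope) and self.mean_slope <= 0):
            raise ValueError(f"mean_slope must be finite and <= 0, got {self.mean_slope}")
        if not np.isfinite(self.mean_intercept):
            raise ValueError("mean_intercept must be finite")

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps({"units": {"signal_variance": "points^2", "length_scale": "years",
                                  "noise_variance": "points^2", "mean_slope": "points/year",
                                  "mean_intercept": "points"}, **asdict(self)}, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, src: str | Path) -> "GPHyperparams":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        d.pop("units", None)
        return cls(**d)


def se_kernel(t1: np.ndarray, t2: np.ndarray, h: GPHyperparams) -> np.ndarray:
    """Squared-exponential covariance between two time vectors."""
    t1 = np.asarray(t1, float).ravel()
    t2 = np.asarray(t2, float).ravel()
    d = t1[:, None] - t2[None, :]
    return h.signal_variance * np.exp(-0.5 * (d / h.length_scale) ** 2)


def linear_kernel(t1: np.ndarray, t2: np.ndarray, h: GPHyperparams) -> np.ndarray:
    """Homogeneous linear covariance through the onset origin."""
    t1 = np.asarray(t1, float).ravel()
    t2 = np.asarray(t2, float).ravel()
    return h.signal_variance * np.outer(t1, t2)


_KERNELS: dict[str, Callable] = {"se": se_kernel, "linear": linear_kernel}


def kernel_matrix(t1, t2, h: GPHyperparams, kernel: str = "se") -> np.ndarray:
    try:
        return _KERNELS[kernel](t1, t2, h)
    except KeyError:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {sorted(_KERNELS)}") from None


def linear_mean(t: np.ndarray, h: GPHyperparams) -> np.ndarray:
    """Negative-linear prior mean m(t) = intercept + slope * t."""
    return h.mean_intercept + h.mean_slope * np.asarray(t, float).ravel()


def _train_gram(t: np.ndarray, h: GPHyperparams, kernel: str, jitter_frac: float) -> np.ndarray:
    K = kernel_matrix(t, t, h, kernel)
    K[np.diag_indices_from(K)] += h.noise_variance + jitter_frac * h.signal_variance
    return K


@dataclass
class GPPosterior:
    """Posterior predictive of a GP conditioned on training visits.

    Callable: ``mean, var = post(times)``; ``predict_cov`` returns the
    full posterior covariance, and ``predictive_logpdf`` the log density
    of new noisy observations under the posterior (the quantity used for
    cluster membership scoring).
    """

    t_train: np.ndarray
    h: GPHyperparams
    kernel: str = "se"
    jitter_frac: float = 1e-6
    _chol: np.ndarray | None = None
    _alpha: np.ndarray | None = None
    _lml: float | None = None

    @classmethod
    def fit(cls, t, y, h: GPHyperparams, kernel: str = "se", jitter_frac: float = 1e-6):
        t = np.asarray(t, float).ravel()
        y = np.asarray(y, float).ravel()
        if t.size == 0:
            return cls(t, h, kernel, jitter_frac)
        K = _train_gram(t, h, kernel, jitter_frac)
        try:
            L = cholesky(K, lower=True)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"training Gram matrix not positive definite (n={t.size}, "
                f"h={h}): {err}"
            ) from err
        r = y - linear_mean(t, h)
        alpha = cho_solve((L, True), r)
        lml = (
            -0.5 * float(r @ alpha)
            - float(np.sum(np.log(np.diag(L))))
            - 0.5 * t.size * math.log(2 * math.pi)
        )
        return cls(t, h, kernel, jitter_frac, L, alpha, lml)

    @property
    def n_train(self) -> int:
        return self.t_train.size

    @property
    def log_marginal_likelihood(self) -> float:
        if self._lml is None:
            return 0.0  # empty conditioning set: log p(nothing) = 0
        return self._lml

    def _cross(self, t_query: np.ndarray) -> np.ndarray:
        return kernel_matrix(self.t_train, t_query, self.h, self.kernel)

    def __call__(self, t_query) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and pointwise (noise-free) variance at query times."""
        t_query = np.asarray(t_query, float).ravel()
        prior_var = np.diag(kernel_matrix(t_query, t_query, self.h, self.kernel)).copy()
        if self.n_train == 0:
            return linear_mean(t_query, self.h), prior_var
        Ks = self._cross(t_query)
        mean = linear_mean(t_query, self.h) + Ks.T @ self._alpha
        V = solve_triangular(self._chol, Ks, lower=True)
        var = np.maximum(prior_var - np.sum(V * V, axis=0), 0.0)
        return mean, var

    def predict_cov(self, t_query) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and full covariance at query times."""
        t_query = np.asarray(t_query, float).ravel()
        Kqq = kernel_matrix(t_query, t_query, self.h, self.kernel)
        if self.n_train == 0:
            return linear_mean(t_query, self.h), Kqq
        Ks = self._cross(t_query)
        mean = linear_mean(t_query, self.h) + Ks.T @ self._alpha
        V = solve_triangular(self._chol, Ks, lower=True)
        return mean, Kqq - V.T @ V

    def predictive_logpdf(self, t_new, y_new) -> float:
        """Log density of new noisy observations under the posterior.

        Equals log p(y_new | y_train) = lml(train ∪ new) − lml(train),
        computed via the conditional Gaussian.
        """
        t_new = np.asarray(t_new, float).ravel()
        y_new = np.asarray(y_new, float).ravel()
        mean, cov = self.predict_cov(t_new)
        cov = cov + (self.h.noise_variance + self.jitter_frac * self.h.signal_variance) * np.eye(t_new.size)
        L = cholesky(cov, lower=True)
        r = y_new - mean
        z = solve_triangular(L, r, lower=True)
        return float(
            -0.5 * z @ z - np.sum(np.log(np.diag(L))) - 0.5 * t_new.size * math.log(2 * math.pi)
        )


def gp_posterior(t, y, h: GPHyperparams, t_query, kernel: str = "se",
                 jitter_frac: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and pointwise variance at query times (convenience)."""
    return GPPosterior.fit(t, y, h, kernel, jitter_frac)(t_query)


def log_marginal_likelihood(t, y, h: GPHyperparams, kernel: str = "se",
                            jitter_frac: float = 1e-6) -> float:
    """log N(y | m(t), K(t,t) + σ_n² I)."""
    return GPPosterior.fit(t, y, h, kernel, jitter_frac).log_marginal_likelihood


@dataclass(frozen=True)
class HyperPriors:
    """Optional log-normal priors on positive hyperparameters.

    Each entry maps a field name ("signal_variance" | "length_scale" |
    "noise_variance") to (mu, sigma) of a normal on the log parameter.
    Acts as a penalty added to the marginal likelihood during
    optimization; unpenalized fields are omitted.
    """

    lognormal: Mapping[str, tuple[float, float]]

    def logpdf(self, h: GPHyperparams) -> float:
        total = 0.0
        for name, (mu, sigma) in self.lognormal.items():
            x = math.log(getattr(h, name))
            total += -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi) - x
        return total

    def grad_log(self, name: str, log_value: float) -> float:
        """d/d(log θ) of the log prior (including the Jacobian term)."""
        if name not in self.lognormal:
            return 0.0
        mu, sigma = self.lognormal[name]
        return -(log_value - mu) / sigma**2 - 1.0


def default_priors(y_max: float = 48.0) -> HyperPriors:
    """Weakly informative priors spanning plausible clinical regimes.

    Length-scale centred at 1 yr (typical decline timescale), signal sd
    at a quarter of the scale span, noise sd at ~6% of the span; all
    with wide (1.0 on the log scale) spread.
    """
    return HyperPriors(
        {
            "length_scale": (0.0, 1.0),
            "signal_variance": (2 * math.log(y_max / 4.0), 1.0),
            "noise_variance": (2 * math.log(y_max / 16.0), 1.0),
        }
    )


def default_bounds(y_max: float = 48.0) -> dict[str, tuple[float, float]]:
    """Box bounds for hyperparameter optimization (natural scale)."""
    return {
        "signal_variance": (1e-4, y_max**2),
        "length_scale": (LENGTH_SCALE_FLOOR, 20.0),
        "noise_variance": (1e-4, y_max**2),
        "mean_slope": (-2.0 * y_max, 0.0),
    }


def _nll_and_grad(theta, t, y, kernel, jitter_frac, priors, fix_slope, h_template):
    """Negative penalized lml and gradient in the optimization parameterization.

    theta = [log σ_f², log ℓ, log σ_n²] (+ [slope] unless fixed) for the
    SE kernel; the linear kernel drops log ℓ.
    """
    i = 0
    log_sv = theta[i]; i += 1
    if kernel == "se":
        log_ls = theta[i]; i += 1
    else:
        log_ls = math.log(h_template.length_scale)
    log_nv = theta[i]; i += 1
    slope = h_template.mean_slope if fix_slope else theta[i]

    h = replace(
        h_template,
        signal_variance=math.exp(log_sv),
        length_scale=math.exp(log_ls),
        noise_variance=math.exp(log_nv),
        mean_slope=min(slope, 0.0),
    )
    n = t.size
    K_sig = kernel_matrix(t, t, h, kernel)
    K = K_sig + (h.noise_variance + jitter_frac * h.signal_variance) * np.eye(n)
    L, low = cho_factor(K, lower=True)
    r = y - linear_mean(t, h)
    alpha = cho_solve((L, low), r)
    lml = -0.5 * r @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * math.log(2 * math.pi)

    Kinv = cho_solve((L, low), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv  # dL/dK = A/2

    # dK/d log σ_f² = K_sig (+ jitter term), dK/d log σ_n² = σ_n² I
    g_sv = 0.5 * np.sum(A * (K_sig + jitter_frac * h.signal_variance * np.eye(n)))
    g_nv = 0.5 * np.trace(A) * h.noise_variance
    grads = [g_sv]
    if kernel == "se":
        d2 = (t[:, None] - t[None, :]) ** 2
        g_ls = 0.5 * np.sum(A * (K_sig * d2 / h.length_scale**2))
        grads.append(g_ls)
    grads.append(g_nv)
    if not fix_slope:
        grads.append(float(alpha @ t))

    obj = lml
    if priors is not None:
        obj += priors.logpdf(h)
        grads[0] += priors.grad_log("signal_variance", log_sv)
        if kernel == "se":
            grads[1] += priors.grad_log("length_scale", log_ls)
        idx_nv = 2 if kernel == "se" else 1
        grads[idx_nv] += priors.grad_log("noise_variance", log_nv)
    return -obj, -np.asarray(grads)


def optimize_hyperparams(
    t,
    y,
    init: GPHyperparams,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    priors: HyperPriors | None = None,
    kernel: str = "se",
    jitter_frac: float = 1e-6,
    fix_intercept: bool = True,
    fix_slope: bool = False,
    maxiter: int = 100,
) -> tuple[GPHyperparams, bool]:
    """Type-II ML (or MAP) hyperparameter fit by L-BFGS-B on the log scale.

    Returns (hyperparameters, converged_flag).  The returned point never
    has a lower penalized marginal likelihood than ``init``: on
    optimizer failure or non-improvement, ``init`` is returned with the
    flag set False.  ``fix_intercept`` keeps the mean intercept pinned
    (at y_max for anchored trajectories).
    """
    if not fix_intercept:
        raise NotImplementedError("free mean intercept is not supported; anchor the data")
    t = np.asarray(t, float).ravel()
    y = np.asarray(y, float).ravel()
    b = default_bounds(max(abs(init.mean_intercept), 48.0))
    b.update(bounds or {})

    def pack(h: GPHyperparams):
        theta = [math.log(h.signal_variance)]
        box = [tuple(math.log(v) for v in b["signal_variance"])]
        if kernel == "se":
            theta.append(math.log(h.length_scale))
            box.append(tuple(math.log(v) for v in b["length_scale"]))
        theta.append(math.log(h.noise_variance))
        box.append(tuple(math.log(v) for v in b["noise_variance"]))
        if not fix_slope:
            theta.append(h.mean_slope)
            box.append(b["mean_slope"])
        return np.array(theta), box

    theta0, box = pack(init)
    obj0 = -_nll_and_grad(theta0, t, y, kernel, jitter_frac, priors, fix_slope, init)[0]
    try:
        res = minimize(
            _nll_and_grad,
            theta0,
            args=(t, y, kernel, jitter_frac, priors, fix_slope, init),
            jac=True,
            method="L-BFGS-B",
            bounds=box,
            options={"maxiter": maxiter},
        )
    except np.linalg.LinAlgError:
        return init, False
    if not np.isfinite(res.fun) or -res.fun < obj0:
        return init, False
    i = 0
    log_sv = res.x[i]; i += 1
    if kernel == "se":
        log_ls = res.x[i]; i += 1
    else:
        log_ls = math.log(init.length_scale)
    log_nv = res.x[i]; i += 1
    slope = init.mean_slope if fix_slope else min(res.x[i], 0.0)
    fitted = replace(
        init,
        signal_variance=math.exp(log_sv),
        length_scale=math.exp(log_ls),
        noise_variance=math.exp(log_nv),
        mean_slope=slope,
    )
    return fitted, bool(res.success or -res.fun >= obj0)
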