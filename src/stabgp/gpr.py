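"""Exact Gaussian-process regression with Matérn-3/2 kernels.

The isotropic kernel is

    k(x_i, x_j) = sigma^2 (1 + sqrt(3) r / l) exp(-sqrt(3) r / l),

with r the Euclidean distance; the automatic-relevance-determination (ARD)
variant replaces r/l by r_ARD = sqrt(sum_m (x_im - x_jm)^2 / l_m^2), one
length scale per feature, so irrelevant features are down-weighted by large
l_m. Observation noise is a learned Gaussian variance added on the
diagonal (stability-constant measurements carry real scatter; exact
interpolation would be both wrong and numerically fragile), plus a small
jitter (default 1e-8, escalated tenfold on factorization failure).

Model/results split follows statsmodels: ``GaussianProcess(X, y)`` holds
data, ``fit()`` maximizes the log marginal likelihood over
(sigma^2, l_1..l_d, noise) with multi-restart L-BFGS and analytic
gradients, and returns a :class:`GPResults` carrying the hyperparameters,
the factorized covariance, ``predict`` and ``summary``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

SQRT3 = np.sqrt(3.0)

__all__ = [
    "KernelParams",
    "GaussianProcess",
    "GPResults",
    "matern32",
    "matern32_ard",
    "kernel_matrix",
]


@dataclass
class KernelParams:
    """Hyperparameters of the Matérn-3/2 (ARD) kernel plus noise.

    ``signal_amplitude`` is sigma (so the prior variance is sigma^2);
    ``length_scales`` has one entry per feature (or a single entry for the
    isotropic kernel); ``noise_variance`` is the Gaussian observation-noise
    variance on the standardized-target scale; ``jitter`` is the fixed
    diagonal added for numerical positive-definiteness.
    """

    signal_amplitude: float
    length_scales: np.ndarray
    noise_variance: float = 0.0
    jitter: float = 1e-8

    def __post_init__(self):
        self.length_scales = np.atleast_1d(
            np.asarray(self.length_scales, dtype=float)
        )
        if self.signal_amplitude <= 0:
            raise ValueError("signal amplitude must be > 0")
        if np.any(self.length_scales <= 0):
            raise ValueError("length scales must be > 0")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be >= 0")

    @property
    def signal_variance(self) -> float:
        return self.signal_amplitude**2


def _check_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite input to kernel")


def matern32(x_i, x_j, sigma: float, l: float) -> float:
    """Isotropic Matérn-3/2 covariance between two points."""
    if l <= 0:
        raise ValueError("length scale must be > 0")
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    _check_finite(x_i, x_j)
    r = np.linalg.norm(x_i - x_j)
    a = SQRT3 * r / l
    return float(sigma**2 * (1.0 + a) * np.exp(-a))


def matern32_ard(x_i, x_j, sigma: float, l_vec) -> float:
    """ARD Matérn-3/2 covariance with per-feature length scales."""
    x_i = np.atleast_1d(np.asarray(x_i, dtype=float))
    x_j = np.atleast_1d(np.asarray(x_j, dtype=float))
    l_vec = np.atleast_1d(np.asarray(l_vec, dtype=float))
    if x_i.shape != x_j.shape or x_i.shape[-1] != l_vec.shape[-1]:
        raise ValueError(
            f"dimension mismatch: x has {x_i.shape[-1]} features, "
            f"l has {l_vec.shape[-1]}"
        )
    _check_finite(x_i, x_j)
    if np.any(l_vec <= 0):
        raise ValueError("length scales must be > 0")
    r = np.sqrt(np.sum((x_i - x_j) ** 2 / l_vec**2))
    a = SQRT3 * r
    return float(sigma**2 * (1.0 + a) * np.exp(-a))


def _ard_distance(X: np.ndarray, Z: np.ndarray, l: np.ndarray) -> np.ndarray:
    Xs = X / l
    Zs = Z / l
    d2 = (
        np.sum(Xs**2, axis=1)[:, None]
        + np.sum(Zs**2, axis=1)[None, :]
        - 2.0 * Xs @ Zs.T
    )
    return np.sqrt(np.maximum(d2, 0.0))


def kernel_matrix(
    X: np.ndarray, Z: np.ndarray, params: KernelParams
) -> np.ndarray:
    """Cross-covariance matrix K(X, Z) under the ARD Matérn-3/2 kernel."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    l = params.length_scales
    if l.size == 1:
        l = np.full(X.shape[1], l[0])
    if l.size != X.shape[1]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} features, "
            f"length_scales has {l.size}"
        )
    a = SQRT3 * _ard_distance(X, Z, l)
    return params.signal_variance * (1.0 + a) * np.exp(-a)


# ---------------------------------------------------------------------------


class GaussianProcess:
    """Exact GP regression model (zero prior mean on standardized targets).

    Parameters
    ----------
    X : array-like or DataFrame, shape (n, d)
        Training inputs; expected standardized when used in the stability
        pipeline (the kernel is distance-based).
    y : array-like, shape (n,)
        Targets; standardized internally, predictions are de-standardized.
    column_names
        Feature names (taken from the DataFrame if given); predictions on
        DataFrames are checked against them.
    fixed_noise
        If not None, the noise variance is held at this value (on the
        standardized-target scale) instead of being learned.
    max_rows
        Practical ceiling for dense factorization; if ``n > max_rows`` a
        uniform random subsample of that size is used (seeded).
    """

    def __init__(
        self,
        X,
        y,
        *,
        column_names: Sequence[str] | None = None,
        fixed_noise: float | None = None,
        jitter: float = 1e-8,
        max_rows: int | None = None,
        subsample_seed: int = 0,
    ):
        if isinstance(X, pd.DataFrame):
            if column_names is None:
                column_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y row counts differ")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite training data")
        if max_rows is not None and X.shape[0] > max_rows:
            rng = np.random.default_rng(subsample_seed)
            idx = np.sort(
                rng.choice(X.shape[0], size=max_rows, replace=False)
            )
            X, y = X[idx], y[idx]
        self.X = X
        self.y_raw = y
        self.y_mean = float(y.mean())
        self.y_scale = float(y.std()) or 1.0
        self.y = (y - self.y_mean) / self.y_scale
        self.column_names = (
            list(column_names) if column_names is not None else None
        )
        self.fixed_noise = fixed_noise
        self.jitter = jitter

    @property
    def nobs(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    # -- log marginal likelihood -------------------------------------------
    def _feature_sqdiff(self, m: int) -> np.ndarray:
        col = self.X[:, m]
        return (col[:, None] - col[None, :]) ** 2

    def loglike_and_grad(self, theta: np.ndarray):
        """Log marginal likelihood and gradient in log-parameters.

        ``theta`` = [log sigma^2, log l_1..d, (log noise)]; the noise entry
        is absent when ``fixed_noise`` is set.
        """
        n, d = self.X.shape
        sig2 = np.exp(theta[0])
        l = np.exp(theta[1 : 1 + d])
        noise = (
            self.fixed_noise
            if self.fixed_noise is not None
            else np.exp(theta[1 + d])
        )
        a = SQRT3 * _ard_distance(self.X, self.X, l)
        E = np.exp(-a)
        Kf = sig2 * (1.0 + a) * E
        K = Kf + (noise + self.jitter) * np.eye(n)
        try:
            L = cholesky(K, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros_like(theta)
        alpha = cho_solve((L, True), self.y)
        ll = (
            -0.5 * self.y @ alpha
            - np.sum(np.log(np.diag(L)))
            - 0.5 * n * np.log(2.0 * np.pi)
        )
        Kinv = cho_solve((L, True), np.eye(n))
        W = np.outer(alpha, alpha) - Kinv  # d(ll)/dK = W/2
        grad = np.empty_like(theta)
        grad[0] = 0.5 * np.sum(W * Kf)  # d/d log sigma^2
        base = 3.0 * sig2 * E  # dK/d log l_m = base * D_m^2 / l_m^2
        for m in range(d):
            Dm2 = self._feature_sqdiff(m)
            grad[1 + m] = 0.5 * np.sum(W * (base * Dm2)) / l[m] ** 2
        if self.fixed_noise is None:
            grad[1 + d] = 0.5 * np.trace(W) * noise
        return ll, grad

    def loglike(self, params: KernelParams) -> float:
        theta = self._pack(params)
        ll, _ = self.loglike_and_grad(theta)
        return ll

    def _pack(self, params: KernelParams) -> np.ndarray:
        l = params.length_scales
        if l.size == 1:
            l = np.full(self.dim, l[0])
        theta = [np.log(params.signal_variance), *np.log(l)]
        if self.fixed_noise is None:
            theta.append(np.log(max(params.noise_variance, 1e-12)))
        return np.array(theta)

    def _unpack(self, theta: np.ndarray) -> KernelParams:
        d = self.dim
        noise = (
            self.fixed_noise
            if self.fixed_noise is not None
            else float(np.exp(theta[1 + d]))
        )
        return KernelParams(
            signal_amplitude=float(np.exp(0.5 * theta[0])),
            length_scales=np.exp(theta[1 : 1 + d]),
            noise_variance=noise,
            jitter=self.jitter,
        )

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        *,
        n_restarts: int = 5,
        seed: int = 0,
        maxiter: int = 200,
        params: KernelParams | None = None,
    ) -> "GPResults":
        """Maximize the log marginal likelihood (multi-restart L-BFGS).

        Restart initial points are drawn log-uniformly: sigma^2 in
        [0.1, 10], each l_m in [0.3, 30], noise in [1e-4, 1]. The first
        start is the fixed default (sigma^2=1, l_m=sqrt(d), noise=0.1).
        With ``params`` given, optimization is skipped and the posterior is
        computed at those hyperparameters (used e.g. for out-of-fold
        refits and for noise-free interpolation checks).
        """
        d = self.dim
        if params is not None:
            theta = self._pack(params)
            ll, _ = self.loglike_and_grad(theta)
            return self._results(self._unpack(theta), ll, converged=True)

        rng = np.random.default_rng(seed)
        n_free = 1 + d + (0 if self.fixed_noise is not None else 1)
        bounds = [(np.log(1e-4), np.log(1e4))] + [
            (np.log(1e-3), np.log(1e6))
        ] * d
        if self.fixed_noise is None:
            bounds.append((np.log(1e-8), np.log(1e2)))

        starts = [
            np.concatenate(
                [
                    [0.0],
                    np.full(d, 0.5 * np.log(d)),
                    [] if self.fixed_noise is not None else [np.log(0.1)],
                ]
            )
        ]
        for _ in range(max(0, n_restarts - 1)):
            s = np.concatenate(
                [
                    rng.uniform(np.log(0.1), np.log(10.0), size=1),
                    rng.uniform(np.log(0.3), np.log(30.0), size=d),
                    []
                    if self.fixed_noise is not None
                    else rng.uniform(np.log(1e-4), np.log(1.0), size=1),
                ]
            )
            starts.append(s)

        def neg(theta):
            ll, g = self.loglike_and_grad(theta)
            if not np.isfinite(ll):
                return 1e12, np.zeros(n_free)
            return -ll, -g

        best = None
        for s in starts:
            res = minimize(
                neg,
                s,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
        ll, _ = self.loglike_and_grad(best.x)
        return self._results(self._unpack(best.x), ll, converged=best.success)

    def _results(
        self, params: KernelParams, llf: float, converged: bool
    ) -> "GPResults":
        n = self.nobs
        K = kernel_matrix(self.X, self.X, params) + (
            params.noise_variance + params.jitter
        ) * np.eye(n)
        jit = params.jitter
        while True:
            try:
                L = cholesky(K, lower=True)
                break
            except np.linalg.LinAlgError:
                jit *= 10.0
                if jit > 1e-2:
                    w = np.linalg.eigvalsh(K)
                    raise np.linalg.LinAlgError(
                        "covariance not positive definite even after "
                        f"jitter escalation to {jit:.0e}; eigenvalue range "
                        f"[{w.min():.3e}, {w.max():.3e}]"
                    )
                K[np.diag_indices(n)] += jit
        alpha = cho_solve((L, True), self.y)
        return GPResults(self, params, L, alpha, llf, converged)


@dataclass
class GPResults:
    """Fitted GP: hyperparameters, factorized covariance, predictions."""

    model: GaussianProcess
    params: KernelParams
    chol_lower: np.ndarray = dataclass_field(repr=False, default=None)
    alpha: np.ndarray = dataclass_field(repr=False, default=None)
    llf: float = np.nan
    converged: bool = True

    def _coerce(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            names = self.model.column_names
            if names is not None:
                missing = [c for c in names if c not in X.columns]
                extra = [c for c in X.columns if c not in names]
                if missing or extra:
                    raise ValueError(
                        f"column mismatch: missing {missing}, "
                        f"unexpected {extra}"
                    )
                X = X[names]
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.model.dim:
            raise ValueError(
                f"expected {self.model.dim} features, got {X.shape[1]}"
            )
        return X

    def predict(
        self, X, *, include_noise: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and standard deviation on the original y scale.

        ``include_noise=True`` (default) returns the predictive std of a
        new observation (latent variance + noise variance); set False for
        the latent-function std.
        """
        X = self._coerce(X)
        Ks = kernel_matrix(X, self.model.X, self.params)
        mean_std = Ks @ self.alpha
        V = solve_triangular(self.chol_lower, Ks.T, lower=True)
        var = self.params.signal_variance - np.sum(V**2, axis=0)
        if include_noise:
            var = var + self.params.noise_variance
        var = np.maximum(var, 0.0)
        mean = mean_std * self.model.y_scale + self.model.y_mean
        std = np.sqrt(var) * self.model.y_scale
        return mean, std

    def summary(self) -> str:
        p = self.params
        lines = [
            "Gaussian Process Regression Results",
            "=" * 52,
            f"No. observations:     {self.model.nobs}",
            f"No. features:         {self.model.dim}",
            f"Log marginal lik.:    {self.llf:.4f}",
            f"Converged:            {self.converged}",
            f"Signal amplitude:     {p.signal_amplitude:.6g}",
            f"Noise variance:       {p.noise_variance:.6g}"
            + ("  (fixed)" if self.model.fixed_noise is not None else ""),
            "-" * 52,
            "Length scales (ascending = most relevant first):",
        ]
        names = self.model.column_names or [
            f"x{m}" for m in range(self.model.dim)
        ]
        order = np.argsort(p.length_scales)
        for m in order[: min(20, len(order))]:
            lines.append(f"  {names[m]:<32s} {p.length_scales[m]:.6g}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        m = self.model
        return {
            "schema": "stabgp.gpr/1",
            "signal_amplitude": self.params.signal_amplitude,
            "length_scales": self.params.length_scales.tolist(),
            "noise_variance": self.params.noise_variance,
            "jitter": self.params.jitter,
            "fixed_noise": m.fixed_noise,
            "column_names": m.column_names,
            "X": m.X.tolist(),
            "y": m.y_raw.tolist(),
            "llf": self.llf,
            "converged": self.converged,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, payload: dict) -> "GPResults":
        if payload.get("schema") != "stabgp.gpr/1":
            raise ValueError("unrecognized model schema")
        model = GaussianProcess(
            np.array(payload["X"], dtype=float),
            np.array(payload["y"], dtype=float),
            column_names=payload["column_names"],
            fixed_noise=payload["fixed_noise"],
            jitter=payload["jitter"],
        )
        params = KernelParams(
            signal_amplitude=payload["signal_amplitude"],
            length_scales=np.array(payload["length_scales"], dtype=float),
            noise_variance=payload["noise_variance"],
            jitter=payload["jitter"],
        )
        res = model.fit(params=params)
        res.llf = payload.get("llf", res.llf)
        res.converged = payload.get("converged", True)
        return res

    @classmethod
    def load(cls, path: str | Path) -> "GPResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_gpr(
    X,
    y,
    *,
    n_restarts: int = 5,
    seed: int = 0,
    maxiter: int = 200,
    fixed_noise: float | None = None,
    max_rows: int | None = None,
    **model_kwargs,
) -> GPResults:
    """Convenience wrapper: build a :class:`GaussianProcess` and fit it."""
    model = GaussianProcess(
        X, y, fixed_noise=fixed_noise, max_rows=max_rows, **model_kwargs
    )
    return model.fit(n_restarts=n_restarts, seed=seed, maxiter=maxiter)
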