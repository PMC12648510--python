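"""Hyperparameter learning by free-energy maximization.

Hyperparameters live in an unconstrained Gaussian space: positive
parameters through a log transform, bounded ones (λ, w2) through a
scaled logistic sigmoid with upper bound α, unbounded ones through the
identity.  Fixed parameters are pinned at their transformed prior means;
the free ones are stacked into a vector ξ and fitted by maximizing

    V(ξ) = Σ_k ln p(o_k | r̂0,k, ξ) + ln p(ξ)

— the one-step-ahead predictive log-likelihood accumulated by the filter
plus the Gaussian prior — with BFGS from the prior mean.  A Laplace
approximation at the optimum μξ gives the posterior covariance
Cξ = (−∇²V)⁻¹ and the negative free energy

    F = V(μξ) + dξ/2·ln(2πe) + ½·ln det Cξ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .ablation_filter import AblationParams, run_ablation_filter
from .filter_core import FilterConfig, ModelParams, run_filter, total_predictive_loglik
from .linalg_utils import SPDGuardError

__all__ = [
    "ParamSpecEntry",
    "HyperParamSpec",
    "FitResult",
    "transform",
    "untransform",
    "full_model_spec",
    "ablation_model_spec",
    "objective_V",
    "fit",
    "negative_free_energy",
    "fd_gradient",
    "fd_hessian",
    "maximize_objective",
]

logger = logging.getLogger(__name__)

_DIVERGED = -1e12  # sentinel objective value for a diverged filter


def transform(value_G: np.ndarray, kind: str, alpha: float = 1.0) -> np.ndarray:
    """Map a transformed-space (Gaussian) value to native space."""
    v = np.asarray(value_G, dtype=float)
    if kind == "identity":
        return v
    if kind == "log":
        return np.exp(v)
    if kind == "sigmoid":
        if alpha <= 0:
            raise ValueError("sigmoid transform requires alpha > 0")
        return alpha / (1.0 + np.exp(-v))
    raise ValueError(f"unknown transform kind {kind!r}")


def untransform(native: np.ndarray, kind: str, alpha: float = 1.0) -> np.ndarray:
    """Exact inverse of :func:`transform` on the open native range."""
    v = np.asarray(native, dtype=float)
    if kind == "identity":
        return v
    if kind == "log":
        if np.any(v <= 0):
            raise ValueError("log transform requires positive native values")
        return np.log(v)
    if kind == "sigmoid":
        if np.any(v <= 0) or np.any(v >= alpha):
            raise ValueError(f"sigmoid untransform requires values in (0, {alpha})")
        return np.log(v / (alpha - v))
    raise ValueError(f"unknown transform kind {kind!r}")


@dataclass(frozen=True)
class ParamSpecEntry:
    """One named hyperparameter: transform, Gaussian prior, fixed/free flag.

    prior_mean and prior_var (diagonal covariance) are stated in the
    transformed space.
    """

    name: str
    kind: str
    prior_mean: np.ndarray
    prior_var: np.ndarray
    free: bool
    alpha: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "prior_mean", np.atleast_1d(np.asarray(self.prior_mean, float)))
        object.__setattr__(self, "prior_var", np.atleast_1d(np.asarray(self.prior_var, float)))
        if self.prior_var.shape != self.prior_mean.shape:
            raise ValueError(f"{self.name}: prior mean/variance shape mismatch")
        if self.free and np.any(self.prior_var <= 0):
            raise ValueError(f"{self.name}: free parameters need a positive prior variance")

    @property
    def size(self) -> int:
        return self.prior_mean.size


@dataclass(frozen=True)
class HyperParamSpec:
    """Ordered collection of hyperparameter entries for one model."""

    model: str  # "full" | "ablation"
    entries: tuple[ParamSpecEntry, ...]
    d1: int

    def entry(self, name: str) -> ParamSpecEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def free_entries(self) -> tuple[ParamSpecEntry, ...]:
        return tuple(e for e in self.entries if e.free)

    @property
    def dxi(self) -> int:
        return sum(e.size for e in self.free_entries)

    def prior_mean_vector(self) -> np.ndarray:
        return np.concatenate([e.prior_mean for e in self.free_entries]) if self.dxi else np.empty(0)

    def prior_var_vector(self) -> np.ndarray:
        return np.concatenate([e.prior_var for e in self.free_entries]) if self.dxi else np.empty(0)

    def pack(self, values_G: dict[str, np.ndarray]) -> np.ndarray:
        """Stack free parameters' transformed-space values into ξ."""
        return np.concatenate([np.atleast_1d(values_G[e.name]) for e in self.free_entries])

    def unpack(self, xi: np.ndarray) -> dict[str, np.ndarray]:
        """ξ plus pinned fixed entries → transformed-space values by name."""
        xi = np.asarray(xi, dtype=float)
        if xi.shape != (self.dxi,):
            raise ValueError(f"xi must have length {self.dxi}")
        out: dict[str, np.ndarray] = {}
        k = 0
        for e in self.entries:
            if e.free:
                out[e.name] = xi[k : k + e.size].copy()
                k += e.size
            else:
                out[e.name] = e.prior_mean.copy()
        return out

    def prior_logpdf(self, xi: np.ndarray) -> float:
        """Gaussian prior density over the free parameters only."""
        if self.dxi == 0:
            return 0.0
        m = self.prior_mean_vector()
        v = self.prior_var_vector()
        d = np.asarray(xi, float) - m
        return float(-0.5 * np.sum(d * d / v) - 0.5 * np.sum(np.log(2.0 * np.pi * v)))

    def to_native(self, xi: np.ndarray):
        """Build the model's native parameter object from ξ."""
        g = self.unpack(xi)
        if self.model == "full":
            d1 = self.d1
            return ModelParams(
                w1=transform(g["w1"], "log"),
                b1=g["b1"],
                w2=transform(g["w2"], "sigmoid", self.entry("w2").alpha),
                b2=g["b2"],
                lam=transform(g["lam"], "sigmoid", self.entry("lam").alpha),
                mu1_0=g["mu1_0"],
                C1_0=np.diag(transform(g["c1"], "log")),
                mu2_0=g["mu2_0"],
                C2_0=np.diag(transform(g["c2"], "log")),
            )
        if self.model == "ablation":
            return AblationParams(
                sigma1=transform(g["sigma1"], "log"),
                w1=transform(g["w1"], "log"),
                b1=g["b1"],
                mu1_0=g["mu1_0"],
                C1_0=np.diag(transform(g["c1"], "log")),
            )
        raise ValueError(f"unknown model {self.model!r}")


def full_model_spec(d1: int = 2) -> HyperParamSpec:
    """Default hyperparameter table of the full hierarchical model.

    Free: μ2,0 (prior N(0, 0.1·I)), μ1,0 (prior N(25·1, I)) and the
    log-diagonal c1 of C1,0 (prior N(0, I)) — dξ = 7 for d1 = 2.  Fixed
    at their prior means: λ (sigmoid, α = 0.04), w2 (sigmoid, α = 1),
    b2 = 0, c2 = 0 (so C2,0 = I), w1 = 0.06 (log space) and b1 = 0.
    """
    d2 = d1 * (d1 + 1) // 2
    entries = (
        ParamSpecEntry("mu2_0", "identity", np.zeros(d2), 0.1 * np.ones(d2), free=True),
        ParamSpecEntry("mu1_0", "identity", 25.0 * np.ones(d1), np.ones(d1), free=True),
        ParamSpecEntry("c1", "log", np.zeros(d1), np.ones(d1), free=True),
        ParamSpecEntry("lam", "sigmoid", np.zeros(d2), np.ones(d2), free=False, alpha=0.04),
        ParamSpecEntry("w2", "sigmoid", np.zeros(d2), np.ones(d2), free=False, alpha=1.0),
        ParamSpecEntry("b2", "identity", np.zeros(d2), np.zeros(d2), free=False),
        ParamSpecEntry("c2", "log", np.zeros(d2), np.ones(d2), free=False),
        ParamSpecEntry("w1", "log", np.log(0.06) * np.ones(d1), np.zeros(d1), free=False),
        ParamSpecEntry("b1", "identity", np.zeros(d1), np.zeros(d1), free=False),
    )
    return HyperParamSpec(model="full", entries=entries, d1=d1)


def ablation_model_spec(d1: int = 2) -> HyperParamSpec:
    """Default hyperparameter table of the constant-volatility baseline.

    Free: μ1,0 (prior N(25·1, I)) and c1 (prior N(ln 0.25, I)) — dξ = 4
    for d1 = 2.  Fixed: σ1 = 0.01 (log-space mean ln 0.01), w1 = 0.06,
    b1 = 0.
    """
    entries = (
        ParamSpecEntry("mu1_0", "identity", 25.0 * np.ones(d1), np.ones(d1), free=True),
        ParamSpecEntry("c1", "log", np.log(0.25) * np.ones(d1), np.ones(d1), free=True),
        ParamSpecEntry("sigma1", "log", np.log(0.01) * np.ones(d1), np.ones(d1), free=False),
        ParamSpecEntry("w1", "log", np.log(0.06) * np.ones(d1), np.zeros(d1), free=False),
        ParamSpecEntry("b1", "identity", np.zeros(d1), np.zeros(d1), free=False),
    )
    return HyperParamSpec(model="ablation", entries=entries, d1=d1)


def objective_V(
    xi: np.ndarray,
    observations: np.ndarray,
    spec: HyperParamSpec,
    config: FilterConfig | None = None,
) -> float:
    """V(ξ): accumulated predictive log-likelihood plus the prior density.

    A diverged filter returns a large negative sentinel so the optimizer
    retreats.
    """
    config = config or FilterConfig()
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    try:
        native = spec.to_native(xi)
    except (ValueError, np.linalg.LinAlgError):
        return _DIVERGED
    if obs.shape[0] == 0:
        return spec.prior_logpdf(xi)
    try:
        if spec.model == "full":
            traj = run_filter(obs, native, config, records=False)
        else:
            traj = run_ablation_filter(obs, native, config)
    except (SPDGuardError, FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("filter diverged during objective evaluation: %s", exc)
        return _DIVERGED
    ll = total_predictive_loglik(traj)
    if not np.isfinite(ll):
        return _DIVERGED
    return ll + spec.prior_logpdf(xi)


@dataclass(frozen=True)
class FitResult:
    """Laplace fit of the free hyperparameters.

    The identity F = V_max + dξ/2·ln(2πe) + ½·ln det Cξ holds exactly by
    construction.
    """

    model: str
    mu_xi: np.ndarray
    C_xi: np.ndarray
    V_max: float
    F: float
    n_iter: int
    n_feval: int
    converged: bool
    seed: int = 0

    @property
    def dxi(self) -> int:
        return self.mu_xi.size


def fd_gradient(f, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference gradient."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (symmetric by construction)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = np.array([rel_step * max(1.0, abs(xi)) for xi in x])
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def negative_free_energy(V_max: float, C_xi: np.ndarray) -> float:
    """F = V_max + dξ/2·ln(2πe) + ½·ln det Cξ (Laplace evidence bound)."""
    C_xi = np.atleast_2d(np.asarray(C_xi, dtype=float))
    sign, logdet = np.linalg.slogdet(C_xi)
    if sign <= 0:
        raise ValueError("C_xi must be positive definite")
    dxi = C_xi.shape[0]
    return float(V_max + 0.5 * dxi * np.log(2.0 * np.pi * np.e) + 0.5 * logdet)


def _spd_floor(M: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Symmetrize and floor eigenvalues so the Laplace covariance is SPD."""
    S = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(S)
    if np.all(w > floor):
        return S
    logger.warning("Laplace covariance floored: min eigenvalue %.3e", w.min())
    return (V * np.maximum(w, floor)) @ V.T


def maximize_objective(
    observations: np.ndarray,
    spec: HyperParamSpec,
    config: FilterConfig | None = None,
    maxiter: int = 60,
    gtol: float = 1e-3,
):
    """BFGS maximization of V(ξ) from the prior mean.

    Returns (μξ, V(μξ), scipy result).  The returned point is never
    worse than the starting prior mean (maximization contract).
    """
    config = config or FilterConfig()
    obs = np.atleast_2d(np.asarray(observations, dtype=float))

    def neg_V(xi: np.ndarray) -> float:
        return -objective_V(xi, obs, spec, config)

    x0 = spec.prior_mean_vector()
    res = minimize(neg_V, x0, method="BFGS", options={"maxiter": maxiter, "gtol": gtol})
    mu_xi = res.x if res.fun <= neg_V(x0) else x0
    return np.asarray(mu_xi, dtype=float), -neg_V(mu_xi), res


def fit(
    observations: np.ndarray,
    spec: HyperParamSpec,
    config: FilterConfig | None = None,
    maxiter: int = 60,
    gtol: float = 1e-3,
    hess_rel_step: float = 1e-4,
    seed: int = 0,
) -> FitResult:
    """Maximize V(ξ) by BFGS from the prior mean; Laplace covariance at μξ.

    The optimizer works on −V with scipy's line-search BFGS and
    finite-difference gradients; the posterior covariance is the inverse
    of the negative central-difference Hessian of V at the optimum,
    floored to SPD.  Non-convergence is reported, not raised.
    """
    config = config or FilterConfig()
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    mu_xi, V_max, res = maximize_objective(obs, spec, config, maxiter=maxiter, gtol=gtol)

    def V_of(xi: np.ndarray) -> float:
        return objective_V(xi, obs, spec, config)

    H = fd_hessian(V_of, mu_xi, rel_step=hess_rel_step)
    C_xi = _spd_floor(np.linalg.inv(_spd_floor(-H)))
    F = negative_free_energy(V_max, C_xi)
    return FitResult(
        model=spec.model,
        mu_xi=np.asarray(mu_xi, dtype=float),
        C_xi=C_xi,
        V_max=V_max,
        F=F,
        n_iter=int(res.nit),
        n_feval=int(res.nfev),
        converged=bool(res.success),
        seed=seed,
    )
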