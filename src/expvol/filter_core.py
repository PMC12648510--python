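"""Trial-by-trial variational update engine for the two-level filter.

The model: observations o_k have independent exponential components with
rate r0 = exp(W1·x1 + b1); the log-rate state x1 diffuses as a Brownian
motion whose diffusion matrix Σ1 = L1·L1ᵀ is itself driven, through the
Cholesky log-space parameterization, by a second Brownian state x2.
Euler discretization with sampling interval ϵ_k gives closed-form
Gaussian belief updates at both levels, each a single Newton step on the
level's variational energy evaluated at the previous posterior mean.

Per trial, in order: one-step-ahead predictions (rate r̂0, volatility
Σ̂1 from μ2 of the previous trial, prediction precisions Π̂1, Π̂2); the
level-1 precision then mean update driven by the precision-weighted
observation prediction error PE0 = 1 − o⊙r̂0; the level-2 precision then
mean update driven by the volatility prediction error Δ1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property, lru_cache

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dtrtri

from .exponential_obs import ObservationCoupling, predict_rate, prediction_error0, predictive_loglik
from .linalg_utils import commutation_matrix, ensure_spd, lvec
from .volatility_param import Lg_jacobian, VolatilityCoupling, volatility_factor

__all__ = [
    "FilterConfig",
    "ModelParams",
    "GaussianBelief",
    "LevelOnePrediction",
    "Level2Intermediates",
    "TrialRecord",
    "default_params",
    "predict_level1",
    "update_level1",
    "update_level2",
    "variational_energy_V1",
    "grad_V1",
    "hess_V1",
    "variational_energy_V2",
    "prediction_correlation",
    "run_filter",
    "total_predictive_loglik",
]


@dataclass(frozen=True)
class FilterConfig:
    """Numerical settings: sampling interval ϵ_k and the SPD-guard scale."""

    epsilon: float = 1.0
    jitter_scale: float = 1e-10

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon (sampling interval) must be positive")


@dataclass(frozen=True)
class ModelParams:
    """All hyperparameters of the hierarchical model, in native space.

    w1, b1: observation coupling (r0 = exp(W1·x1 + b1), W1 = diag(w1)).
    w2, b2: volatility coupling (y2 = W2·x2 + b2, W2 = diag(w2)).
    lam: diagonal of the Cholesky factor of Σ2 (volatility of x2), so
    Σ2 = diag(lam²).
    mu1_0, C1_0, mu2_0, C2_0: Gaussian priors on the initial states.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    lam: np.ndarray
    mu1_0: np.ndarray
    C1_0: np.ndarray
    mu2_0: np.ndarray
    C2_0: np.ndarray

    def __post_init__(self) -> None:
        for name in ("w1", "b1", "w2", "b2", "lam", "mu1_0", "C1_0", "mu2_0", "C2_0"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        d1, d2 = self.w1.size, self.w2.size
        if d2 != d1 * (d1 + 1) // 2:
            raise ValueError("w2 must have length d1(d1+1)/2")
        if self.lam.shape != (d2,) or np.any(self.lam < 0):
            raise ValueError("lam must be a non-negative vector of length d2")
        if self.mu1_0.shape != (d1,) or self.C1_0.shape != (d1, d1):
            raise ValueError("level-1 prior dimension mismatch")
        if self.mu2_0.shape != (d2,) or self.C2_0.shape != (d2, d2):
            raise ValueError("level-2 prior dimension mismatch")

    @property
    def d1(self) -> int:
        return self.w1.size

    @property
    def d2(self) -> int:
        return self.w2.size

    @cached_property
    def obs_coupling(self) -> ObservationCoupling:
        return ObservationCoupling(w1=self.w1, b1=self.b1)

    @cached_property
    def vol_coupling(self) -> VolatilityCoupling:
        return VolatilityCoupling(w2=self.w2, b2=self.b2, d1=self.d1)

    @cached_property
    def Sigma2(self) -> np.ndarray:
        return np.diag(self.lam**2)


def default_params(d1: int = 2) -> ModelParams:
    """Standard hyperparameter values for a d1-dimensional signal.

    Coupling strengths w1 = 0.06·1 and w2 = 0.5·1, zero biases,
    λ = 0.02·1, prior means μ1,0 = 25·1 and μ2,0 = 0 with unit prior
    covariances.  These are the fixed/prior-mean settings of the
    bivariate simulation study.
    """
    d2 = d1 * (d1 + 1) // 2
    return ModelParams(
        w1=np.full(d1, 0.06),
        b1=np.zeros(d1),
        w2=np.full(d2, 0.5),
        b2=np.zeros(d2),
        lam=np.full(d2, 0.02),
        mu1_0=np.full(d1, 25.0),
        C1_0=np.eye(d1),
        mu2_0=np.zeros(d2),
        C2_0=np.eye(d2),
    )


@dataclass(frozen=True)
class GaussianBelief:
    """Gaussian posterior of a hidden level: mean μ, covariance C, precision P."""

    mu: np.ndarray
    C: np.ndarray
    P: np.ndarray

    @classmethod
    def from_moments(cls, mu: np.ndarray, C: np.ndarray, jitter_scale: float = 1e-10) -> "GaussianBelief":
        C_spd, _ = ensure_spd(C, jitter_scale)
        P = _spd_inverse(C_spd, jitter_scale)
        return cls(mu=np.asarray(mu, dtype=float), C=C_spd, P=P)


@dataclass(frozen=True)
class LevelOnePrediction:
    """One-step-ahead quantities entering the level-1 update.

    S_pred = ϵΣ̂1 + C1,k−1 is the prediction covariance; Pi1_hat its
    inverse (the prediction precision Π̂1).
    """

    r_hat: np.ndarray
    L1_hat: np.ndarray
    Sigma1_hat: np.ndarray
    S_pred: np.ndarray
    Pi1_hat: np.ndarray


@dataclass(frozen=True)
class Level2Intermediates:
    PE1: np.ndarray
    Delta1: np.ndarray
    Omega1_hat: np.ndarray
    Lg: np.ndarray
    delta1: np.ndarray
    Pi2_hat: np.ndarray


@dataclass(frozen=True)
class TrialRecord:
    """Everything computed at one trial."""

    k: int
    o: np.ndarray
    prediction: LevelOnePrediction
    PE0: np.ndarray
    belief1: GaussianBelief
    belief2: GaussianBelief | None
    intermediates: Level2Intermediates | None
    rho1: float | np.ndarray | None
    pred_loglik: float
    jitter: float = 0.0


@lru_cache(maxsize=32)
def _eye(d: int) -> np.ndarray:
    I = np.eye(d)
    I.flags.writeable = False
    return I


def _kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Kronecker product for small dense blocks (fast path for np.kron)."""
    m, n = A.shape
    p, q = B.shape
    return (A[:, None, :, None] * B[None, :, None, :]).reshape(m * p, n * q)


def _spd_inverse(M: np.ndarray, jitter_scale: float) -> np.ndarray:
    """Inverse of an SPD matrix via its Cholesky factor, with the
    escalating jitter guard on factorization failure."""
    S = 0.5 * (M + M.T)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        S, _ = ensure_spd(M, jitter_scale)
        L = np.linalg.cholesky(S)
    Li, info = dtrtri(L, lower=1)
    if info != 0:  # pragma: no cover - L has positive diagonal by construction
        return np.linalg.inv(S)
    return Li.T @ Li


def predict_level1(
    belief1_prev: GaussianBelief,
    belief2_prev: GaussianBelief,
    params: ModelParams,
    config: FilterConfig,
) -> LevelOnePrediction:
    """Predictions from the previous trial's posteriors.

    L̂1 is the volatility factor evaluated at μ2,k−1; the prediction
    precision is Π̂1 = (ϵΣ̂1 + C1,k−1)⁻¹.
    """
    vf = volatility_factor(belief2_prev.mu, params.vol_coupling)
    S_pred = config.epsilon * vf.Sigma1 + belief1_prev.C
    Pi1_hat = _spd_inverse(S_pred, config.jitter_scale)
    r_hat = predict_rate(belief1_prev.mu, params.obs_coupling)
    return LevelOnePrediction(
        r_hat=r_hat, L1_hat=vf.L1, Sigma1_hat=vf.Sigma1, S_pred=S_pred, Pi1_hat=Pi1_hat
    )


def update_level1(
    o: np.ndarray,
    belief1_prev: GaussianBelief,
    prediction: LevelOnePrediction,
    params: ModelParams,
    config: FilterConfig,
) -> tuple[GaussianBelief, np.ndarray]:
    """Level-1 Newton step: precision P1 = Π̂1 + W1ᵀdiag(o⊙r̂0)W1, then
    mean μ1,k = μ1,k−1 + C1,k·W1ᵀ·PE0."""
    o = np.asarray(o, dtype=float)
    if np.any(o < 0):
        raise ValueError("observations must be non-negative")
    w1 = params.w1
    P1 = prediction.Pi1_hat + np.diag(w1**2 * o * prediction.r_hat)
    C1 = _spd_inverse(P1, config.jitter_scale)
    PE0 = prediction_error0(o, prediction.r_hat)
    mu1 = belief1_prev.mu + C1 @ (w1 * PE0)
    return GaussianBelief(mu=mu1, C=C1, P=0.5 * (P1 + P1.T)), PE0


def variational_energy_V1(
    x1: np.ndarray,
    o: np.ndarray,
    belief1_prev: GaussianBelief,
    prediction: LevelOnePrediction,
    params: ModelParams,
) -> float:
    """Level-1 variational energy (additive constant dropped):
    1ᵀ(W1x1+b1) − oᵀexp(W1x1+b1) − ½(x1−μ1,k−1)ᵀΠ̂1(x1−μ1,k−1)."""
    x1 = np.asarray(x1, dtype=float)
    eta = params.w1 * x1 + params.b1
    d = x1 - belief1_prev.mu
    return float(np.sum(eta) - np.asarray(o) @ np.exp(eta) - 0.5 * d @ prediction.Pi1_hat @ d)


def grad_V1(x1, o, belief1_prev, prediction, params) -> np.ndarray:
    """Analytic gradient of V1: W1ᵀ[1 − o⊙exp(W1x1+b1)] − Π̂1(x1−μ1,k−1)."""
    x1 = np.asarray(x1, dtype=float)
    r = np.exp(params.w1 * x1 + params.b1)
    return params.w1 * (1.0 - np.asarray(o) * r) - prediction.Pi1_hat @ (x1 - belief1_prev.mu)


def hess_V1(x1, o, belief1_prev, prediction, params) -> np.ndarray:
    """Analytic Hessian of V1: −W1ᵀdiag(o⊙exp(W1x1+b1))W1 − Π̂1."""
    x1 = np.asarray(x1, dtype=float)
    r = np.exp(params.w1 * x1 + params.b1)
    return -np.diag(params.w1**2 * np.asarray(o) * r) - prediction.Pi1_hat


def update_level2(
    belief2_prev: GaussianBelief,
    belief1_prev: GaussianBelief,
    belief1_new: GaussianBelief,
    prediction: LevelOnePrediction,
    params: ModelParams,
    config: FilterConfig,
    _K: np.ndarray | None = None,
) -> tuple[GaussianBelief, Level2Intermediates, float]:
    """Level-2 Newton-style step for the log-volatility state.

    The drive is the exact gradient of the level-2 variational energy at
    μ2,k−1: ϵ·W2ᵀ·L̂g·(Ω̂1⊗I)·vec(Δ1ᵀ), where Δ1 = (C1,k + PE1·PE1ᵀ)·Π̂1 − I
    compares the realized level-1 second moment against the predicted
    one.  The precision update adds the curvature terms (quadratic in ϵ
    for products of first derivatives of the prediction covariance,
    linear in ϵ for its second derivatives).  The result is symmetrized
    and SPD-guarded before inversion.
    """
    eps = config.epsilon
    d1 = params.d1
    Pi1 = prediction.Pi1_hat
    L1h = prediction.L1_hat
    PE1 = belief1_new.mu - belief1_prev.mu
    Delta1 = (belief1_new.C + np.outer(PE1, PE1)) @ Pi1 - _eye(d1)
    Omega = L1h.T @ Pi1
    Lg = Lg_jacobian(belief2_prev.mu, params.vol_coupling)
    Pi2_hat = _spd_inverse(eps * params.Sigma2 + belief2_prev.C, config.jitter_scale)
    K = commutation_matrix(d1, d1) if _K is None else _K

    OmT = Omega.T
    PiD = Pi1 @ Delta1
    braces = (
        eps**2
        * K
        @ (
            _kron(OmT, Omega @ Delta1)
            + _kron(Delta1.T @ OmT, Omega)
            + _kron(OmT, Omega)
        )
        + eps**2
        * (
            _kron(L1h.T @ Delta1.T @ OmT, Pi1)
            + _kron(L1h.T @ OmT, PiD)
            + _kron(L1h.T @ OmT, Pi1)
        )
        - eps * _kron(_eye(d1), PiD)
    )
    delta1 = eps * (Delta1.T @ OmT) * L1h
    w2 = params.w2
    G = Lg @ braces @ Lg.T
    P2 = (
        Pi2_hat
        + w2[:, None] * G * w2[None, :]
        - np.diag(w2**2 * lvec(delta1))
    )
    P2_spd, jit = ensure_spd(P2, config.jitter_scale)
    C2 = _spd_inverse(P2_spd, config.jitter_scale)
    # (Ω̂1 ⊗ I)·vec(Δ1ᵀ) = vec(Δ1ᵀ·Ω̂1ᵀ)
    drive = eps * w2 * (Lg @ (Delta1.T @ OmT).reshape(-1, order="F"))
    mu2 = belief2_prev.mu + C2 @ drive
    belief2 = GaussianBelief(mu=mu2, C=C2, P=P2_spd)
    inter = Level2Intermediates(
        PE1=PE1, Delta1=Delta1, Omega1_hat=Omega, Lg=Lg, delta1=delta1, Pi2_hat=Pi2_hat
    )
    return belief2, inter, jit


def variational_energy_V2(
    x2: np.ndarray,
    belief2_prev: GaussianBelief,
    belief1_prev: GaussianBelief,
    belief1_new: GaussianBelief,
    params: ModelParams,
    config: FilterConfig,
) -> float:
    """Reference level-2 variational energy (additive constant dropped).

    With A(x2) = ϵ·F2(x2)F2(x2)ᵀ + C1,k−1 and M = C1,k + PE1·PE1ᵀ:
    V2 = −½·ln det A − ½·tr(A⁻¹M) − ½·(x2−μ2,k−1)ᵀΠ̂2(x2−μ2,k−1).
    The closed-form level-2 update is its approximate Newton step.
    """
    x2 = np.asarray(x2, dtype=float)
    eps = config.epsilon
    vf = volatility_factor(x2, params.vol_coupling)
    A = eps * vf.Sigma1 + belief1_prev.C
    try:
        c, low = cho_factor(0.5 * (A + A.T), lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - A is SPD by construction
        raise ValueError("prediction covariance A(x2) is not SPD") from exc
    PE1 = belief1_new.mu - belief1_prev.mu
    M = belief1_new.C + np.outer(PE1, PE1)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Pi2_hat = _spd_inverse(eps * params.Sigma2 + belief2_prev.C, config.jitter_scale)
    d = x2 - belief2_prev.mu
    return float(-0.5 * logdet - 0.5 * np.trace(cho_solve((c, low), M)) - 0.5 * d @ Pi2_hat @ d)


def prediction_correlation(prediction: LevelOnePrediction) -> float | np.ndarray:
    """Prediction correlation ρ̂1 from the inverse prediction precision.

    With S = Π̂1⁻¹ = ϵΣ̂1 + C1,k−1, the normalized off-diagonal
    S(i,j)/√(S(i,i)·S(j,j)) estimates the pairwise coupling between
    signal dimensions.  Returns the scalar ρ̂1 for d1 = 2, the full
    correlation matrix otherwise.
    """
    S = prediction.S_pred
    d = np.sqrt(np.diag(S))
    if np.any(d <= 0):
        raise ValueError("prediction covariance must have positive diagonal")
    R = S / np.outer(d, d)
    if S.shape[0] == 2:
        return float(R[0, 1])
    return R


def run_filter(
    observations: np.ndarray,
    params: ModelParams,
    config: FilterConfig | None = None,
    records: bool = True,
) -> list[TrialRecord]:
    """Run the two-level filter over a K×d0 observation matrix.

    Beliefs are initialized from the priors; each trial runs the
    prediction step, the level-1 update and the level-2 update.  With
    ``records=False`` a lightweight pass keeps only the per-trial
    predictive log-likelihood (for hyperparameter fitting).
    """
    config = config or FilterConfig()
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    if obs.shape[1] != params.d1:
        raise ValueError(f"observations must have {params.d1} columns")
    bad = np.argwhere(obs < 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"negative observation at row {r + 1}, column {c + 1}")
    belief1 = GaussianBelief.from_moments(params.mu1_0, params.C1_0, config.jitter_scale)
    belief2 = GaussianBelief.from_moments(params.mu2_0, params.C2_0, config.jitter_scale)
    K = commutation_matrix(params.d1, params.d1)
    out: list[TrialRecord] = []
    for k, o in enumerate(obs, start=1):
        prediction = predict_level1(belief1, belief2, params, config)
        belief1_new, PE0 = update_level1(o, belief1, prediction, params, config)
        belief2_new, inter, jit = update_level2(
            belief2, belief1, belief1_new, prediction, params, config, _K=K
        )
        ll = predictive_loglik(o, prediction.r_hat)
        rho = prediction_correlation(prediction) if params.d1 >= 2 else None
        if records:
            out.append(
                TrialRecord(
                    k=k,
                    o=o.copy(),
                    prediction=prediction,
                    PE0=PE0,
                    belief1=belief1_new,
                    belief2=belief2_new,
                    intermediates=inter,
                    rho1=rho,
                    pred_loglik=ll,
                    jitter=jit,
                )
            )
        else:
            out.append(
                TrialRecord(
                    k=k, o=o, prediction=prediction, PE0=PE0, belief1=belief1_new,
                    belief2=None, intermediates=None, rho1=None, pred_loglik=ll, jitter=jit,
                )
            )
        belief1, belief2 = belief1_new, belief2_new
    return out


def total_predictive_loglik(trajectory: list[TrialRecord]) -> float:
    """Sum of one-step-ahead predictive log-likelihoods over all trials."""
    return float(sum(rec.pred_loglik for rec in trajectory))
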