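"""Constant-volatility baseline: level-1 updates only, fixed diagonal Σ1.

The baseline (Ma) removes the volatility level of the hierarchy: the
log-rate state x1 diffuses with a constant, diagonal Σ1 = diag(σ1), and
each trial runs the same level-1 Newton update as the full model with
Σ̂1 pinned at Σ1.  It is the reference point for the Bayes-factor
comparison that quantifies what the time-varying volatility level buys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exponential_obs import ObservationCoupling
from .filter_core import (
    FilterConfig,
    GaussianBelief,
    LevelOnePrediction,
    TrialRecord,
    _spd_inverse,
    update_level1,
)
from .exponential_obs import predict_rate, predictive_loglik

__all__ = ["AblationParams", "default_ablation_params", "run_ablation_filter"]


@dataclass(frozen=True)
class AblationParams:
    """Hyperparameters of the constant-volatility model.

    sigma1 holds the diagonal of Σ1 (variances of the per-trial log-rate
    diffusion); w1/b1 and the level-1 prior are shared with the full
    model.
    """

    sigma1: np.ndarray
    w1: np.ndarray
    b1: np.ndarray
    mu1_0: np.ndarray
    C1_0: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sigma1", "w1", "b1", "mu1_0", "C1_0"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        d1 = self.w1.size
        if self.sigma1.shape != (d1,) or np.any(self.sigma1 <= 0):
            raise ValueError("sigma1 must be a strictly positive vector of length d1")
        if self.mu1_0.shape != (d1,) or self.C1_0.shape != (d1, d1):
            raise ValueError("prior dimension mismatch")

    @property
    def d1(self) -> int:
        return self.w1.size

    @property
    def obs_coupling(self) -> ObservationCoupling:
        return ObservationCoupling(w1=self.w1, b1=self.b1)


def default_ablation_params(d1: int = 2) -> AblationParams:
    """Standard baseline settings: σ1 = 0.01·1 (variances), w1 = 0.06·1,
    prior mean 25·1 with covariance 0.25·I."""
    return AblationParams(
        sigma1=np.full(d1, 0.01),
        w1=np.full(d1, 0.06),
        b1=np.zeros(d1),
        mu1_0=np.full(d1, 25.0),
        C1_0=0.25 * np.eye(d1),
    )


def run_ablation_filter(
    observations: np.ndarray,
    params: AblationParams,
    config: FilterConfig | None = None,
) -> list[TrialRecord]:
    """Run the constant-volatility filter; records carry no level-2 state."""
    config = config or FilterConfig()
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    if obs.shape[1] != params.d1:
        raise ValueError(f"observations must have {params.d1} columns")
    bad = np.argwhere(obs < 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"negative observation at row {r + 1}, column {c + 1}")
    Sigma1 = np.diag(params.sigma1)
    L1 = np.diag(np.sqrt(params.sigma1))
    # reuse the level-1 machinery of the full model with Σ̂1 = Σ1 fixed
    full_like = _as_model_like(params)
    belief1 = GaussianBelief.from_moments(params.mu1_0, params.C1_0, config.jitter_scale)
    out: list[TrialRecord] = []
    for k, o in enumerate(obs, start=1):
        S_pred = config.epsilon * Sigma1 + belief1.C
        Pi1_hat = _spd_inverse(S_pred, config.jitter_scale)
        prediction = LevelOnePrediction(
            r_hat=predict_rate(belief1.mu, params.obs_coupling),
            L1_hat=L1,
            Sigma1_hat=Sigma1,
            S_pred=S_pred,
            Pi1_hat=Pi1_hat,
        )
        belief1_new, PE0 = update_level1(o, belief1, prediction, full_like, config)
        out.append(
            TrialRecord(
                k=k,
                o=o.copy(),
                prediction=prediction,
                PE0=PE0,
                belief1=belief1_new,
                belief2=None,
                intermediates=None,
                rho1=None,
                pred_loglik=predictive_loglik(o, prediction.r_hat),
            )
        )
        belief1 = belief1_new
    return out


class _W1Only:
    """Minimal parameter view exposing w1, as update_level1 requires."""

    def __init__(self, w1: np.ndarray):
        self.w1 = w1


def _as_model_like(params: AblationParams) -> _W1Only:
    return _W1Only(params.w1)
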