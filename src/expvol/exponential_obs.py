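"""Bottom-level observation model: independent-component exponential
likelihood and the log-space rate mapping r0 = exp(W1·x1 + b1)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ObservationCoupling",
    "exp_logpdf",
    "rate_from_x1",
    "predict_rate",
    "prediction_error0",
    "predictive_loglik",
]


@dataclass(frozen=True)
class ObservationCoupling:
    """Diagonal coupling from the log-rate state x1 to the rate r0.

    r0 = exp(diag(w1)·x1 + b1); w1 strictly positive (coupling
    strength), b1 a shift.  One rate per observed dimension (d0 = d1).
    """

    w1: np.ndarray
    b1: np.ndarray

    def __post_init__(self) -> None:
        w1 = np.asarray(self.w1, dtype=float)
        b1 = np.asarray(self.b1, dtype=float)
        object.__setattr__(self, "w1", w1)
        object.__setattr__(self, "b1", b1)
        if w1.ndim != 1 or b1.shape != w1.shape:
            raise ValueError("w1 and b1 must be vectors of equal length")
        if np.any(w1 <= 0):
            raise ValueError("all components of w1 must be positive")

    @property
    def d1(self) -> int:
        return self.w1.size


def exp_logpdf(x0: np.ndarray, r0: np.ndarray) -> float:
    """Log-density of independent exponential components:
    Σ_i [ln r0(i) − r0(i)·x0(i)].
    """
    x0 = np.asarray(x0, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    if x0.shape != r0.shape:
        raise ValueError("x0 and r0 must have matching shapes")
    if np.any(x0 < 0):
        raise ValueError("exponential observations must be non-negative")
    if np.any(r0 <= 0):
        raise ValueError("rates must be strictly positive")
    return float(np.sum(np.log(r0) - r0 * x0))


def rate_from_x1(x1: np.ndarray, coupling: ObservationCoupling) -> np.ndarray:
    """Elementwise exp(w1(i)·x1(i) + b1(i)); strictly positive."""
    x1 = np.asarray(x1, dtype=float)
    if x1.shape != coupling.w1.shape:
        raise ValueError("x1 dimension mismatch")
    return np.exp(coupling.w1 * x1 + coupling.b1)


def predict_rate(mu1_prev: np.ndarray, coupling: ObservationCoupling) -> np.ndarray:
    """One-step-ahead rate prediction r̂0 from the previous posterior mean."""
    return rate_from_x1(mu1_prev, coupling)


def prediction_error0(o: np.ndarray, r_hat: np.ndarray) -> np.ndarray:
    """Observation-level prediction error PE0 = 1 − o ⊙ r̂0.

    Zero exactly when each observation equals its predicted expectation
    1/r̂0(i); negative when the observation exceeds it.
    """
    o = np.asarray(o, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    if o.shape != r_hat.shape:
        raise ValueError("observation/prediction dimension mismatch")
    return 1.0 - o * r_hat


def predictive_loglik(o: np.ndarray, r_hat: np.ndarray) -> float:
    """One-step-ahead predictive log-likelihood 1ᵀln r̂0 − oᵀr̂0.

    Identical to :func:`exp_logpdf` evaluated at the predicted rate.
    """
    return exp_logpdf(o, r_hat)
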