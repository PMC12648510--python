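"""Cholesky log-space parameterization of the first level's volatility.

The second-level state x2 maps through y2 = W2·x2 + b2 to the entries of
a lower-triangular factor L1: diagonal entries are exp(y2) (kept
positive), off-diagonal entries are 2·sinh(y2) (free sign).  The
diffusion matrix of the log-rate's Brownian motion is then
Σ1 = L1·L1ᵀ, symmetric positive definite by construction.  This module
also provides the Jacobian of vec(L1) with respect to x2 (up to the W2
scaling), needed by the second-level precision and mean updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from functools import lru_cache

from .linalg_utils import IndexedLowerTriangle, lvec_index

__all__ = [
    "VolatilityCoupling",
    "VolatilityFactor",
    "y2_from_x2",
    "L1_from_y2",
    "y2_from_L1",
    "volatility_factor",
    "Lg_jacobian",
    "Y2_CLAMP",
]

# |y2| beyond this signals a diverged filter; exp(30) ~ 1e13 already.
Y2_CLAMP = 30.0


@dataclass(frozen=True)
class VolatilityCoupling:
    """Diagonal coupling y2 = diag(w2)·x2 + b2 from level 2 to level 1.

    w2 (strictly positive, length d2 = d1(d1+1)/2) scales the hidden
    volatility state; b2 shifts it.
    """

    w2: np.ndarray
    b2: np.ndarray
    d1: int

    def __post_init__(self) -> None:
        w2 = np.asarray(self.w2, dtype=float)
        b2 = np.asarray(self.b2, dtype=float)
        object.__setattr__(self, "w2", w2)
        object.__setattr__(self, "b2", b2)
        d2 = self.d1 * (self.d1 + 1) // 2
        if w2.shape != (d2,) or b2.shape != (d2,):
            raise ValueError(f"w2 and b2 must have length d2={d2}")
        if np.any(w2 <= 0):
            raise ValueError("all components of w2 must be positive")

    @property
    def d2(self) -> int:
        return self.d1 * (self.d1 + 1) // 2


@dataclass(frozen=True)
class VolatilityFactor:
    """A realized volatility: y2, its Cholesky factor L1 and Σ1 = L1·L1ᵀ."""

    y2: np.ndarray
    L1: np.ndarray
    Sigma1: np.ndarray


def y2_from_x2(x2: np.ndarray, coupling: VolatilityCoupling) -> np.ndarray:
    """Elementwise w2(i)·x2(i) + b2(i)."""
    x2 = np.asarray(x2, dtype=float)
    if x2.shape != (coupling.d2,):
        raise ValueError(f"x2 must have length d2={coupling.d2}")
    return coupling.w2 * x2 + coupling.b2


def _clamp(y2: np.ndarray) -> np.ndarray:
    return np.clip(y2, -Y2_CLAMP, Y2_CLAMP)


@lru_cache(maxsize=32)
def _tri_structure(d1: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cached index arrays for the lvec ordering of a d1×d1 lower triangle.

    Returns (rows, cols) 0-based in lvec order, the diagonal mask, and
    the column-major vec(L1) position of each lvec entry.
    """
    pos = IndexedLowerTriangle(d1).positions
    rows = np.array([i - 1 for i, _ in pos])
    cols = np.array([j - 1 for _, j in pos])
    diag = rows == cols
    vec_pos = cols * d1 + rows
    return rows, cols, diag, vec_pos


def L1_from_y2(y2: np.ndarray, d1: int) -> np.ndarray:
    """Build the lower-triangular factor from its log-space parameters.

    L1(i,i) = exp(y2 at lvec position of (i,i)); L1(i,j) = 2·sinh(y2 at
    lvec position of (i,j)) for j < i; zeros above the diagonal.
    """
    y2 = _clamp(np.asarray(y2, dtype=float))
    d2 = d1 * (d1 + 1) // 2
    if y2.shape != (d2,):
        raise ValueError(f"y2 must have length d2={d2} for d1={d1}")
    rows, cols, diag, _ = _tri_structure(d1)
    L = np.zeros((d1, d1))
    L[rows, cols] = np.where(diag, np.exp(y2), 2.0 * np.sinh(y2))
    return L


def y2_from_L1(L1: np.ndarray) -> np.ndarray:
    """Inverse of :func:`L1_from_y2`: ln on the diagonal, asinh(·/2) below."""
    L1 = np.asarray(L1, dtype=float)
    d1 = L1.shape[0]
    if L1.ndim != 2 or L1.shape != (d1, d1):
        raise ValueError("L1 must be square")
    if np.any(np.diag(L1) <= 0):
        raise ValueError("diagonal of L1 must be strictly positive")
    rows, cols, diag, _ = _tri_structure(d1)
    v = L1[rows, cols]
    return np.where(diag, np.log(np.where(diag, v, 1.0)), np.arcsinh(v / 2.0))


def volatility_factor(x2: np.ndarray, coupling: VolatilityCoupling) -> VolatilityFactor:
    """Full map x2 → (y2, L1, Σ1)."""
    y2 = y2_from_x2(x2, coupling)
    L1 = L1_from_y2(y2, coupling.d1)
    return VolatilityFactor(y2=y2, L1=L1, Sigma1=L1 @ L1.T)


def Lg_jacobian(mu2_prev: np.ndarray, coupling: VolatilityCoupling) -> np.ndarray:
    """d2×d1² Jacobian structure of x2 ↦ vec(L1), without the W2 factor.

    Row i carries f′(y2(i))·e2(i)ᵀ where f′ is exp for lvec positions on
    the diagonal of L1 and 2·cosh off the diagonal, and e2(i) indicates
    where lvec position i sits inside the column-major vec(L1).  The
    chain rule gives ∂vec(L1)/∂x2 = (W2ᵀ·Lg)ᵀ since y2 = W2·x2 + b2 with
    diagonal W2.
    """
    d1 = coupling.d1
    d2 = coupling.d2
    y2 = _clamp(y2_from_x2(np.asarray(mu2_prev, dtype=float), coupling))
    _, _, diag, vec_pos = _tri_structure(d1)
    Lg = np.zeros((d2, d1 * d1))
    Lg[np.arange(d2), vec_pos] = np.where(diag, np.exp(y2), 2.0 * np.cosh(y2))
    return Lg
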