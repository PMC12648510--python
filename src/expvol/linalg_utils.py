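"""Matrix-calculus primitives for the second-level volatility update.

Small, dense helpers: column-major vectorization (``vec``), lower-triangle
stacking (``lvec``) and its index arithmetic, the commutation matrix
K_mn with K·vec(A) = vec(Aᵀ), and a Cholesky-based positive-definiteness
guard.  Everything here is exact linear algebra on matrices of side at
most a few tens; no sparsity is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IndexedLowerTriangle",
    "vec",
    "lvec",
    "lvec_inverse",
    "lvec_index",
    "commutation_matrix",
    "ensure_spd",
    "SPDGuardError",
]


@dataclass(frozen=True)
class IndexedLowerTriangle:
    """Column-major ordering of the lower triangle of a d1×d1 matrix.

    ``positions`` lists (row, col) pairs, 1-based, sorted by (col, row):
    the order in which :func:`lvec` stacks entries.
    """

    d1: int
    positions: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.d1 < 1:
            raise ValueError("d1 must be a positive integer")
        pos = tuple(
            (i, j) for j in range(1, self.d1 + 1) for i in range(j, self.d1 + 1)
        )
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.d1 * (self.d1 + 1) // 2


def vec(M: np.ndarray) -> np.ndarray:
    """Stack the columns of ``M`` into a single vector (column-major)."""
    M = np.asarray(M)
    if M.ndim == 1:
        return M.copy()
    if M.ndim != 2:
        raise ValueError("vec expects a matrix")
    return M.reshape(-1, order="F").copy()


def lvec(L: np.ndarray) -> np.ndarray:
    """Stack the lower triangle of square ``L`` column by column.

    Returns a vector of length d(d+1)/2.  Entries above the diagonal are
    ignored (they are structurally zero for a lower-triangular matrix).
    """
    L = np.asarray(L)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("lvec expects a square matrix")
    d = L.shape[0]
    return np.concatenate([L[j:, j] for j in range(d)])


def lvec_inverse(v: np.ndarray, d: int | None = None) -> np.ndarray:
    """Rebuild the lower-triangular matrix whose lvec is ``v``."""
    v = np.asarray(v, dtype=float)
    if d is None:
        # d(d+1)/2 = len(v)  =>  d = (sqrt(8n+1)-1)/2
        d = int(round((np.sqrt(8 * v.size + 1) - 1) / 2))
    if d * (d + 1) // 2 != v.size:
        raise ValueError(f"length {v.size} is not a triangular number for d={d}")
    L = np.zeros((d, d))
    k = 0
    for j in range(d):
        n = d - j
        L[j:, j] = v[k : k + n]
        k += n
    return L


def lvec_index(i: int, j: int, d1: int) -> int:
    """1-based position of lower-triangle entry (i, j) in lvec ordering.

    Computed as (2·d1 − j + 2)(j − 1)/2 + i − j + 1 for 1 ≤ j ≤ i ≤ d1.
    """
    if not (1 <= j <= i <= d1):
        raise ValueError(f"(i={i}, j={j}) is not in the lower triangle of d1={d1}")
    return (2 * d1 - j + 2) * (j - 1) // 2 + i - j + 1


def commutation_matrix(m: int, n: int) -> np.ndarray:
    """Dense mn×mn permutation matrix K with K·vec(A) = vec(Aᵀ) for m×n A."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be positive")
    mn = m * n
    K = np.zeros((mn, mn))
    # vec(A)[i + j*m] = A[i, j] must land at vec(A^T)[j + i*n]
    for i in range(m):
        for j in range(n):
            K[j + i * n, i + j * m] = 1.0
    return K


class SPDGuardError(np.linalg.LinAlgError):
    """Raised when jitter escalation cannot restore positive definiteness."""


def ensure_spd(
    M: np.ndarray, jitter_scale: float = 1e-10
) -> tuple[np.ndarray, float]:
    """Symmetrize ``M`` and add the smallest escalating jitter c·I that
    makes a Cholesky factorization succeed.

    Returns ``(spd_matrix, applied_jitter)``.  Escalation multiplies the
    jitter by 10 each attempt; exceeding 1e6·jitter_scale signals a
    diverged filter state and raises :class:`SPDGuardError`.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("ensure_spd expects a square matrix")
    if not np.all(np.isfinite(M)):
        raise SPDGuardError("non-finite entries in matrix passed to SPD guard")
    S = 0.5 * (M + M.T)
    eye = np.eye(S.shape[0])
    try:
        np.linalg.cholesky(S)
        return S, 0.0
    except np.linalg.LinAlgError:
        pass
    c = float(jitter_scale)
    while c <= 1e6 * jitter_scale:
        try:
            np.linalg.cholesky(S + c * eye)
            return S + c * eye, c
        except np.linalg.LinAlgError:
            c *= 10.0
    raise SPDGuardError(
        f"jitter escalation exceeded {1e6 * jitter_scale:g} without reaching SPD"
    )
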