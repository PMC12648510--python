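"""Synthetic data generators.

Two generators drive testing and simulation studies:

* the cosine-rate benchmark — a bivariate exponential series whose rate
  vector follows 3.5 cosine periods over K trials, with the second
  dimension flipping sign mid-series so that the two dimensions move
  synchronously in the first half and anti-synchronously in the second;
* the model's own generative hierarchy — nested Brownian motions
  sampled by Euler–Maruyama through the Cholesky volatility map, for
  parameter-recovery experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exponential_obs import rate_from_x1
from .filter_core import ModelParams
from .volatility_param import L1_from_y2, y2_from_x2

__all__ = [
    "SyntheticDataset",
    "cosine_rate_trajectory",
    "sample_exponential_series",
    "make_benchmark",
    "sample_from_hierarchy",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class SyntheticDataset:
    """Observations plus ground truth for recovery tests.

    true_x1/true_x2 are only populated by the hierarchy sampler.
    """

    observations: np.ndarray
    true_rates: np.ndarray
    seed: int
    generator_tag: str
    true_x1: np.ndarray | None = None
    true_x2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.observations.shape[0] != self.true_rates.shape[0]:
            raise ValueError("observations and true_rates must have equal row counts")
        if np.any(self.observations < 0):
            raise ValueError("observations must be non-negative")
        if np.any(self.true_rates <= 0):
            raise ValueError("true rates must be strictly positive")

    @property
    def K(self) -> int:
        return self.observations.shape[0]


def cosine_rate_trajectory(
    K: int,
    *,
    offset: float = 2.5,
    amplitude: float = 2.0,
    cycles: float = 3.5,
    switch_trial: int = 200,
) -> np.ndarray:
    """Bivariate cosine rate benchmark over trials t_k = k, k = 1..K.

    r0(1)(t_k) = offset + amplitude·cos(2π·cycles·t_k/K) throughout;
    r0(2) equals r0(1) up to ``switch_trial`` and mirrors it
    (offset − amplitude·cos) afterwards.  Defaults trace the standard
    benchmark: rates in [0.5, 4.5], 3.5 periods over K = 400, switch
    after trial 200.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    t = np.arange(1, K + 1, dtype=float)
    wave = amplitude * np.cos(2.0 * np.pi * cycles * t / K)
    r1 = offset + wave
    r2 = np.where(t <= switch_trial, offset + wave, offset - wave)
    return np.column_stack([r1, r2])


def sample_exponential_series(rates: np.ndarray, seed: int) -> np.ndarray:
    """Independent exponential draws o_k(i) ~ Exp(rate = rates(k,i))."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be strictly positive")
    rng = np.random.default_rng(seed)
    return rng.exponential(scale=1.0 / rates)


def make_benchmark(K: int = 400, seed: int = 0, **kwargs) -> SyntheticDataset:
    """Cosine-rate benchmark dataset: rates plus exponential draws."""
    rates = cosine_rate_trajectory(K, **kwargs)
    obs = sample_exponential_series(rates, seed)
    return SyntheticDataset(
        observations=obs, true_rates=rates, seed=seed, generator_tag="benchmark"
    )


def sample_from_hierarchy(
    params: ModelParams, K: int, seed: int, epsilon: float = 1.0
) -> SyntheticDataset:
    """Euler–Maruyama sample from the full generative hierarchy.

    Per step: x2 diffuses with per-step std √ϵ·λ; the volatility factor
    L1 is evaluated at the pre-step x2 (volatility frozen within a
    step); x1 diffuses with covariance ϵ·L1·L1ᵀ; the rate is
    exp(W1·x1 + b1) and the observation an exponential draw at that
    rate.  Initial states are drawn from the priors.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    rng = np.random.default_rng(seed)
    d1, d2 = params.d1, params.d2
    sqrt_eps = np.sqrt(epsilon)
    x2 = rng.multivariate_normal(params.mu2_0, params.C2_0)
    x1 = rng.multivariate_normal(params.mu1_0, params.C1_0)
    X1 = np.empty((K, d1))
    X2 = np.empty((K, d2))
    R = np.empty((K, d1))
    O = np.empty((K, d1))
    for k in range(K):
        L1 = L1_from_y2(y2_from_x2(x2, params.vol_coupling), d1)
        x1 = x1 + sqrt_eps * (L1 @ rng.standard_normal(d1))
        x2 = x2 + sqrt_eps * (params.lam * rng.standard_normal(d2))
        r = rate_from_x1(x1, params.obs_coupling)
        X1[k], X2[k], R[k] = x1, x2, r
        O[k] = rng.exponential(scale=1.0 / r)
    return SyntheticDataset(
        observations=O,
        true_rates=R,
        seed=seed,
        generator_tag="hierarchy",
        true_x1=X1,
        true_x2=X2,
    )


def write_dataset(ds: SyntheticDataset, csv_path: str | Path) -> None:
    """Write observations + ground truth as CSV with a JSON sidecar."""
    csv_path = Path(csv_path)
    d0 = ds.observations.shape[1]
    cols = {"trial": np.arange(1, ds.K + 1)}
    for i in range(d0):
        cols[f"o{i + 1}"] = ds.observations[:, i]
    for i in range(d0):
        cols[f"r{i + 1}"] = ds.true_rates[:, i]
    if ds.true_x1 is not None:
        for i in range(ds.true_x1.shape[1]):
            cols[f"x1_{i + 1}"] = ds.true_x1[:, i]
    if ds.true_x2 is not None:
        for i in range(ds.true_x2.shape[1]):
            cols[f"x2_{i + 1}"] = ds.true_x2[:, i]
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"seed": ds.seed, "generator_tag": ds.generator_tag, "K": ds.K}, indent=2)
    )


def read_dataset(csv_path: str | Path) -> SyntheticDataset:
    """Round-trip reader for :func:`write_dataset` output."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    o_cols = sorted(c for c in df.columns if c.startswith("o") and c[1:].isdigit())
    r_cols = sorted(c for c in df.columns if c.startswith("r") and c[1:].isdigit())
    x1_cols = sorted(c for c in df.columns if c.startswith("x1_"))
    x2_cols = sorted(c for c in df.columns if c.startswith("x2_"))
    meta = {"seed": -1, "generator_tag": "unknown"}
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return SyntheticDataset(
        observations=df[o_cols].to_numpy(),
        true_rates=df[r_cols].to_numpy(),
        seed=int(meta["seed"]),
        generator_tag=str(meta["generator_tag"]),
        true_x1=df[x1_cols].to_numpy() if x1_cols else None,
        true_x2=df[x2_cols].to_numpy() if x2_cols else None,
    )
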