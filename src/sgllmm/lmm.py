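"""Null linear mixed model: profile likelihood in the variance ratio delta.

Model: y = X beta + y_pop + phi with y_pop ~ N(0, sigma_g^2 K) and
phi ~ N(0, sigma_e^2 I).  With beta fixed at zero, y ~ N(0, sigma_g^2 (K + delta I))
where delta = sigma_e^2 / sigma_g^2.  Profiling out sigma_g^2 leaves a
one-dimensional objective in delta,

    f(delta) = sum_i log(S_i + delta) + m * log( (1/m) sum_i (U^T y)_i^2 / (S_i + delta) ),

the negated log-likelihood up to an additive constant that is dropped
throughout (log-likelihoods are therefore only comparable within a dataset).
The fitted delta defines the whitening rotation S_delta U^T with
(S_delta)_ii = (S_i + delta)^(-1/2), which turns generalized least squares
into ordinary least squares on rotated data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize

from .kinship import KinshipEigen

__all__ = [
    "NullModel",
    "RotatedData",
    "profile_negloglik",
    "estimate_sigma_g2",
    "estimate_delta",
    "rotate_data",
]

LN_DELTA_RANGE = (-10.0, 10.0)
FLAT_TOL = 1e-6


@dataclass
class NullModel:
    """Variance components estimated with the SNP effects fixed at zero."""

    delta: float
    sigma_g2: float
    loglik: float
    flat_likelihood: bool = False
    m: int = 0

    def __post_init__(self) -> None:
        if not (self.delta > 0 and self.sigma_g2 > 0 and np.isfinite(self.loglik)):
            raise ValueError("invalid null model parameters")

    @property
    def sigma_e2(self) -> float:
        return self.delta * self.sigma_g2

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in [
                ("delta", self.delta),
                ("sigma_g2", self.sigma_g2),
                ("loglik", self.loglik),
                ("flat_likelihood", int(self.flat_likelihood)),
                ("m", self.m),
            ]:
                fh.write(f"{k}\t{v}\n")

    @classmethod
    def load(cls, path: str | Path) -> "NullModel":
        kv = {}
        with open(path) as fh:
            for line in fh:
                k, v = line.rstrip("\n").split("\t")
                kv[k] = v
        return cls(
            delta=float(kv["delta"]),
            sigma_g2=float(kv["sigma_g2"]),
            loglik=float(kv["loglik"]),
            flat_likelihood=bool(int(kv["flat_likelihood"])),
            m=int(kv.get("m", 0)),
        )


@dataclass
class RotatedData:
    """Whitened response and design: y_tilde = S_delta U^T y etc."""

    y_tilde: np.ndarray
    X_tilde: np.ndarray
    delta_used: float


def profile_negloglik(delta: float, S: np.ndarray, Uty: np.ndarray) -> float:
    """Negated profile log-likelihood (constant dropped); smaller is better."""
    S = np.asarray(S, dtype=float)
    Uty = np.asarray(Uty, dtype=float)
    d = S + delta
    if delta <= 0 or np.any(d <= 0):
        raise ValueError("delta must keep all S_i + delta positive")
    m = len(S)
    quad = float(np.sum(Uty**2 / d)) / m
    if quad <= 0:
        raise ValueError("degenerate likelihood: y is identically zero")
    return float(np.sum(np.log(d)) + m * np.log(quad))


def estimate_sigma_g2(delta: float, S: np.ndarray, Uty: np.ndarray) -> float:
    """Profile-maximizing genetic variance (1/m) sum (U^T y)_i^2 / (S_i + delta)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    S = np.asarray(S, dtype=float)
    Uty = np.asarray(Uty, dtype=float)
    return float(np.sum(Uty**2 / (S + delta)) / len(S))


def estimate_delta(
    ke: KinshipEigen,
    y: np.ndarray,
    grid_size: int = 100,
) -> NullModel:
    """Grid-then-refine minimization of the delta profile on ln delta in [-10, 10].

    The profile is evaluated on a log-spaced grid, then refined by bounded
    scalar minimization inside the bracketing grid cell.  A profile whose
    range over the grid is below 1e-6 is flagged flat (K indistinguishable
    from I at this sample size) and delta is set to 1 by convention.
    """
    y = np.asarray(y, dtype=float).ravel()
    m = ke.n_samples
    if len(y) != m:
        raise ValueError("phenotype length does not match kinship dimension")
    if m < 10:
        import warnings

        warnings.warn("fewer than 10 samples: delta estimate will be unstable")
    Uty = ke.U.T @ y
    ln_grid = np.linspace(*LN_DELTA_RANGE, grid_size)
    vals = np.empty(grid_size)
    for i, ln_d in enumerate(ln_grid):
        vals[i] = profile_negloglik(np.exp(ln_d), ke.S, Uty)
        if not np.isfinite(vals[i]):
            raise ValueError(f"non-finite profile objective at delta={np.exp(ln_d):.3e}")

    if vals.max() - vals.min() < FLAT_TOL:
        delta = 1.0
        return NullModel(
            delta=delta,
            sigma_g2=estimate_sigma_g2(delta, ke.S, Uty),
            loglik=-0.5 * profile_negloglik(delta, ke.S, Uty),
            flat_likelihood=True,
            m=m,
        )

    i = int(np.argmin(vals))
    lo = ln_grid[max(i - 1, 0)]
    hi = ln_grid[min(i + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda ln_d: profile_negloglik(np.exp(ln_d), ke.S, Uty),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    # refinement never loses to the grid incumbent
    if res.fun <= vals[i]:
        delta = float(np.exp(res.x))
        best = float(res.fun)
    else:
        delta = float(np.exp(ln_grid[i]))
        best = float(vals[i])
    return NullModel(
        delta=delta,
        sigma_g2=estimate_sigma_g2(delta, ke.S, Uty),
        loglik=-0.5 * best,
        flat_likelihood=False,
        m=m,
    )


def rotate_data(
    ke: KinshipEigen,
    nm: NullModel,
    y: np.ndarray,
    X: np.ndarray,
) -> RotatedData:
    """Whiten y and X by S_delta U^T so that GLS under K + delta I becomes OLS.

    For any beta, ||y_tilde - X_tilde beta||^2 = (y - X beta)^T (K + delta I)^{-1} (y - X beta).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    m = ke.n_samples
    if len(y) != m or X.shape[0] != m:
        raise ValueError("y/X rows must match the kinship dimension")
    s_delta = 1.0 / np.sqrt(ke.S + nm.delta)
    Ut = ke.U.T
    return RotatedData(
        y_tilde=s_delta * (Ut @ y),
        X_tilde=s_delta[:, None] * (Ut @ X),
        delta_used=nm.delta,
    )
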