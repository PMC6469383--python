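"""Realized relationship matrix (RRM) construction and eigendecomposition.

The RRM K = Z Z^T / p of column-standardized genotypes Z is the covariance of
the random polygenic/population effect in the mixed model.  Its spectral
decomposition K = U diag(S) U^T is what makes the variance-ratio profile
likelihood and the data rotation cheap downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

from .io import GenotypeData

__all__ = [
    "StandardizationStats",
    "KinshipEigen",
    "standardize_genotypes",
    "apply_standardization",
    "compute_rrm",
    "eigendecompose",
    "kinship_from_genotypes",
]


@dataclass
class StandardizationStats:
    """Per-SNP centering/scaling learned on training data.

    ``kept`` indexes the non-constant columns that survive standardization;
    means and scales are stored for those columns only, so the identical
    transform can be replayed on held-out samples.
    """

    means: np.ndarray
    scales: np.ndarray
    kept: np.ndarray
    unit_variance: bool


def standardize_genotypes(
    g: GenotypeData | np.ndarray,
    unit_variance: bool = True,
) -> tuple[np.ndarray, StandardizationStats]:
    """Mean-impute missing dosages per SNP, then center (and scale) columns.

    Scaling uses the sample standard deviation (denominator m - 1), the
    FaST-LMM convention for RRM input; ``unit_variance=False`` centers only.
    Constant columns carry no relatedness information and are dropped with a
    warning.
    """
    X = g.dosages if isinstance(g, GenotypeData) else np.asarray(g, dtype=float)
    X = X.copy()
    if X.shape[1] < 1:
        raise ValueError("need at least one SNP")
    means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = means[nan_c]
    sd = X.std(axis=0, ddof=1)
    kept = np.where(sd > 0)[0]
    if kept.size == 0:
        raise ValueError("all genotype columns are constant")
    if kept.size < X.shape[1]:
        warnings.warn(f"dropped {X.shape[1] - kept.size} constant genotype columns")
    X = X[:, kept] - means[kept]
    scales = sd[kept] if unit_variance else np.ones(kept.size)
    if unit_variance:
        X /= scales
    return X, StandardizationStats(means[kept], scales, kept, unit_variance)


def apply_standardization(
    g: GenotypeData | np.ndarray, stats: StandardizationStats
) -> np.ndarray:
    """Apply training-set imputation/centering/scaling to new samples."""
    X = g.dosages if isinstance(g, GenotypeData) else np.asarray(g, dtype=float)
    X = X[:, stats.kept].copy()
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = stats.means[nan_c]
    X -= stats.means
    X /= stats.scales
    return X


def compute_rrm(Z: np.ndarray) -> np.ndarray:
    """K = Z Z^T / p for a column-standardized matrix Z (m x p)."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] == 0:
        raise ValueError("Z must be m x p with p >= 1")
    K = Z @ Z.T / Z.shape[1]
    return (K + K.T) / 2  # kill round-off asymmetry


@dataclass
class KinshipEigen:
    """K together with its full spectral decomposition K = U diag(S) U^T."""

    K: np.ndarray
    U: np.ndarray
    S: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.K.shape[0]

    def rank(self, tol: float = 1e-8) -> int:
        return int(np.sum(self.S > tol))

    def save(self, prefix: str | Path, sample_ids: list[str] | None = None) -> None:
        """K as TSV; U, S in a documented binary sidecar (m, S, U column-major)."""
        prefix = Path(prefix)
        import pandas as pd

        ids = sample_ids or [f"s{i}" for i in range(self.n_samples)]
        pd.DataFrame(self.K, index=ids, columns=ids).to_csv(
            prefix.with_suffix(".kinship.tsv"), sep="\t", index_label="sample_id"
        )
        with open(prefix.with_suffix(".eigen.bin"), "wb") as fh:
            np.array([self.n_samples], dtype=np.int64).tofile(fh)
            self.S.astype(np.float64).tofile(fh)
            np.asfortranarray(self.U, dtype=np.float64).T.tofile(fh)

    @classmethod
    def load(cls, prefix: str | Path) -> "KinshipEigen":
        prefix = Path(prefix)
        import pandas as pd

        K = pd.read_csv(prefix.with_suffix(".kinship.tsv"), sep="\t", index_col=0).to_numpy()
        with open(prefix.with_suffix(".eigen.bin"), "rb") as fh:
            m = int(np.fromfile(fh, dtype=np.int64, count=1)[0])
            S = np.fromfile(fh, dtype=np.float64, count=m)
            U = np.fromfile(fh, dtype=np.float64, count=m * m).reshape(m, m, order="F")
        return cls(K, U, S)


def eigendecompose(K: np.ndarray, sym_tol: float = 1e-8) -> KinshipEigen:
    """Full eigendecomposition of a symmetric PSD kinship matrix.

    Eigenvalues are returned in descending order; tiny negative round-off
    values (within -1e-8 * trace/m) are clamped to zero, genuinely negative
    ones raise.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if np.max(np.abs(K - K.T)) > sym_tol * max(1.0, np.max(np.abs(K))):
        raise ValueError("K is not symmetric within tolerance")
    S, U = linalg.eigh((K + K.T) / 2)
    m = K.shape[0]
    neg_tol = 1e-8 * max(np.trace(K) / m, 1.0)
    if S.min() < -neg_tol:
        raise ValueError(f"K has a negative eigenvalue {S.min():.3e} beyond round-off")
    S = np.clip(S, 0.0, None)
    order = np.argsort(S)[::-1]
    return KinshipEigen(K=K, U=U[:, order], S=S[order])


def kinship_from_genotypes(
    g: GenotypeData | np.ndarray,
    marker_subset: np.ndarray | None = None,
    unit_variance: bool = True,
) -> tuple[KinshipEigen, StandardizationStats]:
    """Standardize (optionally a marker subset of) the panel, build K, decompose."""
    if marker_subset is not None:
        g = g.subset_snps(marker_subset) if isinstance(g, GenotypeData) else g[:, marker_subset]
    Z, stats = standardize_genotypes(g, unit_variance=unit_variance)
    return eigendecompose(compute_rrm(Z)), stats
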