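"""Phenotype prediction for new samples (genomic BLUP with fixed SNP effects).

Under the mixed model, the best predictor for unobserved samples with
genotypes X' combines their fixed effect X'b with the conditional mean of the
random effect given the training residuals:

    y'_hat = X' b + K_{X'X} (K_{XX} + delta I)^{-1} (y - X b)

where the kinship blocks are built from genotypes standardized with the
*training* per-SNP means and scales (no leakage) and divided by the same
number of markers as the training K.  The phenotype mean removed before the
null fit is restored here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .io import GenotypeData
from .kinship import StandardizationStats, apply_standardization

__all__ = ["PredictionInput", "predict_phenotype"]


@dataclass
class PredictionInput:
    """Everything needed to predict held-out phenotypes on the training panel."""

    X_train: np.ndarray | GenotypeData
    y_train: np.ndarray
    X_test: np.ndarray | GenotypeData
    beta_hat: np.ndarray
    delta_hat: float
    stats: StandardizationStats
    y_mean: float = 0.0

    def __post_init__(self) -> None:
        tr = self.X_train.dosages if isinstance(self.X_train, GenotypeData) else self.X_train
        te = self.X_test.dosages if isinstance(self.X_test, GenotypeData) else self.X_test
        if tr.shape[1] != te.shape[1]:
            raise ValueError("test SNP panel must match the training panel")
        if isinstance(self.X_train, GenotypeData) and isinstance(self.X_test, GenotypeData):
            if self.X_train.snp_ids != self.X_test.snp_ids:
                raise ValueError("test SNP ids/order must match the training panel")


def predict_phenotype(pi: PredictionInput) -> np.ndarray:
    """Mixed-model prediction X'b + K_{X'X}(K_{XX}+delta I)^{-1}(y - X b) + mean.

    ``beta_hat`` applies to standardized genotypes (the scale on which the
    model was fit).  The linear system is solved, never inverted explicitly.
    """
    if pi.delta_hat <= 0:
        raise ValueError("delta must be positive for a well-posed prediction")
    Z_tr = apply_standardization(pi.X_train, pi.stats)
    Z_te = apply_standardization(pi.X_test, pi.stats)
    p = Z_tr.shape[1]
    K_xx = Z_tr @ Z_tr.T / p
    K_cross = Z_te @ Z_tr.T / p
    y_c = np.asarray(pi.y_train, dtype=float) - pi.y_mean
    resid = y_c - Z_tr @ pi.beta_hat
    A = K_xx + pi.delta_hat * np.eye(K_xx.shape[0])
    w = linalg.solve(A, resid, assume_a="pos")
    return Z_te @ pi.beta_hat + K_cross @ w + pi.y_mean
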