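"""Independent reference implementations used only to check the package.

These deliberately share no code path with the package solvers: the SGL
oracle is a plain (unaccelerated) full-vector proximal gradient with a tiny
fixed step run for many iterations, and the plain-lasso reference is
scikit-learn's coordinate descent.
"""

from __future__ import annotations

import numpy as np


def sgl_objective_reference(X, y, members, weights, alpha, lam, beta):
    """Term-by-term SGL objective with 1/(2n) loss scaling."""
    n = X.shape[0]
    r = y - X @ beta
    val = float(r @ r) / (2 * n)
    for w, idx in zip(weights, members):
        val += lam * (1 - alpha) * w * float(np.sqrt(np.sum(beta[idx] ** 2)))
    val += lam * alpha * float(np.sum(np.abs(beta)))
    return val


def ista_sgl(X, y, members, weights, alpha, lam, n_iter=200_000, tol=1e-12):
    """Full-vector ISTA on the SGL objective, run to high precision.

    The prox of the separable penalty is exact per group: soft-threshold for
    the L1 part, then group-norm shrinkage.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    L = np.linalg.norm(X, 2) ** 2 / n  # Lipschitz constant of the 1/(2n) loss
    step = 1.0 / L
    beta = np.zeros(p)
    for _ in range(n_iter):
        grad = -(X.T @ (y - X @ beta)) / n
        z = beta - step * grad
        new = np.empty_like(z)
        for w, idx in zip(weights, members):
            v = np.sign(z[idx]) * np.maximum(np.abs(z[idx]) - step * lam * alpha, 0.0)
            nv = np.sqrt(np.sum(v**2))
            t2 = step * lam * (1 - alpha) * w
            new[idx] = 0.0 if nv <= t2 else (1 - t2 / nv) * v
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise ROC-AUC: P(score_pos > score_neg) + 0.5 P(equal)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pr_points_by_enumeration(scores, labels):
    """(precision, recall) at every distinct threshold, by direct counting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pts = []
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & labels))
        fp = int(np.sum(pred & ~labels))
        fn = int(np.sum(~pred & labels))
        pts.append((tp / (tp + fp), tp / (tp + fn)))
    return pts
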