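"""Lambda selection by cross-validation and SNP ranking by stability selection.

The regularization strength is chosen by 5-fold cross-validation maximizing
held-out explained variance along the lambda path.  SNP importance is then
measured by stability selection: the chosen lambda plus 9 larger path values
are refit on 100 random half-samples, and a SNP's score is the fraction of
resamples in which it entered the model (nonzero at any of the 10 lambdas);
SNPs with frequency >= 50% form the selected set.

Cross-validation and resampling operate on the rotated rows using the
full-data variance ratio and eigenvectors (the rotation is computed once);
``strict_refit`` callers can re-rotate per subset for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sgl import LambdaPath, SGLFit, SGLProblem, fit_sgl

__all__ = [
    "CVResult",
    "StabilityResult",
    "cv_select_lambda",
    "pick_stability_lambdas",
    "stability_select",
]


@dataclass
class CVResult:
    lambdas: np.ndarray
    mean_explained_variance: np.ndarray
    sd_explained_variance: np.ndarray
    best_lambda: float
    best_index: int
    k_folds: int
    seed: int

    def __post_init__(self) -> None:
        if self.best_lambda not in self.lambdas:
            raise ValueError("best_lambda must be one of the path values")


@dataclass
class StabilityResult:
    snp_ids: list[str]
    frequencies: np.ndarray
    selected: list[str]
    ranking: np.ndarray  # SNP indices, most stable first
    lambdas_used: np.ndarray
    n_resamples: int
    threshold: float
    seed: int
    n_flagged_fits: int = 0

    def selected_mask(self) -> np.ndarray:
        return self.frequencies >= self.threshold

    def to_frame(self, groups=None, beta_best=None):
        import pandas as pd

        df = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "frequency": self.frequencies,
                "selected": self.selected_mask().astype(int),
            }
        )
        if groups is not None:
            df.insert(1, "group_id", [groups.group_ids[a] for a in groups.assignments])
        if beta_best is not None:
            df["beta_at_best_lambda"] = beta_best
        return df


def _subproblem(
    problem: SGLProblem, rows: np.ndarray, use_gram: bool | None = None
) -> SGLProblem:
    return SGLProblem(
        X=problem.X[rows],
        y=problem.y[rows],
        groups=problem.groups,
        alpha=problem.alpha,
        group_weights=problem.group_weights,
        scale_loss=problem.scale_loss,
        use_gram=use_gram,
    )


def _warm_path(problem: SGLProblem, lambdas: np.ndarray, **fit_kw) -> list[SGLFit]:
    fits = []
    beta = np.zeros(problem.p)
    for lam in lambdas:
        fit = fit_sgl(problem, lam, beta_init=beta, **fit_kw)
        fits.append(fit)
        beta = fit.beta
    return fits


def cv_select_lambda(
    problem: SGLProblem,
    path: LambdaPath,
    k_folds: int = 5,
    seed: int = 0,
    **fit_kw,
) -> CVResult:
    """Pick the path lambda maximizing mean held-out explained variance.

    Rows are shuffled once (seeded) into k folds of near-equal size; the path
    is refit warm-started on each training split and scored on the held-out
    rows by 1 - ||y_te - X_te b||^2 / ||y_te - mean(y_te)||^2.
    """
    n = problem.n
    if n < 2 * k_folds:
        raise ValueError("need at least 2 samples per fold")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)
    ev = np.full((k_folds, len(path.lambdas)), np.nan)
    for f, test_rows in enumerate(folds):
        train_rows = np.setdiff1d(perm, test_rows, assume_unique=True)
        sub = _subproblem(problem, train_rows)
        fits = _warm_path(sub, path.lambdas, **fit_kw)
        y_te = problem.y[test_rows]
        denom = float(np.sum((y_te - y_te.mean()) ** 2))
        if denom == 0.0:
            warnings.warn(f"fold {f}: held-out response has zero variance; skipped")
            continue
        X_te = problem.X[test_rows]
        for i, fit in enumerate(fits):
            resid = y_te - X_te @ fit.beta
            ev[f, i] = 1.0 - float(resid @ resid) / denom
    if np.isnan(ev).all():
        raise ValueError("every fold was degenerate")
    mean_ev = np.nanmean(ev, axis=0)
    sd_ev = np.nanstd(ev, axis=0, ddof=0)
    best = int(np.argmax(mean_ev))
    return CVResult(
        lambdas=path.lambdas,
        mean_explained_variance=mean_ev,
        sd_explained_variance=sd_ev,
        best_lambda=float(path.lambdas[best]),
        best_index=best,
        k_folds=k_folds,
        seed=seed,
    )


def pick_stability_lambdas(
    path: LambdaPath, best_lambda: float, n_extra: int = 9
) -> np.ndarray:
    """best_lambda plus ``n_extra`` larger path values at evenly spaced indices.

    Spacing is on path index (equivalently log-lambda, the path being
    geometric), between the point after lambda_max and the chosen lambda.
    Returned strictly decreasing, best_lambda last.
    """
    lambdas = np.asarray(path.lambdas)
    matches = np.where(np.isclose(lambdas, best_lambda, rtol=1e-12))[0]
    if matches.size == 0:
        raise ValueError("best_lambda is not on the path")
    b = int(matches[0])
    if b == 0:
        raise ValueError("best lambda is lambda_max: the path is uninformative")
    if b - 1 < n_extra:
        warnings.warn(
            f"only {b - 1} path values larger than best_lambda (excluding "
            f"lambda_max); using all of them"
        )
        extra = np.arange(1, b)
    else:
        extra = np.round(np.arange(1, n_extra + 1) * b / (n_extra + 1)).astype(int)
        extra = np.unique(np.clip(extra, 1, b - 1))
    idx = np.unique(np.r_[extra, b])
    return lambdas[idx]  # descending because the path is


def stability_select(
    problem: SGLProblem,
    lambdas: np.ndarray,
    n_resamples: int = 100,
    sample_frac: float = 0.5,
    threshold: float = 0.5,
    seed: int = 0,
    snp_ids: list[str] | None = None,
    beta_best: np.ndarray | None = None,
    **fit_kw,
) -> StabilityResult:
    """Half-sample stability selection over a set of lambdas.

    Per resample, floor(n * sample_frac) rows are drawn without replacement
    and the SGL is fit at every lambda (descending, warm-started); a SNP
    counts as selected in that resample iff its coefficient is nonzero at any
    of the lambdas.  The selected set is {j : freq_j >= threshold} (the
    boundary is inclusive).  Ranking is by frequency, ties broken by |beta|
    at the best lambda on the full data (when supplied), then by SNP index.
    """
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    if lambdas.size == 0:
        raise ValueError("need at least one lambda")
    if sample_frac > 0.5:
        raise ValueError("stability selection draws no more than half the samples")
    n, p = problem.X.shape
    n_draw = int(np.floor(n * sample_frac))
    counts = np.zeros(p)
    n_flagged = 0
    children = np.random.SeedSequence(seed).spawn(n_resamples)
    for ss in children:
        rng = np.random.default_rng(ss)
        rows = rng.choice(n, size=n_draw, replace=False)
        # few sparse fits per resample: residual updates beat a fresh Gram build
        sub = _subproblem(problem, rows, use_gram=False)
        ever = np.zeros(p, dtype=bool)
        beta = np.zeros(p)
        for lam in lambdas:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_sgl(sub, lam, beta_init=beta, **fit_kw)
            if not fit.converged:
                # one retry with a larger iteration budget, then keep the flag
                kw = dict(fit_kw)
                kw["max_iter"] = 4 * kw.get("max_iter", 10_000)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_sgl(sub, lam, beta_init=fit.beta, **kw)
                if not fit.converged:
                    n_flagged += 1
            ever |= fit.beta != 0.0
            beta = fit.beta
        counts += ever
    freq = counts / n_resamples
    if n_flagged:
        warnings.warn(f"{n_flagged} stability fits remained non-converged (counted as-is)")
    ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(p)]
    tie = np.abs(beta_best) if beta_best is not None else np.zeros(p)
    ranking = np.lexsort((np.arange(p), -tie, -freq))
    selected = [ids[j] for j in range(p) if freq[j] >= threshold]
    return StabilityResult(
        snp_ids=list(ids),
        frequencies=freq,
        selected=selected,
        ranking=ranking,
        lambdas_used=lambdas,
        n_resamples=n_resamples,
        threshold=threshold,
        seed=seed,
        n_flagged_fits=n_flagged,
    )
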