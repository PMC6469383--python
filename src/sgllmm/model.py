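"""Model / Results layer tying the pipeline together.

``SGLLMM`` is constructed from a phenotype, a genotype panel and a group
structure; construction standardizes the genotypes, builds and decomposes the
kinship matrix, estimates the null-model variance ratio delta, and whitens
the data.  ``fit()`` runs the sparse-group-lasso path on the rotated data,
chooses lambda by cross-validation (unless one is given) and returns an
``SGLLMMResults`` carrying estimates, diagnostics, ``summary()``,
``predict()`` and ``stability_selection()``.

Baselines are configurations of the same object: ``alpha=1`` is the lasso,
``rotate=False`` drops the mixed-model correction (identity rotation), so
lasso / SGL / lasso-LMM / SGL-LMM share one code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg

from .io import GenotypeData, GroupStructure, PhenotypeVector
from .kinship import (
    KinshipEigen,
    StandardizationStats,
    compute_rrm,
    eigendecompose,
    standardize_genotypes,
)
from .lmm import NullModel, RotatedData, estimate_delta, rotate_data
from .prediction import PredictionInput, predict_phenotype
from .selection import (
    CVResult,
    StabilityResult,
    cv_select_lambda,
    pick_stability_lambdas,
    stability_select,
)
from .sgl import LambdaPath, SGLProblem, fit_path, fit_sgl

__all__ = ["SGLLMM", "SGLLMMResults"]


class SGLLMM:
    """Sparse-group-lasso linear mixed model for multi-locus association.

    Parameters
    ----------
    phenotype : PhenotypeVector or 1-d array
        Quantitative trait.  Mean-centered internally; the mean is restored
        at prediction time.
    genotypes : GenotypeData or (m, p) array
        Allele dosages; missing entries are mean-imputed per SNP during
        standardization.
    groups : GroupStructure
        Non-overlapping SNP-to-gene grouping.
    alpha : float
        L1/L2 mixing weight of the penalty (1 = lasso, 0 = group lasso).
    rotate : bool
        Apply the mixed-model whitening (False = identity rotation, i.e. the
        plain penalized regression baselines).
    kinship_markers : array of SNP indices, optional
        Marker subset used to build K (default: all columns).
    unit_variance, group_weights, scale_loss
        Standardization and penalty conventions, see the kinship and sgl
        modules.
    """

    def __init__(
        self,
        phenotype: PhenotypeVector | np.ndarray,
        genotypes: GenotypeData | np.ndarray,
        groups: GroupStructure,
        alpha: float = 0.95,
        rotate: bool = True,
        kinship_markers: np.ndarray | None = None,
        unit_variance: bool = True,
        group_weights: np.ndarray | None = None,
        scale_loss: bool = True,
    ):
        if isinstance(phenotype, PhenotypeVector) and isinstance(genotypes, GenotypeData):
            phenotype, genotypes = phenotype.align_to(genotypes)
        y = phenotype.values if isinstance(phenotype, PhenotypeVector) else np.asarray(phenotype, float)
        self.genotypes = genotypes
        self.snp_ids = (
            list(genotypes.snp_ids)
            if isinstance(genotypes, GenotypeData)
            else [f"snp{j}" for j in range(np.asarray(genotypes).shape[1])]
        )
        self.sample_ids = (
            list(genotypes.sample_ids)
            if isinstance(genotypes, GenotypeData)
            else [f"s{i}" for i in range(len(y))]
        )
        self.y_mean = float(np.mean(y))
        self.y = np.asarray(y, dtype=float) - self.y_mean
        self.alpha = float(alpha)
        self.rotate = bool(rotate)

        Z, stats = standardize_genotypes(genotypes, unit_variance=unit_variance)
        if stats.kept.size != len(self.snp_ids):
            kept_set = set(stats.kept.tolist())
            mapping = {
                self.snp_ids[j]: groups.group_ids[groups.assignments[j]]
                for j in stats.kept
            }
            self.snp_ids = [self.snp_ids[j] for j in stats.kept]
            groups = GroupStructure.from_mapping(self.snp_ids, mapping)
        self.Z = Z
        self.stats: StandardizationStats = stats
        self.groups = groups

        if self.rotate:
            markers = Z if kinship_markers is None else Z[:, kinship_markers]
            self.kinship: Optional[KinshipEigen] = eigendecompose(compute_rrm(markers))
            self.null: Optional[NullModel] = estimate_delta(self.kinship, self.y)
            rot = rotate_data(self.kinship, self.null, self.y, Z)
            self.rotated: Optional[RotatedData] = rot
            X_fit, y_fit = rot.X_tilde, rot.y_tilde
        else:
            self.kinship = None
            self.null = None
            self.rotated = None
            X_fit, y_fit = Z, self.y

        self.problem = SGLProblem(
            X=X_fit,
            y=y_fit,
            groups=groups,
            alpha=self.alpha,
            group_weights=group_weights,
            scale_loss=scale_loss,
        )

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_files(
        cls,
        genotype_path,
        phenotype_path,
        groups_path=None,
        annotation_path=None,
        format: str = "tsv",
        qc: bool = True,
        buffer_bp: int = 10_000,
        **kwargs,
    ) -> "SGLLMM":
        from . import io as gio

        g = gio.read_genotypes(genotype_path, format=format)
        if qc:
            g, report = gio.qc_filter(g)
            if report.n_kept < report.n_input:
                warnings.warn(
                    f"QC removed {report.n_input - report.n_kept} of {report.n_input} SNPs"
                )
        pheno = gio.read_phenotype(phenotype_path)
        pheno, g = pheno.align_to(g)
        if groups_path is not None:
            groups = gio.read_groups(groups_path, g, ignore_missing=qc)
        elif annotation_path is not None:
            ann = gio.read_gene_annotation(annotation_path)
            groups = gio.map_snps_to_genes(g, ann, buffer_bp=buffer_bp)
        else:
            raise ValueError("either a group file or a gene annotation is required")
        return cls(pheno, g, groups, **kwargs)

    @classmethod
    def from_simulation(cls, dataset, **kwargs) -> "SGLLMM":
        return cls(dataset.phenotype, dataset.genotypes, dataset.groups, **kwargs)

    def with_alpha(self, alpha: float) -> "SGLLMM":
        """Re-penalize the same (rotated) data with a different mixing weight."""
        self.alpha = float(alpha)
        self.problem = SGLProblem(
            X=self.problem.X,
            y=self.problem.y,
            groups=self.groups,
            alpha=self.alpha,
            group_weights=self.problem.group_weights,
            scale_loss=self.problem.scale_loss,
        )
        return self

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        lambda_: float | None = None,
        nlam: int = 100,
        lambda_min_ratio: float = 0.01,
        cv_folds: int = 5,
        seed: int = 0,
        tol: float = 1e-6,
        max_iter: int = 10_000,
    ) -> "SGLLMMResults":
        """Fit the lambda path and (unless lambda_ is given) choose lambda by CV."""
        path = fit_path(
            self.problem, nlam=nlam, lambda_min_ratio=lambda_min_ratio,
            tol=tol, max_iter=max_iter,
        )
        cv = None
        if lambda_ is None:
            cv = cv_select_lambda(
                self.problem, path, k_folds=cv_folds, seed=seed, tol=tol, max_iter=max_iter
            )
            lambda_ = cv.best_lambda
            best = path.fits[cv.best_index]
        else:
            best = fit_sgl(self.problem, lambda_, tol=tol, max_iter=max_iter)
        return SGLLMMResults(model=self, params=best.beta, lambda_=float(lambda_),
                             path=path, cv=cv, fit=best, seed=seed)


@dataclass
class SGLLMMResults:
    """Fitted SGL-LMM: sparse SNP effects plus variance-component diagnostics."""

    model: SGLLMM
    params: np.ndarray
    lambda_: float
    path: LambdaPath
    cv: Optional[CVResult]
    fit: object
    seed: int
    _stability: Optional[StabilityResult] = field(default=None, repr=False)

    @property
    def nonzero_index(self) -> np.ndarray:
        return np.where(self.params != 0)[0]

    @property
    def delta(self) -> float | None:
        return self.model.null.delta if self.model.null is not None else None

    @property
    def sigma_g2(self) -> float | None:
        return self.model.null.sigma_g2 if self.model.null is not None else None

    @property
    def fittedvalues(self) -> np.ndarray:
        """In-sample mixed-model predictions (fixed effects + random-effect BLUP)."""
        m = self.model
        fixed = m.Z @ self.params
        if m.kinship is None:
            return fixed + m.y_mean
        resid = m.y - fixed
        A = m.kinship.K + m.null.delta * np.eye(m.kinship.n_samples)
        return fixed + m.kinship.K @ linalg.solve(A, resid, assume_a="pos") + m.y_mean

    @property
    def resid(self) -> np.ndarray:
        return (self.model.y + self.model.y_mean) - self.fittedvalues

    def explained_variance(self) -> float:
        """In-sample explained variance of the fixed-effect part on rotated data."""
        pr = self.model.problem
        r = pr.y - pr.X @ self.params
        denom = float(np.sum((pr.y - pr.y.mean()) ** 2))
        return 1.0 - float(r @ r) / denom if denom > 0 else np.nan

    # -- stability selection ----------------------------------------------
    def stability_selection(
        self,
        n_resamples: int = 100,
        sample_frac: float = 0.5,
        threshold: float = 0.5,
        n_extra_lambdas: int = 9,
        seed: int | None = None,
        strict_refit: bool = False,
    ) -> StabilityResult:
        """Half-sample stability selection over the chosen lambda set.

        By default resamples reuse the full-data rotation (delta and
        eigenvectors estimated once).  ``strict_refit=True`` re-estimates the
        kinship, the variance ratio and the rotation on every resample's rows
        before fitting — statistically cleaner, several times slower, offered
        for comparison.
        """
        lams = pick_stability_lambdas(self.path, self.lambda_, n_extra=n_extra_lambdas)
        if strict_refit:
            res = self._stability_strict(
                lams, n_resamples, sample_frac, threshold,
                self.seed if seed is None else seed,
            )
        else:
            res = stability_select(
                self.model.problem,
                lams,
                n_resamples=n_resamples,
                sample_frac=sample_frac,
                threshold=threshold,
                seed=self.seed if seed is None else seed,
                snp_ids=self.model.snp_ids,
                beta_best=self.params,
            )
        self._stability = res
        return res

    def _stability_strict(self, lams, n_resamples, sample_frac, threshold, seed):
        """Stability selection with per-resample null refit and re-rotation."""
        m = self.model
        if m.kinship is None:
            raise ValueError("strict refit requires the mixed-model rotation")
        n, p = m.Z.shape
        n_draw = int(np.floor(n * sample_frac))
        counts = np.zeros(p)
        lams_desc = np.sort(np.asarray(lams, dtype=float))[::-1]
        for ss in np.random.SeedSequence(seed).spawn(n_resamples):
            rng = np.random.default_rng(ss)
            rows = rng.choice(n, size=n_draw, replace=False)
            Z_sub, y_sub = m.Z[rows], m.y[rows]
            ke = eigendecompose(compute_rrm(Z_sub))
            nm = estimate_delta(ke, y_sub)
            rot = rotate_data(ke, nm, y_sub, Z_sub)
            sub = SGLProblem(
                X=rot.X_tilde, y=rot.y_tilde, groups=m.groups, alpha=m.alpha,
                group_weights=m.problem.group_weights,
                scale_loss=m.problem.scale_loss, use_gram=False,
            )
            ever = np.zeros(p, dtype=bool)
            beta = np.zeros(p)
            for lam in lams_desc:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_sgl(sub, lam, beta_init=beta)
                ever |= fit.beta != 0.0
                beta = fit.beta
            counts += ever
        freq = counts / n_resamples
        tie = np.abs(self.params)
        return StabilityResult(
            snp_ids=list(m.snp_ids),
            frequencies=freq,
            selected=[m.snp_ids[j] for j in range(p) if freq[j] >= threshold],
            ranking=np.lexsort((np.arange(p), -tie, -freq)),
            lambdas_used=lams_desc,
            n_resamples=n_resamples,
            threshold=threshold,
            seed=seed,
        )

    # -- prediction --------------------------------------------------------
    def predict(self, genotypes_new: GenotypeData | np.ndarray) -> np.ndarray:
        """Predict phenotypes for new samples on the training SNP panel.

        A ``GenotypeData`` panel is aligned to the training SNPs by id (extra
        SNPs, e.g. ones the training QC removed, are dropped); a bare array
        must already match the training panel's columns.
        """
        m = self.model
        if isinstance(genotypes_new, GenotypeData) and isinstance(m.genotypes, GenotypeData):
            wanted = m.genotypes.snp_ids
            if genotypes_new.snp_ids != wanted:
                pos = {s: j for j, s in enumerate(genotypes_new.snp_ids)}
                missing = [s for s in wanted if s not in pos]
                if missing:
                    raise ValueError(
                        f"test panel lacks training SNPs: {missing[:5]}"
                    )
                genotypes_new = genotypes_new.subset_snps(
                    np.array([pos[s] for s in wanted])
                )
        if m.kinship is None:
            from .kinship import apply_standardization

            Z_new = apply_standardization(genotypes_new, m.stats)
            return Z_new @ self.params + m.y_mean
        pi = PredictionInput(
            X_train=m.genotypes,
            y_train=m.y + m.y_mean,
            X_test=genotypes_new,
            beta_hat=self.params,
            delta_hat=m.null.delta,
            stats=m.stats,
            y_mean=m.y_mean,
        )
        return predict_phenotype(pi)

    # -- reporting ---------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        m = self.model
        lines = []
        w = 58
        lines.append("=" * w)
        title = "SGL-LMM" if m.rotate else ("Lasso" if m.alpha == 1 else "SGL")
        lines.append(f"{title} results".center(w))
        lines.append("=" * w)
        lines.append(f"{'No. samples:':<28}{m.problem.n}")
        lines.append(f"{'No. SNPs:':<28}{m.problem.p}")
        lines.append(f"{'No. groups:':<28}{m.groups.n_groups}")
        lines.append(f"{'alpha (L1 share):':<28}{m.alpha:.3g}")
        if m.null is not None:
            flat = "  [flat profile]" if m.null.flat_likelihood else ""
            lines.append(f"{'delta (sig_e2/sig_g2):':<28}{m.null.delta:.4g}{flat}")
            lines.append(f"{'sigma_g2:':<28}{m.null.sigma_g2:.4g}")
        lines.append(f"{'lambda (chosen):':<28}{self.lambda_:.4g}")
        if self.cv is not None:
            lines.append(
                f"{'CV explained variance:':<28}"
                f"{self.cv.mean_explained_variance[self.cv.best_index]:.4f}"
            )
        lines.append(f"{'Nonzero coefficients:':<28}{len(self.nonzero_index)}")
        nz = self.nonzero_index
        if nz.size:
            lines.append("-" * w)
            lines.append(f"{'snp_id':<16}{'group':<16}{'beta':>12}")
            order = nz[np.argsort(-np.abs(self.params[nz]))][:top]
            for j in order:
                lines.append(
                    f"{m.snp_ids[j]:<16}{m.groups.group_of(j):<16}{self.params[j]:>12.4g}"
                )
        lines.append("=" * w)
        return "\n".join(lines)
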