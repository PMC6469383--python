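"""Synthetic GWAS data generator with population structure, LD and group signal.

The generator emulates the statistical structure of a structured plant panel:

* genotypes follow a Balding-Nichols model (ancestral allele frequency per
  SNP ~ Uniform(0.1, 0.9), population frequencies Beta-distributed around it
  with differentiation F_ST), samples split evenly across populations;
* within each gene (a contiguous block of SNPs) linkage disequilibrium is
  induced by thresholding latent AR(1) Gaussians per haplotype, so dosages
  keep Binomial(2, p) margins while neighboring SNPs are correlated;
* the phenotype mixes a sparse genetic signal from k causal SNPs confined to
  a few active groups, a kinship-driven population confounder, and iid noise:

      y = s_sig * y_sig + (1 - s_sig) * [ s_pop * y_pop + (1 - s_pop) * phi ]

  with y_sig = X_causal beta, beta ~ N(0, I), phi ~ N(0, I), and
  y_pop ~ N(0, K).  Each component is standardized to mean 0 / unit variance
  before mixing so the weights are interpretable as signal fractions
  (``raw_components=True`` disables this).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .io import GenotypeData, GroupStructure, PhenotypeVector
from .kinship import KinshipEigen, kinship_from_genotypes

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_population_effect",
    "simulate_phenotype",
    "simulate_dataset",
    "simulate_grid",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_samples: int = 1130
    n_groups: int = 200
    snps_per_group: int = 10
    m_active: int = 3
    causal_per_active: int = 5
    sigma_sig: float = 0.5
    sigma_pop: float = 0.5
    n_populations: int = 2
    fst: float = 0.1
    ld_rho: float = 0.5
    raw_components: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if not (0.0 <= self.sigma_sig <= 1.0 and 0.0 <= self.sigma_pop <= 1.0):
            raise ValueError("mixing weights must lie in [0, 1]")
        if self.m_active > self.n_groups:
            raise ValueError("more active groups than groups")
        if self.causal_per_active > self.snps_per_group:
            raise ValueError("active group smaller than the causal SNPs it must hold")

    @property
    def n_snps(self) -> int:
        return self.n_groups * self.snps_per_group

    @property
    def k_causal(self) -> int:
        return self.m_active * self.causal_per_active


@dataclass
class SimulatedDataset:
    """A simulated panel with full ground truth retained for audit."""

    genotypes: GenotypeData
    groups: GroupStructure
    phenotype: PhenotypeVector
    causal_mask: np.ndarray
    beta_true: np.ndarray
    active_groups: np.ndarray
    y_sig: np.ndarray
    y_pop: np.ndarray
    phi: np.ndarray
    config: SimulationConfig
    manifest: dict = field(default_factory=dict)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


def derive_seed(master_seed: int, *keys: float | int) -> int:
    """Stable sub-2^31 seed derived from a master seed and arbitrary keys."""
    ints = [int(master_seed)] + [int(round(float(k) * 10_000)) for k in keys]
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeData, GroupStructure]:
    """Balding-Nichols genotypes with AR(1) within-gene LD; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_snps
    anc = rng.uniform(0.1, 0.9, size=p)
    if cfg.fst > 0:
        a = anc * (1 - cfg.fst) / cfg.fst
        b = (1 - anc) * (1 - cfg.fst) / cfg.fst
        pop_freq = rng.beta(a[:, None], b[:, None], size=(p, cfg.n_populations))
    else:
        pop_freq = np.repeat(anc[:, None], cfg.n_populations, axis=1)
    pop_of = np.repeat(np.arange(cfg.n_populations), int(np.ceil(n / cfg.n_populations)))[:n]
    thresholds = sps.norm.ppf(pop_freq)  # (p, n_pop); allele = latent < threshold
    dosages = np.empty((n, p))
    s = cfg.snps_per_group
    rho = cfg.ld_rho
    for g in range(cfg.n_groups):
        cols = slice(g * s, (g + 1) * s)
        z = np.empty((n, 2, s))
        z[:, :, 0] = rng.standard_normal((n, 2))
        for j in range(1, s):
            z[:, :, j] = rho * z[:, :, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal((n, 2))
        t = thresholds[cols][:, pop_of].T  # (n, s)
        dosages[:, cols] = (z[:, 0, :] < t).astype(float) + (z[:, 1, :] < t)
    snp_ids = [f"snp{j:05d}" for j in range(p)]
    genotypes = GenotypeData(
        dosages=dosages,
        sample_ids=[f"s{i:05d}" for i in range(n)],
        snp_ids=snp_ids,
        chrom=np.array(["1"] * p, dtype=object),
        pos=np.arange(1, p + 1) * 1000,
    )
    group_ids = [f"gene{g:04d}" for g in range(cfg.n_groups)]
    groups = GroupStructure(group_ids, np.repeat(np.arange(cfg.n_groups), s))
    return genotypes, groups


def simulate_population_effect(ke: KinshipEigen, seed: int) -> np.ndarray:
    """One draw of the structured confounder y_pop ~ N(0, K), then standardized."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(ke.n_samples)
    y = ke.U @ (np.sqrt(ke.S) * z)
    return _standardize(y)


def simulate_phenotype(
    cfg: SimulationConfig,
    genotypes: GenotypeData,
    groups: GroupStructure,
    y_pop: np.ndarray,
    seed: int,
) -> SimulatedDataset:
    """Place causal SNPs in active groups and assemble the phenotype mixer."""
    rng = np.random.default_rng(seed)
    p = genotypes.n_snps
    active = np.sort(rng.choice(groups.n_groups, size=cfg.m_active, replace=False))
    causal = []
    for g in active:
        members = groups.members[g]
        if len(members) < cfg.causal_per_active:
            raise ValueError(f"group {groups.group_ids[g]} smaller than causal_per_active")
        causal.extend(rng.choice(members, size=cfg.causal_per_active, replace=False))
    causal = np.sort(np.array(causal))
    beta = np.zeros(p)
    beta[causal] = rng.standard_normal(len(causal))
    X = genotypes.dosages[:, causal]
    if np.isnan(X).any():  # generator output is complete; file inputs may not be
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    y_sig = X @ beta[causal]
    phi = rng.standard_normal(cfg.n_samples)
    if not cfg.raw_components:
        y_sig, y_pop, phi = _standardize(y_sig), _standardize(y_pop), _standardize(phi)
    y = cfg.sigma_sig * y_sig + (1 - cfg.sigma_sig) * (
        cfg.sigma_pop * y_pop + (1 - cfg.sigma_pop) * phi
    )
    mask = np.zeros(p, dtype=bool)
    mask[causal] = True
    return SimulatedDataset(
        genotypes=genotypes,
        groups=groups,
        phenotype=PhenotypeVector(y, list(genotypes.sample_ids)),
        causal_mask=mask,
        beta_true=beta,
        active_groups=active,
        y_sig=y_sig,
        y_pop=y_pop,
        phi=phi,
        config=cfg,
        manifest={
            "sigma_sig": cfg.sigma_sig,
            "sigma_pop": cfg.sigma_pop,
            "seed": cfg.seed,
            "phenotype_seed": seed,
        },
    )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Genotypes -> kinship -> confounder -> phenotype, all from cfg.seed."""
    genotypes, groups = simulate_genotypes(cfg)
    ke, _ = kinship_from_genotypes(genotypes)
    y_pop = simulate_population_effect(ke, derive_seed(cfg.seed, 1))
    ds = simulate_phenotype(cfg, genotypes, groups, y_pop, derive_seed(cfg.seed, 2))
    ds.manifest["kinship_trace"] = float(np.trace(ke.K))
    return ds


def simulate_grid(
    cfg_base: SimulationConfig,
    sigmas_sig: list[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    sigmas_pop: list[float] = (0.5, 0.7, 0.9),
    reps: int = 10,
    combinations: list[tuple[float, float]] | None = None,
):
    """Yield datasets over a (sigma_sig, sigma_pop) grid, ``reps`` per cell.

    ``combinations`` restricts the grid to an explicit subset of
    (sigma_sig, sigma_pop) pairs; the default product grid has
    len(sigmas_sig) * len(sigmas_pop) cells.  Per-dataset seeds are derived
    deterministically from the base seed and the cell coordinates.
    """
    if combinations is None:
        combinations = [(ss, sp) for sp in sigmas_pop for ss in sigmas_sig]
    if not combinations:
        raise ValueError("empty simulation grid")
    for s_sig, s_pop in combinations:
        for rep in range(reps):
            cfg = replace(
                cfg_base,
                sigma_sig=s_sig,
                sigma_pop=s_pop,
                seed=derive_seed(cfg_base.seed, s_sig, s_pop, rep),
            )
            ds = simulate_dataset(cfg)
            ds.manifest.update({"rep": rep, "sigma_sig": s_sig, "sigma_pop": s_pop})
            yield ds
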