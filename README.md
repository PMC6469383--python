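# sgllmm — sparse group lasso + linear mixed model GWAS

`sgllmm` is a multi-locus association mapping tool for quantitative traits.
It is aimed at the common situation where (i) a trait is polygenic, so
single-SNP tests waste power, (ii) causal SNPs cluster in a few genes, and
(iii) population structure or relatedness confounds naive regression.  The
model is

    y = X beta + y_pop + phi,     y_pop ~ N(0, sigma_g^2 K),   phi ~ N(0, sigma_e^2 I)

where `K` is the realized relationship matrix of the genotyped panel.
Fitting is two-step, in the FaST-LMM tradition: first the variance ratio
`delta = sigma_e^2 / sigma_g^2` is estimated under the null (`beta = 0`) by
a one-dimensional profile likelihood over the eigenvalues of `K`; then the
data are whitened through `S_delta U^T` (with `K = U S U^T`,
`(S_delta)_ii = (S_i + delta)^{-1/2}`) and the SNP effects are estimated by
a sparse group lasso on the rotated data:

    argmin_b (1/(2n)) ||y~ - X~ b||^2 + lambda (1-alpha) sum_G w_G ||b_G||_2 + lambda alpha ||b||_1

with SNPs grouped by gene (10 kb buffers around gene bodies), so sparsity is
enforced both between and within genes.  `lambda` is chosen by 5-fold
cross-validation along a geometric path; SNPs are then ranked by stability
selection (100 half-sample resamples over the chosen lambda plus 9 larger
path values) and the selection frequency is the evidence score for each SNP.
Phenotypes of new samples are predicted by
`X' b + K_{X'X} (K_{XX} + delta I)^{-1} (y - X b)`.

Setting `alpha = 1` gives a lasso, and disabling the rotation gives the
structure-unadjusted baselines, so lasso / SGL / lasso-LMM / SGL-LMM are all
configurations of one code path.  A synthetic-data module generates
population-structured genotype panels (Balding–Nichols with within-gene
AR(1) linkage disequilibrium) and phenotypes mixing a grouped sparse signal,
a kinship-driven confounder and iid noise, and an evaluation module scores
causal-SNP recovery with precision-recall curves.

## Worked example

```python
import numpy as np
from sgllmm import SGLLMM, SimulationConfig
from sgllmm.simulate import simulate_dataset
from sgllmm.metrics import pr_curve

cfg = SimulationConfig(n_samples=300, n_groups=40,
                       sigma_sig=0.5, sigma_pop=0.7, seed=7)
ds = simulate_dataset(cfg)                      # genotypes, groups, phenotype, truth
model = SGLLMM.from_simulation(ds, alpha=0.95)  # kinship, null model, rotation
results = model.fit(nlam=50, seed=0)            # lambda path + 5-fold CV
print(results.summary())
```

```
==========================================================
                     SGL-LMM results
==========================================================
No. samples:                300
No. SNPs:                   399
No. groups:                 40
alpha (L1 share):           0.95
delta (sig_e2/sig_g2):      0.1091
sigma_g2:                   0.4019
lambda (chosen):            0.02337
CV explained variance:      0.5238
Nonzero coefficients:       81
----------------------------------------------------------
snp_id          group                   beta
snp00364        gene0036             -0.2281
snp00263        gene0026               0.201
snp00264        gene0026             -0.1945
snp00234        gene0023              0.1711
...
```

`delta = 0.109` says the null model attributes most trait variance to the
kinship-structured component (as simulated: `sigma_pop = 0.7`), and the
CV explained variance (0.52) is close to the simulated signal fraction.  The
ten largest coefficients fall in three genes — the three simulated active
groups.  Stability selection then scores every SNP:

```python
stab = results.stability_selection(n_resamples=50, seed=0)
auc = pr_curve(stab.frequencies, ds.causal_mask).pr_auc
print(f"PR-AUC: {auc:.3f}")        # PR-AUC: 0.682 at this small scale
```

Twelve of the fifteen simulated causal SNPs reach the 50% selection
threshold at this reduced size; the misses are causal SNPs whose simulated
effects are near zero (the generator draws `beta ~ N(0, 1)`).  At the full
default scale (`n = 1130`, `p = 2000`) recovery is substantially better;
see the reproduction script below.

The same pipeline runs from the shell on PLINK or TSV files:

```bash
sgllmm simulate --out sim/ --seed 7
sgllmm run --genotypes sim/genotypes.tsv --phenotype sim/phenotype.tsv \
           --groups sim/groups.tsv --alpha 0.95 --seed 7 --out run/
sgllmm benchmark --out bench/ --reps 3   # four-method PR-AUC comparison grid
```

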