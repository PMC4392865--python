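# refcellfree

Reference-free decomposition of phenotype effects on DNA methylation into a
cell-composition component and a non-cell-mediated component.

## The problem

An epigenome-wide association study (EWAS) measures methylation beta values
`Y` (m CpGs × n samples, values in [0, 1]) in a mixed tissue such as whole
blood and relates them to phenotypes `X` (n × d design matrix, intercept
first). Most phenotype–methylation associations in such data are driven by
shifts in the tissue's underlying cell-type proportions, not by methylation
changes within cells. When reference methylomes for the constituent cell
types are unavailable, the mixture must be handled *reference-free*.

The model is

```
Y = B Xᵀ + M Ωᵀ + E,        Ω = X Γ + Ξ,
```

with `M` (m × k′) the unknown cell-type mean profiles, `Ω` (n × k′) the
mixing proportions (rows on the simplex), `B` the direct (non-cell-mediated)
effects and `E` measurement noise. The total effect of `X` on `Y` is
`A = B + M Γᵀ`, estimable by row-wise OLS with residual matrix `R`.

The key observation: direct effects live in the orthogonal complement of the
cell-profile space, and the profile space dominates the variation of both
`A` and `R`. A thin SVD of the concatenation

```
[A R] = U Λ Vᵀ,    A = Σⱼ λⱼ uⱼ v*ⱼᵀ     (v*ⱼ = first d coordinates of vⱼ)
```

therefore expands the total effect into rank-one terms whose leading `k`
terms estimate the cell-composition effect and whose remainder estimates the
direct effect:

```
Δₖ = Σ_{j≤k} λⱼ uⱼ v*ⱼᵀ,    Bₖ = A − Δₖ,    Δₖᵀ Bₖ = 0.
```

The package implements this decomposition together with

- dimension selection for `k`: the median-RMSD stability criterion (argmin
  over k of the median per-CpG RMS change Δₖ − Δₖ₋₁ on non-intercept
  columns), its bootstrap-t variant, and a random-matrix-theory bound on
  the residual spectrum;
- subject-resampling bootstrap standard errors, Wald p-values and
  Storey/Benjamini–Hochberg q-values per coefficient column;
- stratified **exact Mantel–Haenszel** gene-set enrichment of significant
  CpGs, conditioning on genomic context (CpG-island relation, Infinium
  chemistry, gene region), with a Fisher fallback for degenerate strata;
- a lineage-structured synthetic mixture generator with known ground truth,
  plus the null-scenario constructions (phenotype permutation; nonlinear
  effect injection on the M-value scale) used to calibrate the method;
- diagnostics: Ward/Euclidean clustering of Δₖ columns with Newick export,
  cross-dataset singular-vector cross-products, stratified correlations.

## Worked example

```python
import numpy as np
from refcellfree import (
    default_scenario, fit_total_effect, svd_expansion, partition_effect,
    bootstrap_decomposition, decomposition_tables, rmsd_profile, select_k_rmt,
)

# simulate a 4-cell-type case/control study with planted direct effects
Y, X, truth = default_scenario(m=6000, n=200, n_dmr_per_split=90, seed=0)

fit = fit_total_effect(Y, X)          # A: per-CpG total effects, R: residuals
dec = svd_expansion(fit)              # SVD of [A R]
print(dec.lambdas[:6].round(2))       # [46.23  7.43  3.64  3.53  1.8   1.8 ]

k = 4                                 # number of terms treated as composition
part = partition_effect(dec, k)
boot = bootstrap_decomposition(Y, X, k=k, n_boot=100, seed=1)
tables = decomposition_tables(part, boot, fit.cpg_ids, fit.covariate_names)

b_case = tables["b"].query("covariate == 'case'")
print((b_case.q < 0.05).sum())        # 106  (100 planted direct-effect loci)
print(select_k_rmt(fit.R))            # 3    (residual components above noise)
```

The singular values show the mixture structure (a large mean term, a case
term, two lineage terms, then the noise bulk at ~1.8). At `k = 4` the
significant `B_k` case coefficients recover the planted direct-effect loci:
106 calls against 100 planted loci at q < 0.05 (all 100 recovered, 6 false
positives — a realized false-discovery proportion of 0.057).

A command-line interface mirrors the library:

```
refcellfree simulate --config scenario.yaml --seed 7 --out-prefix sim
refcellfree decompose --beta sim.beta.tsv --design sim.design.tsv --k 4
refcellfree select-k --beta sim.beta.tsv --design sim.design.tsv --method rmsd
refcellfree bootstrap --beta sim.beta.tsv --design sim.design.tsv --k 4 --seed 1
refcellfree enrich --coefficients refcellfree.b.tsv --gene-sets sets.gmt \
    --annotation annot.tsv --platform 450K
refcellfree diagnose --delta refcellfree.delta.tsv
```

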