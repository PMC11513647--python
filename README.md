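# phylodem

Phylogenetic comparative demography from matrix population models (MPMs).

`phylodem` asks how a five-level **sociality continuum** (solitary →
gregarious → communal → colonial → social) relates to the demography of
animal species, after removing the confounding effects of adult body mass
and shared ancestry. It provides, as a tested pipeline:

1. **MPM handling** — validation of the decomposition `A = U + F`
   (survival/transition matrix `U`, reproduction matrix `F`), study
   selection filters (wild & unmanipulated, dimension ≥ 4, U/F split,
   stage survival ≤ 1, extant), annualization (`a_ij ← a_ij^(1/P)` for
   projection interval `P`), per-species grand-mean matrices, and the
   irreducible/primitive/ergodic gate that guarantees a single dominant
   eigenvalue.
2. **Age-from-stage demography** — survivorship `l_x` and fertility `m_x`
   schedules from the absorbing Markov chain defined by `U`, and lifespan
   moments via the fundamental matrix `N = (I − U)⁻¹`.
3. **Eleven life-history traits** per species: generation time `T`, net
   reproductive output `R₀` (dominant eigenvalue of `F N`), mean and
   variance of life expectancy `η_e`, `Δη_e`, maximum longevity `L_max`
   (99% cohort death), age at maturity `L_α`, reproductive window
   `L_{α−ω}`, maturity probability `p_R`, the shape statistics of
   survivorship and reproduction `s_{lx}`, `s_{mx}` (both in
   [−0.5, +0.5], 0 = constant with age), and degree of parity `S`
   (entropy of the age distribution of reproduction; 0 = semelparity).
4. **Asymptotics, elasticities and transients** — `λ`, `|1 − λ|`,
   stable-structure-weighted vital rates (σ, γ, ρ, φ), elasticities of λ
   to those rates (element elasticities `e_ij = a_ij v_i w_j / (λ vᵀw)`
   aggregated by a chain rule validated against finite differences),
   damping ratio `ζ = λ/|λ₂|`, period of oscillation `P_i = 2π/|arg λ₂|`,
   reactivity and first-step attenuation (max/min column sums of `A/λ`).
5. **Comparative statistics** — PGLS of each trait on log body mass with
   jointly ML-estimated Pagel's λ and profile-likelihood CI;
   simulation-based phylogenetic ANOVA of the residuals against sociality
   (Brownian-motion null on the tree) with Bonferroni correction, post hoc
   pairwise tests and compact letter displays; Spearman-|ρ| > 0.70
   collinearity pruning; <40% missingness screening; regularized
   iterative-PCA imputation (20 sets); and phylogenetic PCA with Kaiser
   retention.
6. **Synthetic studies** — birth–death trees, Brownian traits with tunable
   signal, thresholded-liability sociality, and progression-structured
   MPMs with closed-form ground truth, so every stage is testable offline.

## Worked example

```python
import numpy as np
from phylodem import (
    MatrixPopulationModel, compute_all_traits, summarize,
)

A = np.array([[1.0, 2.0], [0.5, 0.0]])   # golden-ratio Leslie matrix
U = np.array([[0.0, 0.0], [0.5, 0.0]])
F = np.array([[1.0, 2.0], [0.0, 0.0]])
m = MatrixPopulationModel(A=A, U=U, F=F)

t = compute_all_traits(m)
s = summarize(m)
print(f"lambda = {s.lam:.4f}, R0 = {t.R0:.1f}, T = {t.T:.4f}")
print(f"zeta = {s.zeta:.4f}, Pi = {s.Pi:.1f}, reactivity = {s.reactivity:.4f}")
```

prints

```
lambda = 1.6180, R0 = 2.0, T = 1.4404
zeta = 2.6180, Pi = 2.0, reactivity = 1.2361
```

i.e. the population grows by the golden ratio each year, an average
newborn leaves 2 offspring, a generation takes `log 2 / log 1.618 ≈ 1.44`
years, perturbations decay at ratio 2.618 while oscillating with period 2,
and a disturbance can inflate total population size by at most 23.6% in
one step.

A full synthetic study end to end:

```bash
phylodem simulate --n-species 152 --seed 1 --out bundle/
phylodem comparative --bundle bundle/ --seed 2 --out results/
```

`results/table1.csv` then holds one row per demographic variable (R², F,
d.f., simulation p, Bonferroni-adjusted p, Pagel's λ with 95% CI),
`posthoc_letters.csv` the per-level compact letter displays, and
`ppca_*.csv` the ordination loadings, scores and per-axis variance.

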