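# Methods

This note records the models implemented in `phylodem`, the choices made
where the methodology is genuinely open, and what the synthetic data can
and cannot establish about real comparative datasets.

## Matrix population models

An MPM projects stage abundances over one interval, `n(t+1) = A n(t)`,
with `A = U + F`: `U[i, j]` is the probability that an individual in
stage `j` survives and is in stage `i` one interval later, `F[i, j]` the
expected offspring in stage `i` per stage-`j` individual. Columns index
the source stage (the COMADRE orientation). Validation enforces
nonnegativity, `A = U + F` to 1e−9, and column sums of `U` ≤ 1 —
published matrices rarely carry more than six significant digits, so a
tighter tolerance would reject legitimate data while a looser one would
admit survival > 1, which inflates longevity and senescence estimates.

Study selection keeps wild, unmanipulated, extant species with a U/F
split and dimension ≥ 4; with fewer than four stages, age-from-stage
schedules plateau too early to resolve senescence. Matrices on
non-annual intervals are annualized element-wise (`a^(1/P)`) **before**
per-species averaging; the two operations do not commute (Jensen), and
annualize-first matches how multi-study species are averaged on a common
time unit.

Asymptotic, elasticity and transient metrics require a unique dominant
eigenvalue, so they are gated on irreducibility (strongly connected
life-cycle graph), primitivity (aperiodic cycles) and ergodicity
(strictly positive dominant left eigenvector). Life-history traits
depend only on the absorbing chain of `U` and `F` and are computed
regardless of the gate.

## Age-from-stage machinery

Death is the absorbing state of the chain defined by `U`. The
fundamental matrix `N = (I − U)⁻¹` gives expected intervals spent in
each stage; life expectancy is `η_e = 1ᵀN c` and its variance
`1ᵀ(2N − I)N c − η_e²`, where `c` is the cohort entry distribution. Age
is counted in projection intervals, age 0 at the first census, so an
individual certain to die before the second census has lifespan 1.

The entry distribution is not recorded in matrix databases; by default
all mass is placed on the stage receiving the largest reproduction
inflow (largest row sum of `F`), ties resolved to the earliest stage.
Schedules are truncated at `xmax = 1000` intervals or once `l_x < 1e−7`;
the truncation is far beyond `L_max` for any gated matrix and does not
bias the shape statistics, which are additionally computed only up to
`L_max` so that late-life plateaus carried by a vanishing cohort
fraction cannot distort them.

Maturation quantities make the reproductive stages (positive `F`
columns) absorbing: `p_R` is the absorption probability, `L_α` the mean
absorption time of the Doob-conditioned chain (the literal reading "age
of the *first* individual to reproduce" is a cohort minimum that
degenerates with cohort size; the conditional mean is the standard
estimator), and the reproductive window is the mean remaining life
expectancy at first entry, averaged over the conditional entry
distribution.

## Shape statistics and parity

`s_lx` standardizes retained ages to [0, 1] and log-survivorship to
`g = log l_x / log l_x(last)`, and equals 0.5 minus the area under `g`.
For constant per-step survival `g` is the diagonal and `s_lx = 0`
exactly; because `g` is monotone within [0, 1], the statistic is
guaranteed to lie in [−0.5, +0.5] for any monotone schedule.

`s_mx` is the area under the standardized cumulative-reproduction curve
minus 0.5. The curve is anchored at (0, 0) with age-`x` reproduction
accrued by the *end* of interval `x`: with the naive same-index
standardization, constant fertility yields a spurious offset of
`1/(2(X+1))` (0.01 at 50 ages), violating the definitional anchor that
constant reproduction maps to 0. With the end-of-interval convention the
constant schedule maps to 0 exactly, early-concentrated reproduction
approaches +0.5, and the bound ±0.5 holds.

The parity index `S` is the Shannon entropy (natural log, `0·log 0 = 0`)
of `p_x ∝ l_x m_x`. Undiscounted entropy is used — a λ-discounted
variant exists, but only the undiscounted form satisfies `S = 0` for
strict semelparity at any growth rate, which is the index's defining
anchor.

Generation time defaults to `T = log R₀ / log λ`; the alternative mean
age of mothers at the stable structure (`abar = λ vᵀw / vᵀFw`) is
available via a method flag. Both are standard; the default is the one
consistent with the `R₀`/λ machinery already required, and it is flagged
undefined at the removable singularity `λ = R₀ = 1`.

## Elasticities and transients

Element elasticities are `e_ij = a_ij v_i w_j/(λ vᵀw)` and sum to 1 by
Euler homogeneity. Vital-rate elasticities parameterize each column of
`U` as survival σ_j times a conditional transition distribution split
into growth (below diagonal), shrinkage (above diagonal) and stasis
(diagonal): a survival perturbation scales the whole column, a
growth/shrinkage perturbation scales that conditional mass with
compensation from stasis, and a reproduction perturbation scales the `F`
column. Databases do not dictate how rate-level elasticities aggregate
over stages; this column parameterization is the documented choice and
is validated against central finite differences (relative step 1e−6,
agreement to 1e−4) on a thousand random matrices. Under it,
`E_σ + E_φ = 1`.

Transients use the λ-standardized matrix: damping ratio `ζ = λ/|λ₂|`,
period `P_i = 2π/|arg λ₂|` (infinite for real positive λ₂; of a complex
pair, the member with positive imaginary part is taken), and
reactivity/attenuation as the max/min column sums of `A/λ` — the
one-step amplification envelope, which necessarily straddles 1.

## Comparative layer

Under Brownian motion, tip values are multivariate normal with
covariance `σ²C`, `C[i,j]` the shared root-to-MRCA path length (any stem
below the root is ignored; topologies without branch lengths fall back
to Grafen's heights). Pagel's λ scales the off-diagonal of `C`. PGLS
profiles λ over [0, 1] by ML; for ultrametric trees `C` and `C_λ` share
eigenvectors, so one symmetric eigendecomposition makes each likelihood
evaluation O(np). The 95% CI is the profile-likelihood interval (1.92
log-units), truncated at the boundaries.

The phylogenetic ANOVA refers the observed one-way F statistic on the
PGLS residuals to F statistics from BM simulations on the tree (rate =
REML estimate from the residuals; the statistic is scale- and
location-invariant, so the rate estimate does not affect the null law),
with the add-one Monte-Carlo p-value. Pairwise post hoc |t| statistics
are referred to the same simulations and Holm-adjusted; compact letters
label the maximal cliques of the not-significantly-different graph.
Sociality enters as an unordered five-level factor — the ordering is
interpretive and the F-test does not use it. Conventional degrees of
freedom (k−1, n−k) are reported.

The pPCA estimates a single λ for the multivariate Brownian model,
centres traits on the GLS mean and eigen-decomposes the evolutionary
covariance `R = (X−1a)ᵀC⁻¹(X−1a)/(n−1)`; scores are exactly orthogonal
in the `C⁻¹` metric, and axes with eigenvalue > 1 are retained (Kaiser —
meaningful because inputs are standardized to unit variance). Before the
ordination, time-based traits are pruned at |Spearman ρ| > 0.70 (keep
the less-missing member, ties to the canonical trait order), screened at
< 40% missingness, log-transformed, body-mass-corrected by PGLS and
z-scored.

## Imputation

Missing residual cells are filled by regularized iterative PCA: column
means → rank-`ncomp` SVD reconstruction with singular values shrunk by
the noise variance estimated from the trailing components → refill →
iterate to a 1e−6 relative change (`ncomp = 2`, matching the two
retained ordination axes; max 1000 iterations, non-convergence flagged,
never raised). Observed cells are never modified. Complete auxiliary
columns (vital rates, elasticities, transients, log mass) are appended
during imputation to lend covariation strength and discarded afterwards
(flag to disable). Twenty imputation sets are produced by perturbing
imputed cells with residual noise; downstream results use the first
completed set, with the between-set SD of ordination scores reported as
a sensitivity descriptor.

## Synthetic data

`make_dataset` emulates the statistical structure of a real comparative
compilation: 152 species by default on an ultrametric birth–death tree
(unit depth), log body mass Brownian with variance 4 (spanning roughly
insect-to-megafauna once exponentiated around 500 g), sociality from a
Brownian liability with λ = 0.9 cut at quintiles (matching the strong
signal such classifications show), log life expectancy built as
intercept + 0.25·log mass (quarter-power scaling) + level shift +
Brownian deviation (SD 0.3, λ = 0.9), and a four-stage progression life
cycle whose adult survival is solved to meet the life-expectancy target,
with fertility set so `R₀` scatters around a mild surplus. Missing
cells are masked completely at random at 15%, capped so every column
stays under the 40% screen and every row keeps one value.

What this does **not** emulate: taxonomic tree shape, measurement error
in matrix entries, retrogression (shrinkage) stages — so `ρ` and `E_ρ`
are degenerate in synthetic runs and the pipeline skips them — informative
missingness, and cross-study heterogeneity within species. Passing tests
therefore certify the estimators and their calibration under the stated
generative model, not robustness to those real-data features.

## Numerical choices

Decomposition/survival tolerance 1e−9; eigen-identities checked to
1e−8; singular life cycles (survival outflow 1) raise with the stage
named; ties in the subdominant modulus resolved to the positive
imaginary member; `0·log 0 = 0` throughout; `L_max` uses the strict
reading "more than 99% dead" (`l_x < 0.01`); degenerate σ_j = 0 stages
contribute zero growth/shrinkage and are dropped from those weighted
means' renormalization. Monte-Carlo oracles simulate stage-occupancy
counts with multinomial transitions — distributionally identical to
individual-based simulation and fast enough for 200 000-individual
cohorts in tests. Test problem sizes (500-replicate type-I calibration
at 150 tips with 500 null simulations each; 200-replicate recovery runs)
were chosen so the full suite runs in about a minute on one core,
enabled by vectorizing the null-simulation matrix algebra.
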