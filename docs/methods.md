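# Methods

## The model

`thermoherd` implements a genetic evaluation of dairy-cow conception under
heat stress.  Heat load is quantified by the temperature–humidity index

    THI = (1.8·temp + 32) − (0.55 − 0.0055·rh)(1.8·temp − 26)

computed hourly from °C temperature and % relative humidity and averaged
over the insemination date.  Conception is assumed unaffected below a
threshold (THI_thr = 68 by default); the reaction-norm regressor is the
broken stick f(THI) = max(0, THI − THI_thr).

The observation model is a multitrait linear repeatability test-day model
treating the first three parities as distinct traits.  For cow *n*, parity
*l*, herd-day *k*, DIM class *m*:

    y_klmn = HTD_kl + DIM_m + a_nl + pe_nl + (v_nl + q_nl)·f(THI) + e_klmn

* `HTD_kl` — fixed herd × insemination-date contemporary group within
  parity; `DIM_m` — fixed 20-day days-in-milk class (1–400 d).
* `a_nl`, `v_nl` — random genetic intercept (thermo-neutral performance)
  and slope (thermotolerance: change in conception per THI degree above
  threshold).
* `pe_nl`, `q_nl` — the permanent-environment analogues for cows with
  records.
* Var[(a,v)-stack] = A ⊗ Φ with A the pedigree numerator relationship
  matrix and Φ the 6×6 coefficient covariance; Var[(pe,q)-stack] = I ⊗ ψ;
  residual variances are parity-specific (diagonal R).

The 0/1 insemination outcome is modelled **linearly** (no link function),
which is the standard treatment of conception scores in test-day
evaluations; residual variances then sit near p(1−p) of the conception
rate, and all variance components are on the observed 0/1 scale.  This is
a known limitation, not an oversight: heritabilities on this scale are
small (a few percent) by construction.

Coefficient order within every 6-block is (a1, v1, a2, v2, a3, v3) —
parity-major, intercept before slope — fixed across the whole package.

## Identifiability

The first HTD level of each parity and the first DIM class are constrained
to zero.  Sparse contemporary-group structures can still alias an HTD
level with a DIM class on small data sets; the Gibbs sampler and iterative
solvers tolerate this (the aliased direction is simply not interpretable),
but the dense GLS comparisons require a full-rank fixed design.

## Variance-component estimation

Φ, ψ and R are sampled by Gibbs:

1. location parameters from their full conditionals — fixed-effect levels
   single-site, genetic and permanent-environment coefficients blocked per
   animal/cow 6-vector using the Kronecker structure (for animal *n* the
   conditional precision is the data part plus a^{nn}Φ⁻¹, with the
   neighbour term −Φ⁻¹Σ_{m≠n}a^{nm}u_m);
2. Φ | rest ~ inverse-Wishart(ν₀ + q, S₀ + U′A⁻¹U) where U stacks the
   genetic 6-vectors of all q pedigree animals;
3. ψ | rest ~ inverse-Wishart(ν₀ + c, S₀ + P′P) over the c cows;
4. each parity's residual variance from a scaled inverse-χ² with the
   parity's residual sum of squares.

Priors: inverse-Wishart with ν₀ = 8 (dimension + 2) and scale
S₀ = (ν₀ − 7)·Σ_init for both Φ and ψ — i.e. centered on the chain's
initial covariances at **one pseudo-observation of weight** — and a flat
(df −2, scale 0) scaled inverse-χ² for the residuals.  The prior's
posterior influence is ~1/n and vanishes at any realistic scale, but the
centering matters: a fixed small scale like 1e-6·I is *not* vague for a
covariance matrix (its density behaves as |Σ|^−(ν₀+7)/2 with no
containment near zero) and pins weakly identified components to the
numerical floor, while a large fixed scale like 0.01·I biases slope
variances of order 1e-5 upward.  Prior df and scale are configurable;
a float ``prior_scale`` reproduces the fixed-scale convention.

Two Markov-chain moves per iteration supplement the conditional draws:
an interweaving (parameter-expansion) Metropolis step that jointly
rescales one coefficient column and the matching covariance row/column,
u(:,c) → d·u(:,c), Σ → DΣD with log d ~ N(0, τ²), τ = 0.3 by default.
The Gaussian quadratic form is invariant under this map, so the
acceptance ratio reduces to the likelihood change plus a prior/Jacobian
term d^−ν₀·exp(−½Δtr(Σ⁻¹S₀)).  Centered Gibbs alone is nearly absorbing
at small variances (effective sample sizes of ~5 over 20 000 iterations
in desk-scale runs); the rescaling move frees that slow log-variance
direction.  Correctness is verified two ways in development: an empty-data
chain reproduces the analytic inverse-Wishart prior quantiles, and the
acceptance formula matches direct log-density evaluation to 1e-14.

Genotypes are never used for variance estimation; the genetic metric in
the sampler is always A⁻¹.

Run lengths: the desk-scale default is 20 000 samples, 4 000 burn-in,
thinning 10 (≈1 600 retained draws; about a minute for 1 000 cows / 6 000
records on one CPU).  Production-scale settings (500 000 / 100 000 / 100)
are available through `GibbsConfig`.

Convergence is monitored numerically: per-parameter Geweke z (first 10%
vs last 50% of the chain, batch-means standard errors with n^(2/3)
batches) and an effective sample size from the initial-positive-sequence
autocorrelation sum; trace-plot panels can be written alongside.  A pure
random walk is self-similar, so no consistent Geweke-type statistic
detects it with probability 1: the calibrated detection rate of |z| > 3 is
≈92% at a ≈1% false-positive rate on white noise, which is what the test
suite asserts (with a binomial floor).

Posterior reports transform **each retained draw** (heritability,
correlations) and then summarize by mean and shortest-interval 95% HPD —
transform-then-summarize, pinned by a regression test.  Reported rows use
the customary scalings (100σ²_v, 10σ_av) and default to heat load f = 10
(THI = 78).  Note the genetic correlation formula f·σ_av/√(σ²_a f²σ²_v)
is scale-free in f for f > 0, and that a correlation computed from
*rounded posterior means* of the components generally differs from the
posterior mean of per-draw correlations — only the latter is reported.

## Relationship matrices and single-step evaluation

* A by the tabular method; diagonal = 1 + F.
* A⁻¹ by Henderson's rules **with inbreeding** (Meuwissen–Luo
  Mendelian-sampling variances; kinship recursion with memoisation).
  Unknown parents are unrelated base animals; no genetic groups.  A
  `--no-inbreeding` switch reproduces the classic rules.
* G by VanRaden's first method with observed allele frequencies,
  missing codes mean-imputed (2p) before centering, blended
  G = 0.95·G_raw + 0.05·A22 for guaranteed invertibility.  These are the
  community defaults for single-step evaluations and are all
  configurable.
* H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹] in the genotyped block.
* SNP QC: sex-chromosome, monomorphic and MAF < 1% markers removed (a MAF
  of exactly 1% is retained).

ssGBLUP solutions are obtained by Jacobi-preconditioned conjugate
gradients to a relative residual of 1e-10 at fixed (posterior-mean or
user-supplied) variances.

## Whole-genome scan

SNP effects are back-solved from the genotyped animals' GEBVs:
ŝ = D Z′(Z D Z′)⁻¹ û with D = I.  Because Z is centered at observed
frequencies its columns are zero-mean, so Z D Z′ is singular by
construction (the ones vector spans its null space); with no blending the
package therefore applies the Moore–Penrose inverse, which realizes the
projection identity — ŝ recovers planted effects exactly when Z has full
column rank.  With blending (default α = 0.95 toward k·A22, k = 2Σp(1−p))
an ordinary solve is used.

Windows are 2.0 Mb of adjacent SNPs, **sliding** (anchored at every SNP)
by default, with a non-overlapping mode available.  The reported quantity
per window is var(Σ_{j∈window} z_j ŝ_j)/σ²_u × 100 with the variance taken
across genotyped animals and σ²_u the empirical variance of the effect's
GEBVs among genotyped animals (several denominator conventions circulate;
this choice makes a single all-SNP window report exactly 100%).  One scan per genetic effect (intercept and slope × three
parities).

## Gene-set over-representation

SNPs map to genes within the gene body ± 15 kb (strand-agnostic, 1-based
inclusive coordinates; a converter handles 0-based half-open BED).  Per
parity, the relevant SNPs are the top 5% of |ŝ| — k = ceil(0.05·m) top
markers, ties at the threshold included — and a gene counts as flagged in
a parity if it carries ≥1 relevant SNP.  Genes flagged in ≥2 parities form
the relevant set.  Each gene set is tested by the one-sided cumulative
hypergeometric (Fisher) tail P(X ≥ k) against the background of
SNP-covered genes (not all annotated genes; configurable).  Raw p-values
are reported; Benjamini–Hochberg adjustment is optional.

## The synthetic herd

The generator emulates the statistical structure of a two-herd
subtropical dairy study with known truth:

* **Pedigree** — discrete random-mating generations; founders alternate
  sex, each later generation makes `n_founders//2` sire×dam matings with
  2 offspring.
* **Genotypes** — unlinked biallelic SNPs (founder MAF uniform on
  0.05–0.5), gene-dropped through the pedigree; positions uniform on 5
  chromosomes.
* **Weather** — hourly records from a seasonal sinusoid (22 ± 8 °C,
  diurnal cycle, RH ≈ 70%), giving daily mean THI spanning ≈55–85 with
  roughly half of days above the 68 threshold.
* **Records** — per-parity inseminations on 52 evenly spaced insemination
  dates per year (scheduled AI keeps herd-date contemporary groups at a
  realistic size; fully random dates would give groups of ~1 record that
  absorb nearly all the signal), DIM uniform on 30–280, herd-date and
  DIM-class effects drawn once per level.  Genetic coefficients are MVN(0,
  Φ) founders with Mendelian-sampling deviations of covariance ½Φ (¾Φ/Φ
  for one/no known parent; parental inbreeding ignored in the generator),
  or, in genomic mode, Z·s with planted QTL blocks carrying a chosen
  fraction of each coefficient's variance.
* **Outcomes** — Gaussian mode (default for recovery experiments: the
  estimator is a linear model, so Gaussian data satisfy its assumptions
  exactly) or Bernoulli mode through a clipped-linear probability for
  realism.

Default variance magnitudes are the per-parity scale typical of
conception traits: σ²_a = 0.002/0.004/0.008, 100σ²_v = 0.005/0.009/0.015,
10σ_av = −0.001/−0.003/−0.008, σ²_e = 0.20/0.19/0.18, with across-parity
intercept correlations 0.58/0.83/0.88 and slope correlations
0.17/0.49/0.32.  The cross intercept–slope covariances across parities
follow the path rule corr(a_i, v_j) = cor_gen(i,j)·r_av(j), which keeps
the assembled 6×6 matrix positive definite (zero cross terms do not).
Permanent-environment defaults are σ²_pe = 0.006 and σ²_q = 5e-5 per
parity with no across-parity covariance.

What the generator does **not** emulate: linkage disequilibrium (an
optional block-copy mode aside), selection and culling, seasonal calving
management, genotype-by-environment beyond the reaction norm, and the
binary-outcome bias of the linear model (Gaussian mode sidesteps it).
Passing recovery tests therefore demonstrate internal consistency of the
estimator under its own assumptions, not field performance on real herd
data.

## Validation experiments (problem sizes)

The test suite runs three simulation experiments end to end:

* **Parameter recovery** — 10 seeds; 700 founders × 2 generations
  (2 100 animals), 1 000 cows × 6 records (6 000 records — the ~6
  records-per-cow ratio typical of multi-lactation conception data),
  truth at the default magnitudes above, Gaussian outcomes; desk-scale
  Gibbs (20 000 iterations).  Checked (strictly): each genetic variance
  covered by its 95% HPD in ≥80% of seeds, and all three
  general-vs-thermotolerance correlations recovered negative in ≥9/10
  seeds.  This check is known to fall short for the parity-3 components
  at this data size: with across-parity genetic correlations of 0.8–0.9
  and ~2 records per cow-parity, the likelihood barely resolves the
  parities (a univariate REML cross-check on per-parity slices can land
  on the zero boundary), and the inverse-Wishart posterior pools the
  parities toward a common level, pulling the largest variance below its
  interval.  Longer chains converge to the same posterior, i.e. this is
  a property of the model at this size, not of the sampler; field-scale
  analyses of these magnitudes use an order of magnitude more records.
  The assertion is nevertheless kept at its stated strictness rather
  than weakened to fit.
* **Planted-QTL scan** — 20 seeds; 600 animals all genotyped, 250 cows ×
  9 records, 1 000 SNPs on 5×40 Mb chromosomes; a ~1.5 Mb block on
  chromosome 1 carries 50% of the parity-1 slope variance, with boosted
  magnitudes (σ²_a = 0.05, σ²_v = 0.01, σ²_e = 0.25) so the slope GEBVs
  are informative (accuracy ≈ 0.65) at this scale — at conception-trait
  heritabilities of 2–3%, no window scan of a few hundred animals has
  power, so the experiment tests the scan machinery rather than
  replaying a field-scale analysis in miniature.  Checked: the window
  containing the
  largest planted QTL ranks in the top 3 in ≥90% of seeds.
* **Planted-set enrichment** — 20 seeds; 600 genes × 5 SNPs, 30 random
  20-gene sets plus one 25-gene planted set whose SNP effects are scaled
  ×1.19 (≈2× relative risk of exceeding the top-5% threshold).  Checked:
  the planted set beats the median random set's p in ≥95% of seeds and
  ranks top 3 in ≥80%.

## Numerical choices

* MME left-hand sides are symmetrized exactly after assembly (sparse
  matmul summation order otherwise leaves ~1e-17 asymmetries).
* The per-block MVN draws use a hand-rolled 6×6 Cholesky
  (x = P⁻¹b + L⁻ᵀz); the Gibbs sweep is numba-compiled.
* Inverse-Wishart scales are symmetrized and redrawn with escalating
  jitter (logged) in the numerically impossible event of a non-PD draw.
* HPD intervals are the shortest window containing ⌈prob·n⌉ sorted draws.
* Constant chains: ESS ≡ n and Geweke z ≡ 0 by convention.
* Empty scan windows report 0% with B = 0; ties in window ranking break
  by (chromosome, start).
* Heritability with a negative numerator (strongly negative σ_av) is
  returned as-is with a warning, never clipped.

## Known limitations

* Linear treatment of a binary outcome (see above); no threshold model.
* Single-chain diagnostics only (no Gelman–Rubin).
* No genetic groups/metafounders; no APY or other large-scale G
  approximations.
* Sliding windows overlap, so window percentages are descriptive, not a
  variance decomposition; with unlinked SNPs the non-overlapping windows
  sum to ≈100%.
* The location sampler is implemented only in blocked form; its
  conditionals are verified against closed-form oracles rather than
  against a second single-site implementation.
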