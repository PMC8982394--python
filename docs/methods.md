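# Methods

## The inheritance model

Each of the three crosses (A×B, B×C, A×C, where A, B, C are the
hypothetical dominant genes behind the WT, Wrap and Bulky conidiophore
architectures) produces F2 progeny whose conidiophores are classified
into the three phenotypes. Counts N_ij are modelled as independent
multinomials with fixed row totals n_i and cell probabilities

    p_i(θ) = ⅓·1 + X_i θ,

a *linear-probability* parameterization: θ stacks three allelic effects
(α, β, γ) and three pairwise epistatic interactions (αβ, βγ, αγ), all
dimensionless deviations on the probability scale, and the 3×6 design
matrix X_i of each cross maps them to deviations from the uniform
baseline of a trait with no genetic influence.

### Design-matrix reconstruction

The source analyses define X in prior work and never print it, so the
package ships a declared, overridable reconstruction (`default_design`,
override via `--design` / `load_design`): in cross U×V (U preceding V
in the order A < B < C),

    d_U = θ_U + θ_UV,   d_V = θ_V − θ_UV,   d_third = −θ_U − θ_V.

Properties that motivated this choice:

- every column sums to zero within a cross, so fitted probabilities
  always sum to one;
- the stacked 9×6 matrix has full column rank 6, hence the full
  epistatic model is saturated on the 6 free data df (9 cells − 3 row
  constraints) — reproducing the published 0.00 χ² on 0 df;
- the df accounting of the whole hierarchy (residual df = 6 − number of
  free parameters) matches the published table row for row;
- each interaction appears only in its own cross.

The sign asymmetry (+θ_UV on the alphabetically first gene) is
arbitrary and fixed. Consequences of not knowing the true X: the
environmental and saturated χ² values, all df, the Δχ² arithmetic of
the published environmental/additive pair and the heritability ratio
are design-independent and are reproduced exactly; the *intermediate*
model χ² values and the parameter estimates/SEs are design-dependent
and are treated as reference values only. They are validated instead by
oracle equivalence (IRLS vs a derivative-free ML search) and by
parameter recovery on simulated crosses.

### Fitting: Fisher scoring / IRLS

With y_i the observed proportions and X̃ the free columns (a model of
the hierarchy pins a subset of θ to zero),

    score        U(θ) = Σ_i n_i X̃_i′ diag(1/p_i) (y_i − p_i)
    information  I(θ) = Σ_i n_i X̃_i′ diag(1/p_i) X̃_i

I(θ) is exactly the weighted least-squares matrix N X′AX with
A = diag(1/p̂) recomputed each iteration; because the columns of X sum
to zero within a cross, the usual multinomial rank-1 correction
vanishes and scoring on this information solves the ML equations.

Numerical choices:

- initialization θ = 0 (uniform probabilities) — deterministic, no
  seed;
- convergence when max|Δθ| / max(1, max|θ|) < tol, default tol = 1e−8,
  iteration cap 100 (the saturated fit on the packaged counts converges
  in 2 iterations; restricted models in ≤ 10);
- step-halving whenever a step would push any fitted probability
  outside (1e−6, 1 − 1e−6); an underflowing step raises;
- singular free-column sets raise an error naming the collinear
  columns; non-convergence returns a flagged result (or raises in
  strict mode);
- standard errors are √diag(I(θ̂)⁻¹) for free parameters only.

### Nested tests and heritability

Restricted (H0) vs more general (HA) models are compared by
Δχ² = χ²_H0 − χ²_HA on Δdf = df_H0 − df_HA, referred to the upper
chi-squared tail. At exact optima Δχ² ≥ 0; a numerically negative
difference is clamped to zero with a warning and the raw value kept.
Δdf is always computed from the df rule, not copied from any printed
table (the published table contains two Δdf entries inconsistent with
its own df column, and one unreadable df cell, all resolved by the
rule). Heritability is H² = (χ²_env − χ²_add)/χ²_env; it is undefined
(reported as such) when the environmental model already fits perfectly.

## Dispersal statistics

`ks_statistic` evaluates the EDF sup-distance over the pooled values.
P-values come in two flavours:

- **exact**: P(D ≥ d) under the tie-free null by counting monotone
  lattice paths from (0,0) to (n1,n2) that stay strictly inside the
  band |i·n2 − j·n1| < h, in exact integer arithmetic (Python ints /
  `Fraction`), h = ⌈d·n1·n2 − 0.1⌉ — the 0.1 grid-unit tolerance snaps
  a rounded-off printed D back to its achievable lattice value;
- **asymptotic**: the Kolmogorov series
  Q(λ) = 2 Σ (−1)^{k−1} e^{−2k²λ²} at λ = d·√(n1·n2/(n1+n2)),
  truncated when a term < 1e−12 and clamped to [0,1]. No Stephens-type
  small-sample correction is applied: the plain series is what
  reproduces the published values.

`auto` picks exact iff n1·n2 < 10000 and the pooled sample is tie-free,
else the asymptotic series (with a warning when ties force the
fallback) — the selection rule of the standard two-sample KS routines.
This rule explains the published mixture of methods: the Wrap–Bulky
comparison (195×104) and the WT–Wrap comparison (ties from rounded
image measurements) match the asymptotic series to the printed digits,
while the tie-free WT–Bulky comparison matches the exact tail. The
exact tail is verified against brute-force enumeration of all
interleavings for n1+n2 ≤ 12 and, at the published WT–Wrap statistic,
against an independent reference implementation.

Shapiro–Wilk delegates to the established implementation of Royston's
published approximation (valid 3 ≤ n ≤ 5000); the wrapper is
cross-checked against a second, independent implementation.

**Maximum dispersal.** The observed maximum is standardized against a
reference spore shadow, z = (max − X̄)/S, and z² treated as
approximately χ²(1); the tail of the largest of n such values is
1 − F(z²)ⁿ, computed through the survival function
(−expm1(n·log1p(−q))) so that far tails degrade to n·q instead of
underflowing. n defaults to 3 (the three strain maxima). The published
tail probabilities for this statistic are not recoverable from the
stated procedure under any reading we tested (plain, ×n, or power-n);
the implementation follows the stated procedure literally and is
validated by its monotonicity and Bonferroni-bound properties instead.

## Germination and penetrance

Germination rate = mean replicate colonies / expected colonies × 100%,
with expected colonies = suspension concentration × plated volume
(1.00e3 cells/ml × 0.1 ml → 100). Rates above 100% are possible because
the concentration is only roughly calibrated; they are reported
unchanged, with a warning above 120%. The timeline report flags a
strain on a condition only when it germinated *strictly* earlier than
every other strain. Penetrance is the majority-phenotype fraction; ties
are broken by the fixed WT < Wrap < Bulky order with a warning (real
classifications never tie). The association test is Pearson's χ² of
independence without continuity correction, df = (r−1)(c−1), warning on
expected cells < 5.

## Synthetic data

The generators emulate the three measured layers at study scale:

- **Cross counts**: independent multinomials per cross from the forward
  model. Default sizes (396, 286, 366) match the observed per-cross
  progeny totals; the default effect vector (0.06, −0.03, 0.03, 0.03,
  −0.03, 0) is a moderate setting comfortably inside the probability
  simplex, used for recovery experiments.
- **Dispersal**: isotropic bivariate-normal coordinates about the
  membrane center, returned as radial (Rayleigh) distances; default
  σ = 3.8 cm makes the mean radial distance σ√(π/2) ≈ 4.76 cm match
  the observed mean movement of ≈ 4.7 cm. Default 75 colonies mirrors
  the per-platter sampling cap. Membrane radius (3 cm) and platter
  half-width (22.86 cm) are exposed as constants for boundary-
  truncation experiments.
- **Germination**: replicate counts ~ Binomial(round(expected), rate);
  defaults of 100 expected colonies, 3 replicates and a 39% rate mirror
  the plating assay.

A single global seed fans out to named per-stream generators
(`stream_rngs`), so counts, dispersal and germination streams are
independent yet jointly reproducible.

What the generators do **not** emulate — and hence what passing tests
cannot show about real data: classification error of the phenotype
assignments, between-replicate heterogeneity, boundary truncation and
anisotropy of real dispersal (real spore shadows are long-tailed and
tie-ridden from measurement rounding), and day-resolution germination
dynamics. The recovery experiment validates the fitter under its own
model, not the adequacy of the linear-probability model for real
crosses.

## Validation problem sizes

The suite enumerates all KS interleavings up to n1+n2 = 12; checks the
asymptotic-vs-exact agreement at n1 = n2 = 100 (within 0.005); matches
IRLS to a Nelder–Mead ML search to 1e−5 in θ on the packaged counts and
20 simulated tables; compares information-based SEs to a 20000-draw
parametric bootstrap within 2% (20000 draws keep the Monte-Carlo error
of a bootstrap sd near 0.5%); and runs the recovery experiment at 5000
progeny per cross × 200 replicates (|bias| < 0.01, Wald 95% coverage
within [0.93, 0.97]). Type-I error of the KS test is checked over 500
null pairs of n = 200.

## Known limitations

- The true design matrices of the original analysis are unknown;
  intermediate model statistics and parameter estimates are therefore
  reproducible only under this package's declared reconstruction.
- The exact KS tail assumes continuous (tie-free) data; with ties it
  refuses and the asymptotic series is used, which is slightly
  conservative at small n.
- The extreme-value tail treats the reference mean and variance as
  known constants, ignoring their sampling error, and assumes
  independence of the strain maxima.
- Penetrance and association operate on already-classified counts;
  classifier uncertainty is out of scope.
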