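# Methods

## The model

`marzic` performs causal mediation analysis when the mediator is one taxon
of a microbial composition: a relative abundance (RA) in [0, 1) that is
zero-inflated and measured through sequencing of finite depth.  For a
continuous outcome Y, scalar exposure X and one taxon's RA M, the model
couples three marginal equations:

- **Outcome:** Y = β₀ + β₁M + β₂·1(M>0) + β₃X + β₄·X·1(M>0) + β₅·X·M + ε,
  ε ~ N(0, δ²).  δ is a standard deviation.  The indicator terms let
  presence and abundance act as separate mediation channels; either or
  both interaction terms (β₄, β₅) can be excluded.
- **Mediator, abundance part:** M | M>0 ~ Beta(μφ, (1−μ)φ) with
  logit(μ) = α₀ + α₁X.  φ is the Beta precision (larger = tighter).
- **Mediator, presence part:** P(M = 0) = Δ with logit(Δ) = γ₀ + γ₁X.

A marginal (one-taxon-at-a-time) model is compatible with the
compositional constraint: if the full composition follows a Dirichlet
outcome model, the implied single-taxon regression has closed-form
coefficients (`marginal_coeffs`), which is also how the package's
property tests connect the two views.

## Effect decomposition

For an exposure contrast x₁ → x₂, plugging the three equations into the
potential-outcomes definitions gives closed forms:

- NIE1 = (β₁ + β₅x₂)·[E M(x₂) − E M(x₁)], with E M(x) = (1−Δ(x))·μ(x):
  mediation through the numeric abundance.
- NIE2 = (β₂ + β₄x₂)·[Δ(x₁) − Δ(x₂)]: mediation through the
  absence→presence switch.
- NIE = NIE1 + NIE2 (an identity, not an approximation).
- NDE = (x₂−x₁)·[β₃ + β₄(1−Δ(x₁)) + β₅·E M(x₁)];
  CDE = (x₂−x₁)·[β₃ + β₄·1(m>0) + β₅m] at a controlled level m.

The NDE/CDE closed forms follow from the same plug-in device as the NIE
decomposition; because they are easy to get wrong, the test suite
certifies every formula against a 10⁶-draw Monte-Carlo simulation of the
potential outcomes.  Identification rests on sequential ignorability (no
unmeasured confounding of the X–M and M–Y relations); that is an
assumption about the study design, not something the software can check.

## False zeros and the likelihood

An observed zero is either structural (the taxon is absent) or a
detection failure.  The detection model is a limit-of-detection (LOD)
rule: the observed RA M\* is zero exactly when M·L < 1, i.e. when the
expected read count (sample absolute abundance) falls below one read at
library size L.  Subjects therefore contribute in two ways:

- **Detected (M\* > 0):** a normal outcome density times the positive-part
  ZIB density.  Under the LOD rule a detected abundance always satisfies
  M\*·L ≥ 1, so the detection factor is identically 1; externally
  normalized tables can violate this, in which case the factor is still
  treated as 1 and a warning is emitted rather than returning −∞.
- **Observed zero:** a two-branch mixture.  The structural branch uses the
  outcome mean β₀ + β₃x (no indicator terms).  The false-zero branch
  integrates the joint density of (Y, M) over the undetectable window
  (0, 1/L).  The two branches are combined with a log-sum-exp so neither
  underflows.

### Quadrature

The false-zero integrand contains m^(μφ−1), which is singular at 0
whenever μφ < 1 — the typical case for rare taxa (e.g. μφ ≈ 0.10 in the
rare-taxon validation scenario).  The substitution m = (1/L)·u^(1/(μφ))
absorbs the singularity exactly, leaving a smooth integrand on [0, 1]
that a fixed 32-node Gauss–Legendre rule handles to near machine
precision.  Tests verify: agreement with adaptive quadrature to 1e−8
relative (including the μφ = 0.1 case), agreement with the incomplete-Beta
closed form when all outcome coefficients vanish, 32-vs-128-node
agreement to 1e−9, and that the full two-group density integrates to
total probability 1 (to 1e−6).  The upper limit is capped at
min(1/L, 1−1e−12).

## Estimation

Maximum likelihood over the canonical parameter vector (β₀..β₅, δ, α₀,
α₁, φ, γ₀, γ₁).  Choices that matter:

- **Unconstrained reparameterization:** δ = exp(s), φ = exp(t), so
  quasi-Newton steps cannot leave the parameter space and no boundary
  standard errors arise.  A test confirms the transform does not move the
  optimum relative to bounded optimization on the original scale.
- **Scaling:** optimization variables are divided by max(1, |initial|);
  without this, a rare-taxon abundance slope of ~100 conditions the
  problem badly and roughly triples the fit time.
- **Gradients** are central finite differences (relative step 1e−6); the
  quadrature inside the likelihood makes analytic derivatives
  error-prone, and the observed-information oracle tests bound the
  finite-difference error instead.
- **Starting values:** least squares for β and δ; logit-scale regression
  and Beta method-of-moments for α and φ; ridge-stabilized logistic
  regression of the zero indicator for γ.
- **Convergence:** L-BFGS-B with gradient tolerance 1e−6, up to 3
  jittered restarts.  A line-search abort at a point whose gradient
  infinity-norm is below 1e−3 is accepted as converged; with numerical
  gradients such aborts are almost always spurious.
- **Degenerate data:** a taxon with no zeros cannot identify Δ (the
  likelihood monotonically pushes it to 0), so γ₀, γ₁, β₂, β₄ are dropped,
  the presence effect is reported as exactly 0 with zero SE, and the fit
  reduces to Beta regression plus a linear model — verified against an
  independently optimized stand-alone Beta likelihood.  A taxon absent
  everywhere is an error; constant exposure is an error.

The observed Fisher information is the negative central-difference
Hessian (relative step 1e−4, symmetrized) on the **original** scale,
because the delta-method effect gradients are taken there.  It is checked
against step-halving and against the closed-form X'X/δ² block of the
zeros-free linear model.

## Inference

Delta-method standard errors: se(g) = √(∇g' I⁻¹ ∇g) with
finite-difference ∇g, Wald intervals, and two-sided normal p-values (the
natural companion of the delta method).  An effect whose gradient is
structurally zero gets se = 0 and p = 1.  A nonparametric case-resampling
bootstrap (percentile intervals) is provided as an alternative; a test
requires the two methods to agree on the NIE scale within 25% on a
well-behaved dataset.  The information matrix must have condition number
below 1e12, otherwise the error names the most degenerate parameter
direction.

## Screening

`screen_taxa` fits every taxon of a composition table, collects NIE1 and
NIE2 p-values, and applies Benjamini–Hochberg separately to the two
families (they are distinct detection tasks with separate
recall/precision accounting; a single pooled family is available by
adjusting the returned raw p-values directly).  Taxa that are absent
everywhere, have fewer than 5 positive observations (below which the ZIB
likelihood is routinely ill-conditioned), or fail to converge are flagged
and excluded from the family size, so untestable hypotheses do not dilute
the adjustment.  Confidence intervals are reported unadjusted; only the
significance flags use the FDR.  The default target FDR is 20%.

Default exposure contrast is (0, 1) — the binary-exposure convention of
the validation designs — and the controlled mediator level for the CDE
defaults to 0 (absence).

## Synthetic data

### Univariate ZIB design (`simulate_setting1`)

Emulates a study of n subjects: X ~ Bernoulli(0.5); library sizes
log-uniform over [31,607, 911,652] reads (the depth range of the
motivating mouse study; an empirical list of depths can be supplied
instead); M from the ZIB model; Y from the outcome equation using the
**latent** M — false zeros corrupt only the observed mediator, which is
precisely why methods that ignore detection failure are biased here.
The printed generating truth (`table1_params`) has β = (−2, 100, 4, 5, 3,
0), δ = 1, α₁ = 0.4, φ = 50, γ = (−1.16, −0.5), with α₀ = −6.2 (rare
taxon, mean positive RA ≈ 0.0025) or −1.0 (abundant taxon).  Under the
rare scenario these values yield ≈20% structural zeros and ≈30% false
zeros of all observations; the abundant scenario has no false zeros
(every positive RA exceeds the detection limit).  Both fractions are
asserted in tests.

Because the generating β₅ is 0 and the reported parameter set of the
univariate design does not include an abundance interaction, the analysis
model for this design also excludes β₅ (`SETTING1_INTERACTIONS`).

### Composition design (`simulate_setting2`)

A zero-inflated Dirichlet-multinomial generator: per subject, presence
indicators for designated zero-inflated taxa (logit-linked in X), a
Dirichlet draw over the present taxa, multinomial counts at the library
size, and RA = counts/depth (so rows close to 1 exactly).  The outcome
depends on the first two taxa: Y = 1 + 80·M₁ + 2·M₂ + 3·1(M₂>0) + X +
X·1(M₂>0) + X·M₂ + ε with standard-normal ε.

The default five-taxon configuration targets mean RAs (0.196, 0.250,
0.220, 0.146, 0.188).  Design problem: if an absent taxon's mass were
simply renormalized over the others, every taxon's marginal mean would
depend on X through taxon 2's presence, and taxa 3–5 would genuinely
mediate.  Instead, an absent taxon's concentration mass is absorbed by
taxon 1 (an ecological competitor filling the niche).  Then taxa 3–5 have
exposure-independent marginal means *exactly*, taxon 2 mediates through
both presence and abundance, and taxon 1 mediates through the mass it
absorbs — matching a design in which only the first two taxa carry
mediation signal.  Shares are solved in closed form from the mean targets
(`five_taxon_concentrations`), so the target means are hit exactly in
expectation; truth labels are computed analytically by presence-pattern
enumeration, not asserted by hand.

Two generator parameters are not determined by any printed value: the
presence split (absence 0.28 at x=0 vs 0.03 at x=1) and the total
Dirichlet concentration (50, a realistic overdispersion for deeply
sequenced stool profiles).  They were chosen, once, so that the design
carries the clearly detectable taxon-1/taxon-2 mediation signals the
validation results describe; with the printed means, outcome coefficients
and n = 200, the taxon-2 abundance-path z-statistic is structurally
capped near 3 regardless of dispersion, so recall for the abundance task
plateaus around 0.90–0.95 — the neighborhood of the design's reported
performance.  The screening analysis model for this design excludes both
exposure–mediator interactions (`SETTING2_INTERACTIONS`): with them
included, collinearity among M, 1(M>0) and their X-interactions inflates
the effect variances substantially under this generator.

### What the generators do not emulate

Real 16S/shotgun data have taxon-specific extraction and amplification
bias, longitudinal and spatial structure, many more taxa than subjects,
non-normal outcomes, and confounding; the generators have none of these.
Passing the validation studies therefore shows correctness of the
estimator and its inference under the stated models and robustness to the
composition/zero-mechanism mismatch between the two designs — not
performance guarantees on arbitrary real studies.

## Validation studies and problem sizes

`marzic.validation` packages the two replicated studies used by the tests
and the reproducibility script: 100 rare-taxon datasets (n = 200) fitted
by full MLE with 95% delta-method intervals (coverage, bias, SE
calibration), and 100 five-taxon compositions (n = 200) screened at BH
FDR 20% (recall/precision per mediation channel).  These sizes mirror the
validation designs themselves; both studies complete in a few minutes on
one core.  Replicate seeds are spawned from a single base seed via
`numpy.random.SeedSequence`, so every study is reproducible from one
integer.

## Known limitations

- One scalar exposure; no covariate/confounder adjustment (the closed
  forms extend, but the implementation does not).
- The LOD threshold is fixed at one expected read; alternative detection
  mechanisms (e.g. exponential in the expected count) and
  information-criterion selection between them are extension points, not
  features.
- Delta-method intervals are first-order; for very small n or boundary
  parameters the bootstrap is the safer choice.
- The false-zero integral assumes the library size is the true sampling
  depth of the normalized counts; tables normalized by other pipelines
  weaken that interpretation.
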