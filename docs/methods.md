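# Methods

## Setting and null hypothesis

A fuzzy RD design with sequential assignments records, for each subject, a
running variable X, discrete covariates, an outcome Y, and K binary
treatment statuses Z₁..Z_K set by successive decision-makers: Z₁ = 1{X on
the eligible side of the cutoff c} (ties at c count as eligible), and each
later Z_k decided among those treated at the previous levels.  Under
one-sided compliance the statuses are nested (Z_k = 1 forces Z_{k−1} = 1,
so only the K+1 nonincreasing patterns occur); under two-sided
non-compliance a subject may be treated at level k despite a prior status
0.

The target is the sharp null of no treatment effect: all potential
outcomes Y(z̄) coincide for every subject.  Under the exclusion restriction
(the status vector affects Y only through the final status Z_K) each of
the K comparisons below tests this same null.

Two causal assumptions carry the construction: the statuses are causally
ordered, and no unmeasured common causes link the assignment levels to
each other.  Neither is testable from data; `validate_design` reports the
testable structure (status-pattern cells, per-factor arm sizes) and
surfaces the untestable part as a warning.

## Evidence factors

- EF 1: all subjects inside the window W, assignment Z₁ — the
  intent-to-treat RD comparison under local randomization.
- EF k ≥ 2: subjects with Z₁ = … = Z_{k−1} = 1, assignment Z_k, no window.
  Under two-sided compliance EF 2 therefore drops every ineligible subject
  (whatever their later statuses) and keeps eligible subjects outside the
  window.  Variation of Z_k among subjects with a prior status 0 is never
  used: those assignment mechanisms are unmodeled "exceptions".

Conditioning on the earlier statuses is what isolates biases: an
unmeasured covariate distorting assignment at level j is held fixed (at
value "treated") in every factor k > j, so its bias cannot propagate.  The
unconditioned benchmarks (level k compares Z_k = 1 vs 0 over all subjects;
level 1 coincides with EF 1) deliberately lack this protection and are
used in the simulation study to demonstrate bias spillover.

A factor whose strata never contain both arms is flagged degenerate and
carried with p = 1 — conservative, and batch simulations must not crash.

## Test statistic and randomization inference

Each factor uses the stratified two-sample Wilcoxon rank-sum statistic:
within every stratum containing both arms, outcomes are mid-ranked and the
treated rank sum accumulated; strata without assignment variation
contribute zero.  (The rank-sum rather than signed-rank form is used
because each factor compares two independent arms; there are no matched
pairs to difference.)  The null distribution permutes the assignment
within strata with treated counts fixed, outcomes held fixed — justified
by the assignment models in which, absent unmeasured bias, assignment
probabilities are constant within a stratum, making the conditional law
uniform over equal-count assignments.  One-sided p-values use the add-one
Monte-Carlo estimator (1 + #{T* ≥ T_obs})/(n_perm + 1), which is valid at
any finite number of draws and never exactly zero; 'less' alternatives are
handled by negating outcomes, which maps mid-ranks onto their mirror.  An
exact-enumeration oracle (product of per-stratum assignment spaces, capped
at 10⁶) verifies the Monte-Carlo path on small comparisons; its p-values
are ratios of integers.

## Window selection and residualization

The level-1 window is the largest symmetric candidate (c − w, c + w) whose
covariate balance survives a randomization test: for each covariate, a
two-sided difference-in-means p-value under free permutation of
eligibility within the window, summarized by the minimum across covariates
and compared against the balance threshold (default 0.15).  Free rather
than within-stratum permutation is used because the covariates under test
are the very ones the strata would be built from.  If no candidate passes,
the search fails loudly; there is no silent fallback.

EF 1 uses the outcome residualized on the running variable (ordinary least
squares, intercept and slope).  The regression is fitted on the **full
sample** and the residuals then used inside the window.  Fitting inside
the window instead would force the residuals orthogonal to X over exactly
the comparison sample; because Z₁ is a threshold function of X, that
orthogonality mechanically shrinks the variance of the treated−control
residual contrast far below the permutation-null variance (to roughly 40%
in the simulated designs) and makes the EF-1 test severely conservative —
a finite-sample residual-randomization artifact of the Freedman–Lane type.
The full-sample fit dilutes the constraint (variance ratio ≈ 0.9) and
restores near-nominal levels, which the simulation study confirms.
Residual randomization remains asymptotically, not exactly, valid; this is
a known limitation of residualized outcomes in randomization tests.

## Combining the q largest p-values

q is the conjectured minimum number of valid factors.  The K − q smallest
p-values are discarded and Fisher's statistic H = −2 Σ log p over the q
largest is referred to χ²₂q — the null law of H on q independent uniforms.
Validity: if at least q factors are valid, the j-th smallest retained
p-value is at least the j-th smallest p-value among the valid q (adding
numbers to a multiset can only raise its order statistics), so H is
stochastically no larger than Fisher's statistic on q valid p-values, and
the χ²₂q tail is a valid p-value however the other K − q behave.  When all
K factors are valid the procedure is conservative — the price of
discarding small p-values.  Referring H instead to the null of the q
largest *order statistics* of K uniforms would be exact at q = K but
anticonservative precisely when a discarded factor is biased toward zero
(simulated size 0.23 at nominal 0.05 for q = 2 of 3 with one p ≡ 0), so it
is not offered.  The truncated product statistic W = Π p^{1(p ≤ τ)} over
the retained p-values is referred, by the same dominance argument, to a
seeded Monte-Carlo null under q independent uniforms (default 10⁵ draws;
standard error ≤ 0.0016 near p = 0.5).  Ties at the retention boundary are
broken by sorted position with stable index order.  Degenerate factors
enter the combination as p = 1.

## Sensitivity analysis

The biased assignment model lets two subjects in the same stratum differ
in their odds of level-k assignment by at most Γ_k = exp(γ_k) ≥ 1 through
a per-subject unmeasured covariate u ∈ [0,1].  For a fixed binary u the
conditional law of the treated set (treated counts fixed) is exponentially
tilted, P(A) ∝ Γ^{Σ_{i∈A} u_i}.  The bound maximizes the one-sided tail
over u; for a one-sided greater alternative the maximum over [0,1]ⁿ is
attained at a binary u equal to 1 on the units with the largest
within-stratum rank scores.  The class size b per stratum is chosen to
maximize the expected statistic under the tilt (ties resolve to the
smallest b; at Γ = 1 the mean is free of b, b = 0 results, and the tilted
law is exactly the uniform randomization law).  Across strata the
maximization is separable and done per stratum — the standard
asymptotically-separable approximation for stratified sum statistics.

Sampling exploits the binary u: the number of treated units in the u = 1
class follows Fisher's noncentral hypergeometric distribution with odds Γ,
and the units within each class are uniform draws.  The count is sampled
by inverse-CDF on uniforms generated before any per-stratum permutations,
and the within-class choices come from one shared permutation stream per
stratum, so runs at different Γ with the same seed share random numbers
and the sampled statistics are pathwise nondecreasing in Γ for a fixed
class size; p-value bounds are therefore monotone in Γ up to (small)
Monte-Carlo noise, exactly monotone on the exact-enumeration path.  Small
comparisons (enumeration space ≤ 10⁵) use exact tilted enumeration by
default.  At Γ = 1 the Monte-Carlo bound reproduces the unadjusted
randomization p-value draw for draw.

## The simulator

The generator emulates the benchmark study designs rather than any real
dataset.  Per subject: covariate C ~ Binomial(2, ½); running variable
X = 0.5 (C − 1) + N(0, 1); eligibility Z₁ = 1{X ≥ 0} at cutoff 0.  The
unmeasured covariates are binary: U₁ is a mediator of eligibility,
U₁ | Z₁ ~ Bernoulli(0.3 + 0.4 Z₁) with potential values monotonically
coupled; U₂, U₃ are fair coins.  Sequential assignments (Design 1, K = 3,
one-sided): Z₂ among eligible with logit 0.2 + 0.4(C − 1) + (U₂ − ½), Z₃
among level-2 takers with the same form in U₃, and Z_k = 0 whenever a
prior status is 0.  Design 2 (K = 2, two-sided) draws Z₂ for everyone with
logit −1.2 + 2.2 Z₁ + 0.4(C − 1) + (U₂ − ½), so all four status patterns
occur (≈ 23% treated among ineligible).  Outcomes:
Y(z̄) = λ₁ U₁(z̄₁) + λ₂ U₂ [+ λ₃ U₃] + effect·z̄_K + N(0, 1).  λ_k is the
outcome coefficient of U_k: λ₁ ≠ 0 breaks the exclusion restriction of
eligibility (a Z₁ → U₁ → Y path that window selection cannot remove),
λ₂, λ₃ ≠ 0 confound levels 2 and 3.  The seven Design-1 cases toggle which
λ are nonzero (none; each singly; each pair), nonzero values defaulting to
1 — a strong bias, shifting the outcome mean by ≈ 0.4 SD between
comparison arms.  All coefficients are exposed as `DGPCoefficients`
parameters.

Two deliberate features: the outcome has **no direct X → Y trend by
default** (eligibility is deterministic in X, so any direct trend would
bias the unconditioned as-treated benchmarks even with every λ = 0,
whereas the study design requires all comparisons valid in the no-bias
case; a `y_slope` parameter switches the trend on for other uses), and the
effect enters only through the final status.

What passing simulations do not show: the generator has a single
three-level covariate (real tables have many, with sparse strata), exact
compliance with the assumed assignment models, no missing data, and
continuous outcomes without heavy ties.  Validity on real data still
rests on the untestable causal assumptions above.

## Study profile and numerical choices

The rejection-rate study uses n = 500 subjects, 500 replicates, 400
permutation draws per test, and a fixed level-1 window (−1, 1) (window
re-selection per replicate is available behind a flag; the fixed window is
the package's default study profile because the study targets test
validity, not window choice).  q follows the correctly-specified rule
q = K − #{k : λ_k ≠ 0}, applied to the EF and unconditioned combinations
alike.  Replicate seeds derive from a root seed via `SeedSequence`
spawning, so studies are reproducible and embarrassingly parallel.  Other
defaults: n_perm = 2000 for single analyses, combination null draws 10⁵,
Γ grid {1, 1.1, 1.2, 1.5, 2} per level, enumeration caps 10⁶ (oracle) and
10⁵ (sensitivity exact path).  Floating-point tail comparisons use a 10⁻⁹
slack on rank-sum scales; exact enumeration doubles mid-rank scores into
integers.

## Known limitations

The method tests the sharp null only — no effect sizes or confidence
intervals.  Ordinal running variables need a user-supplied continuous
surrogate.  Covariates must be discrete (pre-bin continuous ones);
exact stratification with many covariates can leave most strata
uninformative, costing power.  The dilution of later factors by
never-takers in the treated comparison arm can depress power; robust
dilution-resistant statistics are not implemented.  The q-of-K combination
is conservative when more than q factors are valid.
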