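# Methods

This note documents the statistical model behind each stage, the numerical
conventions, the synthetic-data generative model, and the design choices
made where more than one defensible option existed.

## Edge-wise GLM and the network-based statistic

Each connectome edge (Fisher-z connectivity value) is regressed on the
outcome with nuisance covariates:

    edge_e = b0 + b1 * outcome + b2 * age + b3 * sex + b4 * meanFD + error

The reported statistic is the t value of `b1`, with
df = n − (covariates + 2).  This t is algebraically identical to the
partial-correlation t between edge and outcome given the covariates; the
test suite verifies the identity against an independent
residualize-then-correlate oracle and against statsmodels OLS to 1e-10.
The fit is computed for all edges at once via the normal equations (one
`p x p` inverse, one `p x m` matrix product), because the permutation loop
evaluates it thousands of times.

Edges with |t| above the primary threshold (default 3.50) form a graph on
regions; its connected components are the candidate subnetworks.
Components are formed on the pooled graph (positive and negative
suprathreshold edges together) and reported with a sign profile; a
`component_mode="by_sign"` option splits them.  Component "size" is edge
count (extent) by default; an intensity measure (sum of |t| − threshold)
is available.

Family-wise error control: the outcome vector is permuted across subjects
(covariates stay attached to their subjects), the GLM and component
extraction are recomputed, and the maximal component size per permutation
forms the null distribution.  For an observed component of size s,

    p_fwe = (1 + #{permutations with max size >= s}) / (1 + B)

with B the number of permutations — the add-one estimator never returns 0
and counts ties in favor of the null.  An exhaustive mode enumerates all
n! orderings for small n and reports the exact proportion (the identity
ordering is included, so p > 0); the test suite checks exact agreement
with a brute-force enumeration at n = 7 (5040 orderings).

Two permutation schemes are provided, because the choice is not settled
for this design: `simple` (shuffle the outcome, default) and
`freedman_lane` (refit the outcome on covariates, permute its residuals,
add back the fitted nuisance part).  With covariates that are nearly
independent of the outcome — the regime of both the synthetic generator
and the motivating study — the two are practically equivalent.

Default parameters: |t| > 3.50 primary threshold, 10 000 permutations,
corrected alpha 0.010.

## Strengths and hubs

Node strength is the sum of |t| over a region's incident component edges
(hence total node strength = 2 x total edge |t|, the handshake identity,
asserted in tests).  Absolute values are used deliberately: an
all-negative component still yields positive, comparable strengths.
Regions are ranked by strength with ties broken by degree then index;
"provincial hubs" are reported descriptively as the top-ranked regions
with degree > 10 — no inferential test is attached.  Within-network links
join two regions of the same canonical network; all others are
between-network, keyed by the unordered network pair.  Possible-link
totals derive combinatorially from the partition sizes:
within = sum_k n_k(n_k−1)/2, between = R(R−1)/2 − within.

## Cross-validated prediction

The single feature is the mean connectivity over the identified
component's edges.  Per repeat, subjects are randomly assigned to 10
balanced folds; an intercept-plus-slope OLS is fit on the training folds
and applied to the held-out fold.  Predictions are correlated with the
actual outcomes **within each held-out fold** and the per-fold r values
averaged; the final statistic is the mean over 100 repeats.

Per-fold averaging, rather than one correlation over the pooled
out-of-fold predictions, is a deliberate choice: the pooled statistic is
negatively biased under the null hypothesis (about −0.17 at n = 100 with
10 folds in our simulations), because each fold's fitted intercept is the
training mean, which anticorrelates with the held-out outcomes.  Per-fold
averaging is centered at zero under the null and recovers the population
correlation under signal (planted r = 0.5 gives mean CV r about 0.48).
The pooled convention remains available via `CVConfig(pooling="pooled")`
and a regression test documents the bias difference.

The permutation p value reruns the *entire* repeated-CV procedure on
outcome-permuted data: p = (1 + #{null r >= observed}) / (1 + B).  Each
null iteration uses a reduced repeat count (default min(repeats, 10),
configurable via `n_null_repeats`) — the null mean is insensitive to the
repeat count, and rerunning 100 repeats inside 5000 permutations would be
wasteful.

Two known caveats are reproduced faithfully rather than hidden: the
component is identified on the **full sample** before CV (the original
design), which makes the CV r optimistic; `nested_cv_predict`
re-identifies the component inside each training fold for an honest
benchmark.  Covariates are *not* residualized out of feature or outcome by
default (matching the design this package implements); `residualize=True`
enables it.

## Mediation

With X the brain feature, M the mediator and Y the outcome (each
standardized to unit variance; covariates left raw and present in every
equation):

    M = i1 + a X + Z g1 + e1
    Y = i2 + c' X + b M + Z g2 + e2
    Y = i3 + c X + Z g3 + e3

The indirect effect is a·b, which equals c − c' exactly for OLS with a
shared covariate set — asserted to 1e-10 on every fit.  The CI is a
subject-level (case-resampling) nonparametric bootstrap, percentile method
by default (5000 draws); a bias-corrected variant is available via
`ci_method="bc"`.  Percentile was chosen as the default because the
bias-corrected variants differ across implementations while the percentile
interval is unambiguous; coverage of the percentile CI under a zero-b
generator is verified empirically (93–97% band) in the acceptance suite.
Degenerate bootstrap draws (a resampled variable becomes constant) are
redrawn with bounded retries.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; it
is the package's test bed, not a biophysical simulator.  Per subject, a
latent brain factor g ~ N(0,1) drives a standardized chain:

    mediator   m = a g + sqrt(1 - a^2) eps_m           Var(m) = 1
    outcome    y = c' g + b m + sum_k gamma_k z_k + s_y eps_y,  Var(y) = 1

with s_y solved from the unit-variance constraint
(s_y^2 = 1 − c'^2 − b^2 − 2abc' − sum gamma^2; configurations that leave
no residual variance are rejected).  Because the chain is standardized,
OLS on the latents recovers a, b, c' directly as standardized
coefficients and the population indirect effect is exactly a·b — the
property the mediation recovery tests exploit.

Planted edges carry w = beta·g + noise_sd·eps; all other edges are pure
noise.  Since w is independent of y given g, corr(w, y) factors as
corr(w, g) · corr(g, y) with corr(g, y) = c' + ab, so beta solves in
closed form for a target edge-outcome correlation rho:

    q = rho / (c' + ab),   beta = noise_sd * q / sqrt(1 - q^2)

which requires |rho| < |c' + ab|; infeasible targets raise at config time.
The planted edges are sampled as a connected subgraph (random recursive
tree plus extra edges) so that recovery can be scored against a single
component.

Defaults and why:

* `n_subjects=100`, `n_regions=136`, partition (24, 22, 20, 18, 18, 17, 17)
  over DMN/CEN/VAN/DAN/AFN/SMN/VN, `effect_edges=70` — the scale of the
  motivating study design.
* `effect_rho=-0.3` — no per-edge effect size is published for this
  design; −0.3 sits in the range of reported brain-feature/outcome
  correlations (|r| 0.26–0.41) and is negative so that weaker connectivity
  predicts worse distress change, matching the all-negative component
  phenotype.  It is a free parameter of the generator, not an estimate.
* `path_a=0.5, path_b=0.4, path_c_prime=0.6` — a partial-mediation regime
  (indirect 0.20, direct 0.6) with corr(g, y) = 0.8, leaving headroom for
  edge-outcome correlations up to that bound.
* `covariate_effects=(0, 0, 0)` — age, sex and motion are drawn but do not
  load on the outcome by default, mirroring a design in which the outcome
  was uncorrelated with all three; the analysis still adjusts for them
  everywhere.
* Demographics: age ~ N(22.4, 2.1), sex ~ Bernoulli(0.58), mean FD
  ~ |N(0.12, 0.04)| — cosmetic, shaped after a young-adult cohort.

Phenotype scores are affine maps of the latents (ΔDistress = 8·y distress
points; mediator score 40 + 15·m) and are deliberately **not** truncated
to instrument ranges: truncation would break the exact affine-invariance
and calibration properties the tests rely on.  Consequently synthetic
scores can stray outside questionnaire bounds; they are continuous
analogs, not simulated item responses.

Two generation modes: direct-matrix (default; edge table is the object of
analysis, fastest, no approximation) and time-series (per-subject
multivariate normal series whose population correlation is the subject's
target matrix after positive-definite repair: eigenvalues clipped at 1e-6,
diagonal renormalized to 1).  The repair perturbs strongly non-PD targets,
so in time-series mode the effective population matrix is the repaired
one; the corresponding test compares rebuilt connectomes against the
repaired target.

What the generator does **not** emulate: hemodynamics, autocorrelated
BOLD noise, spatial structure of parcels, site/scanner effects,
item-level questionnaire behavior, and motion-connectivity coupling.
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under its stated assumptions, not that the pipeline is
robust to these real-data complications.

## Motion QC

Power's framewise displacement with a 50 mm head radius:
fd[0] = 0, fd[t] = sum |Delta translation| + 50·sum |Delta rotation|
(rotations in radians; a flag accepts degrees).  Exclusion at mean
FD > 0.25 mm; scrubbing flags volumes with FD > 0.50 mm.  Only the
flagged volume is removed by default — neighbor augmentation (common in
some pipelines) is available via `scrub_neighbors` but off, as the
simplest defensible rule.

## Scales

Totals are raw item sums; the DASS-21 total is not doubled to the DASS-42
scale because only differences and correlations of totals enter the
analysis and both are invariant to rescaling.  ΔDistress = T1 − T3 (so
*increased* distress is negative); `Cohort.outcome()` exposes a
`convention` switch because downstream correlation signs flip with the
convention and users should choose explicitly.  CPTS is the raw sum of the
IES-R and PCL-5 totals.  The one-factor check eigen-decomposes the
subscale correlation matrix and applies the Kaiser rule (only the first
eigenvalue > 1).  Missing items are an error, never imputed.

## Numerical conventions and degenerate inputs

* Edges are the strict upper triangle in lexicographic (i, j) order,
  0-based; vectorize/devectorize round-trips are bit-exact.
* Connectome diagonals are 0 (self-connections are never analyzed);
  |r| = 1 between two regions is an error (atanh diverges; on real data it
  signals duplicated regions), not a clamp.
* Constant edges get t = 0 with a warning; constant outcomes, constant
  scale columns, rank-deficient designs and too-small samples raise.
* All randomness flows from explicit seeds through
  `numpy.random.SeedSequence`; the pipeline's global seed spawns
  independent per-stage seeds, and identical configurations reproduce
  byte-identical outputs.

## Test scales

The calibration and coverage suites run at reduced problem sizes chosen to
keep the default test run fast while leaving the statistical claims
meaningful: FWE calibration on 200 null cohorts of 60 regions x 60
subjects at 500 permutations; component recovery on 50 replicates of 60
regions x 150 subjects at 1000 permutations; CV null calibration on 100
cohorts of n = 100 at 5 repeats and 199 null permutations per cohort;
bootstrap coverage on 300 datasets at 1000 draws.  The acceptance script
runs the full pipeline at study scale (100 subjects, 136 regions, 10 000
NBS permutations, 5000 CV null permutations, 5000 bootstrap draws).

## Known limitations

* The synthetic generator's simplifications listed above.
* The full-sample component selection before CV reproduces the original
  design's optimism; use `nested_cv_predict` for unbiased estimates.
* The mediation model is the standard linear two-equation system; it
  estimates an indirect association, and supports causal claims only under
  the usual untestable no-unmeasured-confounding assumptions.
* Exhaustive permutation mode is limited to n <= 9 subjects.
* The within/between possible-link split for a real atlas depends on the
  user-supplied membership table; the package validates totals but cannot
  derive a specific atlas's partition.
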