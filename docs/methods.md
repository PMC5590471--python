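# Methods

## Model and estimators

The package works with the pseudo-steady-state balance `S v = 0` for m
metabolites and n reactions, partitioned into measured exchange fluxes
`v_E` (with per-measurement standard deviations) and unknown internal
fluxes `v_I`, giving the regression `y = X b + e` with `y = -S_E v_E` and
`X = S_I`. Estimation requires `X` to have full column rank; rank is
decided from singular values with the threshold
`max(shape) * eps * s_max` (overridable, because curated MFA models often
contain near-collinear lumped reactions).

Sign convention: matrix columns are reactions, a positive coefficient means
production of the row metabolite. Exchange fluxes enter only through
`y = -S_E v_E`, so no additional sign flips appear anywhere else.

OLS and GLS fits are computed through a QR decomposition rather than the
normal equations (the explicit formulas remain the documented contract and
the test suite verifies agreement to 1e-10 or better). For GLS the problem
is whitened with the lower Cholesky factor of the error covariance; the
estimate covariance is `(X' C^-1 X)^-1` with `C` taken as known, while the
OLS covariance uses the unbiased residual variance `SSE/(N-K)`.

**Error covariance and the variance floor.** The covariance of the balance
residuals propagated from the measurements is `S_E diag(sd^2) S_E'`. Rows
with no measured-flux contribution (pure internal balances) have zero
variance, making the matrix singular. Each such row receives a floor of
`1e-6 x` the smallest "real" variance, which approximates treating those
balances as hard constraints while keeping a single GLS code path.
Variances smaller than `1e-12 x` the largest are treated as zero for this
purpose: a measured flux that happens to be numerically zero would
otherwise define a floor of order machine epsilon squared and destroy the
conditioning of the whitening transform. If the floored matrix is still
not positive definite (possible when two balance rows are perfectly
correlated through a single measurement), the floor is added to the entire
diagonal. How the original CHO-style analyses handled this singularity is
not documented anywhere we know of; the floor is this package's choice and
its size is configurable.

**Significance-of-regression ANOVA.** The model has no intercept (y is a
balance residual with no natural mean term), so the overall F test uses the
uncentered decomposition `SST = y'y`, `F = (SSR/K)/(SSE/(N-K))`, on the
whitened scale for GLS fits. Exact fits (SSE below 1e-12 of SST) are
reported as p = 0 with a flag rather than dividing by zero.

## Misspecification diagnostics

**Bias of omitted reactions.** `bias = (S_I'S_I)^-1 S_I'S_O v_O`, computed
by least squares on `S_O v_O` (whitened for the GLS variant). Relative
bias in percent uses a caller-supplied reference flux vector; entries whose
reference is numerically zero (below 1e-9 of the largest reference flux)
are reported as undefined and excluded from the min/median/mean/max
summary. The test suite verifies the formula against the Monte-Carlo mean
of 50,000 misspecified fits.

**RESET test.** The design is augmented with elementwise powers
`yhat^2 ... yhat^(p+1)` of the base fitted values; the statistic compares
the two SSEs and is referred to `F(p, N-K-p)`. Fitted values are divided
by `max|yhat|` before exponentiation — the statistic is scale invariant in
exact arithmetic, the scaling only prevents overflow for fluxes of order
several hundred. Power columns that are numerically collinear with the
design raise an error advising a lower order.

**F test.** Extra-sum-of-squares statistic for a candidate block Z;
`[X Z]` must have full column rank (violations raise an error naming the
dependent candidate columns, never a silent zero statistic). The statistic
depends only on the column space of Z (verified by invariance under
invertible recombination).

**LM test.** Z is residualized against the intercept-augmented design
`[1 X]` exactly as the reference formula prescribes, although the flux
model itself has no intercept; `K` counts the columns of X only in all
degrees-of-freedom formulas. The weight matrix is `Omega = diag(e_i^2)`
from the base OLS residuals and the statistic includes the
`(N-K)/(N-K-o)` factor (a scalar, so its placement inside or outside the
inverse is numerically irrelevant). When `Zc' Omega Zc` loses rank — which
happens when residuals are exactly zero on balance rows orphaned by a
removal — the statistic is evaluated with the Moore–Penrose pseudoinverse;
the score vector provably lies in the range of the weight matrix, so the
value is exact. A hard error is reserved for an identically zero weight
matrix.

**Exact-fit guard.** All three tests return a zero statistic (no evidence
of misspecification) when the base model already fits to within 1e-12 of
`y'y`. Without this, noise-free data would produce 0/0 statistic ratios
whose floating-point value is arbitrary — in particular, the resolver on
noiseless data would keep "detecting" decoys after repairing the model.

**Decision rule.** Rejection follows the printed critical-value comparison
(strict `>` for RESET, `>=` for F and LM); p values are reported alongside
and agree with the decision almost surely since ties have probability
zero. Default significance level: a = 0.05 throughout.

**Raw versus whitened application.** Tests on a problem carrying an error
covariance are applied to the whitened problem (with Z whitened by the
same factor). The simulation harness, however, deliberately applies the
tests to the *raw* OLS problem: with flux-proportional noise that is the
regime in which the RESET test's constant-variance assumption fails, which
reproduces the qualitative test ranking observed on such data (F robust,
RESET unreliable, LM intermediate). A `whiten=True` flag switches modes;
note that at 1% noise the whitened design can fail the numerical rank
check, because the variance floor makes the unmeasured-balance rows
dominate the whitened matrix by three orders of magnitude.

## Iterative model repair

Given a candidate pool, each iteration F-tests (or LM-tests) every k-tuple
of remaining candidates against the current design. "Promote the passing
combination(s)" is ambiguous when passing tuples overlap, so the default
policy promotes greedily in descending-statistic order within the
iteration — skipping tuples that share a member with an already-promoted
tuple or would break full column rank — and then re-tests everything in
the next iteration; `promotion="best_only"` promotes a single tuple per
iteration instead. Ties on the statistic break lexicographically by
candidate id for reproducibility. Tuples violating the rank precondition
are skipped with a logged notice. No multiple-testing correction is
applied by default (a Bonferroni-over-tuples option exists but is off),
matching the plain-threshold usage the procedure was designed with. The
tuple-size schedule defaults to `[1]`; `[1, 2]` runs singles to exhaustion
and then pairs, which recovers more omitted reactions at the cost of more
wrongly included extras. Termination is guaranteed: each iteration either
strictly shrinks the pool or stops the current k.

## Synthetic data generator

The generator emulates the random-network study design and doubles as the
package's test fixture factory.

* **Stoichiometry.** Each reaction column receives 2–4 participating
  metabolites chosen uniformly, coefficient magnitudes from {1, 2}, random
  signs with at least one substrate and one product. Columns are drawn
  independently; any metabolite left untouched then receives one extra
  entry in a random column with spare capacity (pure rejection sampling on
  full coverage has vanishing acceptance at 200 metabolites), and the
  whole matrix is resampled if it is not full column rank. Everything is a
  pure function of the seed.
* **Exchanges.** The first `m_E` metabolites are the measured species:
  `S_E = [I; 0]`, so the noise-free response is `y = [S_I,E v_I; 0]`.
* **Fluxes.** `v_I = B c` with B an orthonormal null-space basis of the
  unmeasured-row block `S_I,NE` and c uniform on (-1, 1), so the
  intracellular-only balances close exactly.
* **Noise.** Gaussian, zero mean, standard deviation `CoV x |y_i|` on the
  measured rows (a stated coefficient of variation, the defaults spanning
  1–20%); zero-valued noise-free entries receive no noise, which differs
  from additive-floor noise models. A homoscedastic variant (constant sd
  `CoV x mean|y|`) reproduces the regime where the RESET test is reliable.
* **Scenarios.** Omitted-reaction instances remove a uniform random column
  subset (removal cannot reduce column rank); decoy candidates are fresh
  columns from the same sparsity model, never equal to a true column, with
  `[X_reduced Z]` kept at full column rank. Independent named seed streams
  (network, fluxes, noise, removal, decoys) are spawned from one seed.

**What the generator does not emulate.** Real metabolic networks have
pathway structure, conserved moieties, heavy-tailed degree distributions
and thermodynamic constraints; the generator has none of these. One
consequence matters for interpreting detection rates: in sparse random
networks a species balanced by a single reaction pins that reaction's flux
to exactly zero, and cascades of this effect leave a substantial fraction
of internal reactions with structurally zero flux. A removed reaction with
zero flux produces no signal and cannot be detected by any test, so
measured true-positive rates are an average over detectable and
undetectable removals, and any comparison with rates obtained under a
different network generator inherits differences in this zero-flux
fraction — it dominates the rates at small omission counts, while the
conditional detection rate given a nonzero omitted flux is essentially
perfect at low noise. Passing tests on this generator
demonstrate the statistics and the protocol, not performance on curated
genome-scale models.

## Study harnesses and problem sizes

The detection experiment draws a fresh network, flux vector and noise per
replicate; the true-positive arm tests the reduced model (truth candidates
for F/LM), the false-positive arm uses the RESET test on the full model
and decoy candidates on the reduced model for F/LM. Rates are rejection
fractions, so TP+FN = 1 and FP+TN = 1 exactly. Default 200 replicates per
cell (the package's desk-scale choice; the printed-table comparisons in
the test suite use three binomial standard errors plus a 0.05 systematic
allowance for the generator differences above). The bias harness follows
the single-removal protocol: closed-form bias relative to a reference fit
plus the mean ANOVA p over repeated noisy GLS fits of the reduced model.
The resolver harness nests data replicates inside model replicates —
remove `n_extra` columns from one base network to get the data-generating
model, remove `n_omit` more to get the fitted one, pool all removals as
candidates, resolve, count what was never promoted by provenance — and
aggregates the mean over model replicates of per-model medians, with
standard errors. Reference fluxes for data generation are null-space
samples, and CoV-scaled noise stands in for measured per-flux standard
deviations whenever none are supplied.

## Known limitations

* The heteroscedasticity-consistent LM statistic is anti-conservative when
  the error degrees of freedom are few relative to N (its finite-sample
  size can far exceed the nominal level at MFA-typical dimensions); its
  printed form is implemented verbatim, so this is a property of the
  method, not of the implementation.
* Near-square designs (N - K of order a few) make single-candidate F tests
  nearly indistinguishable between candidates; the resolver's audit log
  exposes such ties.
* The whitened test mode is numerically fragile at low noise, as described
  above; the raw-OLS mode is the default and the validated path.
* No reaction reversibility semantics, compartments, SBML import, or
  thermodynamic feasibility checks; model files are plain TSV tables.
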