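# Methods

## The model

`lagnet` infers a directed gene regulatory network (GRN) from uniformly
sampled time-course expression data.  For each target gene *i* it fits a
penalized linear autoregression on the lagged expression of every gene *j*
(including gene *i* itself):

    min_{w}  1/2 * Σ_t ( x_i(t) − Σ_j Σ_{k=1..L} w_{ji,k} x_j(t − k·Δt) )²
             + λ Σ_j Σ_k |w_{ji,k}|
    s.t.     |w_{ji,1}| ≥ |w_{ji,2}| ≥ … ≥ |w_{ji,L}|   for every j,

where L = `l_max` is the maximum lag.  The order constraint encodes the
assumption that a regulator's influence decays with temporal distance; it
also gives each predictor a well-defined *maximum effective lag* (all
coefficients beyond it are zero).  An edge *j → i* is predicted whenever any
lag coefficient of *j* is non-zero, which under the constraint reduces to
checking the first lag.

The semi-supervised variant replaces the single penalty with two: groups
whose pair (*j*, *i*) lies in a prior edge set *E* are penalized at
`lambda_edge`, the remaining groups at `lambda_non_edge`.  With
`lambda_edge < lambda_non_edge` the known regulators absorb most of the
explainable variance; non-prior pairs that still enter are reported as
*novel* edges, prior pairs with all-zero coefficients as *anomalous* edges.
With equal penalties the problem reduces exactly (bit-for-bit in the solver)
to the de novo form.

## The solver and the shape of the constraint set

The set {|w_1| ≥ … ≥ |w_L|} is not convex (the midpoint of two feasible
points can violate it), so the magnitude-ordered problem is solved through
its standard convex reformulation: each coefficient is split into
non-negative positive and negative parts, each part is constrained to be
non-increasing across lags, and the penalty is applied to the sum of the
parts.  The reformulated problem is solved by a monotone accelerated
proximal-gradient iteration (step size 1/L with L twice the squared spectral
norm of the standardized design; extrapolated steps that would increase the
objective trigger a momentum restart).  The proximal operator of the penalty
plus the part-cone is a shift by the per-column penalty followed by an
isotonic projection (pool-adjacent-violators, non-increasing order) clipped
at zero.

Two consequences of the split are worth knowing:

* At optima where the two parts are complementary (at most one part non-zero
  per coordinate, the generic case for positive penalties and sign-consistent
  signals) the solution satisfies the written |w| ordering exactly.
* When the optimal lag profile of one predictor alternates in sign, the
  split charges a somewhat larger effective penalty than λ‖w‖₁, and the
  returned profile may break the plain |w| chain across a sign change.  This
  is a property of the ordered-lasso formulation itself, not of this
  implementation; the solver-vs-oracle tests therefore score the objective
  the method actually minimizes (the tests derive the split penalty's closed
  form for L ≤ 2 and verify it against a linear program).
* With a zero penalty on a group (the `lambda_edge = 0` semi-supervised
  default) complementarity is not forced, so the magnitude ordering is
  guaranteed only for groups with positive penalty.

## Standardization and back-scaling

The response and all columns are centered (the intercept is recovered
afterwards, so expression need not be mean-zero), and the columns of each
predictor are scaled by a single *group-pooled* standard deviation rather
than per column.  A shared scale per predictor keeps the lag-ordering of
coefficient magnitudes identical on the standardized and original scales —
per-column scales could silently break the ordering during back-scaling —
while still making one λ comparable across genes and replicate series.

## The regularization path and edge ranking

A shared, descending grid of 100 logarithmically spaced penalties runs from
the dataset-wide critical value λ_max down to 10⁻⁴·λ_max; fits are
warm-started from larger to smaller λ.  λ_max is computed in closed form:
the extreme rays of the non-negative non-increasing cone are prefix
indicator vectors, so the all-zero fit is optimal exactly when every prefix
mean of a group's standardized column–response inner products is at most
λ·pen_j; the critical value is the maximum of those prefix means over
groups (for the unconstrained Lasso-Granger variant it is the usual
per-column maximum).  The tests additionally confirm the value by direct
fitting just above and just below it.

Because edges can enter, leave and re-enter as λ decreases, each directed
pair is assigned the *largest* grid λ at which it is active ("entry value"),
which makes thresholded edge sets nested and the ROC curve monotone.  The
AUC is the Mann–Whitney probability that a random true edge outranks a
random non-edge; ties — including the single shared bottom rank of pairs
that never enter — count one half.  Self-pairs are always included as
covariates but excluded from predicted networks and ROC candidate sets by
default (flag to include), since the benchmark truths score cross-gene
regulation.  Entry values are resolved on the grid, so grid density is the
resolution of the ranking.  A coefficient is "non-zero" when its
back-scaled magnitude exceeds 10⁻¹⁰; convergence is declared at relative
objective change below 10⁻⁸ (iteration cap 10,000, exceeded → a convergence
error carrying the objective history).

## Baselines

*Pairwise Granger causality*: for each ordered pair, an F-test compares the
target's autoregression on its own L lags with the model that adds the
candidate driver's L lags, rows pooled across replicate series (lag windows
never cross series boundaries), residual degrees of freedom n − (2L + 1).
Networks are thresholded on Benjamini–Hochberg-adjusted p-values; for ROC
ranking the edge score is 1 − p.  Series too short for positive residual
degrees of freedom are a hard error — the method's inherent limitation.

*Lasso-Granger*: the identical pipeline with the order constraint removed.
With L = 1 there is no constraint to remove, so its entry path — and hence
its AUC — coincides exactly with the constrained method's, a property the
tests assert path-for-path.  Without the constraint an edge may be carried
by a higher lag alone, so the edge rule inspects every lag.

## Synthetic data

*Repressilator* (three genes, each repressing the next in a cycle):
ẋ = α/(1+zⁿ) − x and cyclic analogues, integrated with an adaptive
high-order Runge–Kutta scheme (DOP853, rtol 10⁻⁸, atol 10⁻¹⁰ — trajectory
error far below fit tolerances) and sampled every Δt.  Defaults α = 4,
n = 3, initial state (1.0, 1.2, 1.5) — asymmetric, to leave the invariant
symmetric manifold; the ODE is deterministic, so no seed is involved.  At
these parameters the symmetric fixed point is a slowly decaying spiral
(|f′(s)| ≈ 1.83 < 2), so trajectories oscillate visibly throughout horizons
of several periods rather than settling; sampled over T = 6π this is ample
signal for recovery, and all validation claims are asserted on exactly this
simulated regime.  One caution: Δt should not be an integer multiple of the
oscillation period, or the sampled data are constant and edges are predicted
at chance.  No observation noise is added.

*Sparse VAR*: x(t) = Σ_k A_kᵀ x(t−k) + ε with known support, the exact
model class of the fit.  Stationarity (companion spectral radius < 1) is
validated at construction; magnitudes halve per extra lag so the truth
obeys the lag-decay assumption.  With process noise, series are sampled
from the stationary regime after a 200-step burn-in; without noise the
process decays, so each series instead starts from a fresh random state and
the deterministic transient is the data.  Two generators are provided:
`random_sparse_var` (self-decay plus two random incoming cross edges per
gene, |coefficients| ≈ 0.3–0.5, radius rescaled to 0.9, noise SD 0.1 —
the default stochastic recovery condition) and `ring_var` (a cyclic cascade
with self-decay).  The ring is the fixture for *exact* support recovery:
its weak collinearity keeps the lasso's irrepresentable condition
comfortably satisfied, whereas densely coupled random draws can violate it,
in which case small spurious coefficients persist at every positive λ — a
property of l1 selection, not a solver defect.  Noiseless exact-recovery
experiments use five 20-point series (fresh initial states) rather than one
long decayed series, which would concentrate on the dominant mode.

What the generators do not emulate: measurement noise on the repressilator,
nonlinear or delayed regulation beyond one sampling step, non-uniform
sampling, and the low-copy-number stochasticity of real single-cell data.
Passing tests therefore demonstrate correctness of the machinery and the
method's behavior inside its model class, not performance on any real
expression dataset.

## Problem sizes and numerical choices

Validation experiments are sized for a desktop: 3-gene repressilator paths
over 100 penalties (≤ 257 time points), 6-gene VARs with 100–200 points,
a 50-problem solver-vs-brute-force battery (≤ 3 predictors, ≤ 2 lags,
≤ 15 rows, nested grid search with 7 points per axis and 10 refinements),
and a 1000-replicate Granger null calibration at n = 200.  Degenerate
inputs are handled explicitly: zero-variance responses fit to zero (and
λ_max warns and returns 0), constant predictors get unit scale and zero
coefficients, empty predictions report precision 1 with a flag, and an AUC
whose positive or negative class is empty raises rather than returning a
number.  Ties in the monotone chain at the tolerance boundary count as
satisfying the constraint.

## Known limitations

* Magnitude ordering across a sign change is enforced only through the
  split formulation (see above).
* Entry values are grid-resolved; no exact breakpoint solving.
* No automatic selection of λ, (λ_edge, λ_non-edge) or l_max: the λ path
  plus ROC/threshold utilities are the intended interface, and per-gene λ
  selection is left to the user.
* Uniform sampling within a series is assumed; the lag index, not wall-clock
  time, drives the model.
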