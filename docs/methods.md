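# Methods

This note documents the models, algorithms and design choices behind
`mediadoe`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what each stage assumes, which knobs matter, and
what the synthetic validation does and does not demonstrate.

## Experimental designs

### Blocked screening fractions

`make_screening_design` builds a regular two-level fraction for k factors
in n = n_blocks × runs_per_block runs (n and n_blocks powers of two).
With m = log₂(n) basis columns, every factor column is the elementwise
product of a subset of basis columns; the defining relation, and hence
the complete alias structure, follows from those subsets and is stored
with the design (`generators`).

Factors are assigned to **odd-weight** subsets (singletons first, then
weight-3 in lexicographic order, then weight-5, …). Any product of two
odd-weight words is a nonempty even-weight word, so no main effect can
alias another main effect or any two-factor interaction — the design is
resolution ≥ IV whenever k ≤ n/2, which covers the 21-factor-in-64-runs
screening case (32 odd-weight columns available). If k exceeds n/2 the
constructor falls back to even-weight columns and logs that the design is
resolution III. Published minimum-aberration generator tables are not
consulted; the odd-weight construction achieves the property that matters
here (mains clear of mains and of 2FIs) and keeps the generator set
self-describing.

Block-defining contrasts are chosen from the **highest-order unused
even-weight** words (independent of one another), so the 8 blocks of the
screening design are confounded only with high-order interactions, never
with main effects. Run order is randomized within block from the seed.
`alias_structure` recovers alias sets for any interaction order by
symmetric-difference arithmetic on the generator subsets, and
`estimable_interactions` lists the 2FIs whose columns are clear of all
main effects — the screening model can include exactly these, rather
than an undisclosed random subset.

### D-optimal custom designs

`make_custom_design` maximizes det(XᵀX) for the model
intercept + mains + all two-factor interactions + block contrasts
(sum-to-zero coding, last block as reference) by coordinate exchange over
coded levels {−1, +1}: every (run, factor) cell is flipped in turn and
the flip kept when log det increases; a pass with no accepted flip ends a
start, and the best of 20 seeded random starts is returned (XᵀX is
updated by rank-2 row swaps and refreshed once per pass against
round-off). Blocks are fixed equal-size partitions of the run list.
Candidate levels are the two coded extremes only; on tiny instances
(2 factors, 4 runs) the exchange provably reaches the global optimum over
the wider {−1, 0, +1} grid (the full factorial), which the tests verify
by brute-force enumeration.

For 9 factors, 56 runs, 7 blocks the model matrix has 52 columns
(1 + 9 + 36 + 6) and the returned design is full rank. At this size
(n = 56 barely above p = 52) residual correlations between main and
interaction columns of |r| ≈ 0.2 are unavoidable; see "What the
synthetic validation shows" below for the consequence.

### Plate layouts

`make_plate_layout` fills a 96-well plate (rows A–H × columns 1–12):
all 36 periphery wells hold water (evaporation guard); treatments,
replicates and controls are placed in the 60 interior wells (B–G × 2–11)
by randomized greedy search with restarts so that no replicate of the
same item occupies an interior row or column twice (Latin-rectangle
property). The validator re-checks every constraint independently and
returns the violation list. At most 6 replicates of any item fit (6
interior rows).

## Synthetic growth responses

`GroundTruth` defines the generating model on the coded scale: latent
u = β₀ + Σ βⱼxⱼ + Σ βᵢⱼxᵢxⱼ + block effect + ε, ε ~ N(0, σ²), emitted
through the saturating map od_max·max(u,0)/(od_max + max(u,0)). The
transform is a Monod-like bounded monotone map chosen because plate
growth curves plateau; it is a config option (`transform="linear"`
disables it) since the downstream analysis never models the ceiling.
Block effects are additive on the latent scale, mirroring observed
batch-to-batch differences without claiming a mechanism.

The default preset (`default_truth`) has one strong positive
bionutrient-like factor (+0.45), two strong negative chelator-like
factors (−0.35, −0.30), two moderate positives (+0.22, +0.18), two true
interactions (+0.25, −0.22) and the rest null; β₀ = 0.55, σ = 0.05,
od_max = 2.0, block effects ~ N(0, 0.05²). Units are Δ*OD₆₀₀*. The
interaction sizes are deliberately larger than the weakest main effects:
the concave ceiling attenuates product terms more strongly than mains,
and the preset is sized so that paper-scale replication (3 biological ×
2 technical replicates) recovers every non-null term in PLS screening.
σ is a free parameter — the replicate error of the original experiments
is unknown (error bars only appear in figures) and no claim is made that
the default matches it.

`restrict` produces the follow-up-iteration truth after screening:
dropped factors sit at their low level (coded −1), so their main effects
fold into the baseline and orphaned interactions fold into the surviving
parent's main effect.

Growth curves are simulated from the Hill form top·tʰ/(t50ʰ + tʰ) plus
Gaussian noise; the value at t = 0 is pure noise.

## PLS screening

Single-response NIPALS with both X and y autoscaled. Technical
replicates are averaged before modelling; biological replicates stay as
rows (the granularity of per-starter-culture means), and
cross-validation folds hold out whole runs so replicates of one
formulation never straddle train and test. Zero-variance predictors are
dropped with a warning naming them rather than failing the pipeline.

Cross-validation fits the full LV path once per fold (predictions for
every component count 1…a_max fall out of the same deflation), pools
squared held-out residuals into PRESS per LV count, and reports Root
Mean PRESS = √(PRESS/n) — the normalization is a documented choice;
only orderings enter the selection rule, which is invariant to any
monotone rescaling. The van der Voet T² comparison of count a against
the PRESS-minimizing count uses the paired statistic T = Σ(e²ₐ − e²_opt)
with a 2000-draw sign-flip null (seeded); the selected count is the
smallest a with p > 0.10. The optimum compares to itself with p = 1 by
construction.

VIP scores use the explained-y-variance weighting
VIP_j = √(p Σₐ (w_ja/‖wₐ‖)² SSₐ / Σₐ SSₐ); Σⱼ VIP²ⱼ = p holds exactly
for every fit and is asserted in the tests. The 0.8 threshold is the
conventional screening cut; each VIP is paired with its
centred-and-scaled coefficient so direction is interpretable.

With n_components = rank(X) the PLS predictions coincide with OLS, which
the tests check against a direct least-squares solve and against the
reference NIPALS implementation in scikit-learn (used as an oracle only).

## Exhaustive AICc subset regression

The term basis is mains + all pairwise interactions (45 terms for 9
mains). Enumeration streams `itertools.combinations` in chunks; each
chunk's normal equations are assembled by fancy-indexing a cached Gram
matrix of the 46-column basis (intercept + terms) and solved as a batched
(s+1)×(s+1) system, so the full 9,531,039-model sweep at n = 56 runs in
about half a minute on one CPU. Gaussian log-likelihood uses the MLE
variance (divisor n); AICc follows the printed small-sample formula with
k = |terms| + 2 (intercept and error variance both counted — Δᵢ is
invariant to any constant offset in k, so ranking does not depend on the
convention). Candidates with n − k − 1 ≤ 0 or a singular subset are
excluded and counted, never silently scored. The running Δᵢ < threshold
set is pruned as the minimum improves, so memory stays flat; ties at the
minimum break lexicographically on term labels.

Strong heredity (an interaction admitted only with both parents present)
is available at enumeration time; the unrestricted mode is the default
because its closed-form count Σ_{k=1..6} C(45,k) equals the reference
figure of 9,531,039 candidate models.

## ANN ensemble and optimizer

The ensemble inputs are the Δᵢ < 2 models' prediction columns (not raw
ingredients). The network is 15→3→1-scale: one hidden layer, logistic
sigmoid by default (tanh available), linear output. Training minimizes
squared error plus an L2 penalty (α = 10⁻³) on connection weights by
full-batch L-BFGS (gradient tolerance 10⁻⁸, 5000 iterations cap) from 10
seeded N(0, 0.1²) initializations, keeping the restart with the lowest
penalized training loss. The penalty and restarts exist because an
unpenalized 3-node net trained from a single start occasionally fits
wiggly or even inverted shapes between its few training points, which
corrupts the downstream argmax; both are standard practice for nets of
this size. Inputs and targets are standardized internally. The holdback
partition (19 rows by default) is drawn once from the seed; R² is
reported on both partitions and is NaN when a partition's response is
constant. Predictions outside the training-target envelope (min/max
± 3 SD) trigger a warning, not clipping.

The optimizer samples n = 5000 candidates uniformly and independently
per ingredient within [low, high] (the reference procedure says only
"randomly assigned"), applies the pinned map (bionutrient → 0) to every
candidate, encodes concentrations to the coded scale, attaches both the
ANN and the PLS prediction, and returns the ANN argmax (ties broken by
first occurrence, logged). The recipe export lists ingredient,
concentration and units, appends pinned stocks and glucose at 10 g L⁻¹.

## Growth kinetics

Hill fits use `scipy.optimize.curve_fit` with top = max(y), t50 =
interpolated half-max time, hill = 2 as the start, all parameters bounded
positive and t50 ≤ 2 × the final time; non-convergence returns a flagged
result, never an exception. Time is the independent variable — the
"one-site specific binding" name for this curve shape is a borrowing
from graphing software, not a binding model. Doubling time is
ln 2 / slope of ln(OD) vs time (minutes) within a window; the automatic
window is the ≥4-point sliding window with positive slope maximizing r²
of the log-linear fit, because no standard window definition exists for
plate curves — users can override it. One-way ANOVA is the classical
between/within decomposition with p from the F distribution; identical
groups return F = 0, p = 1, and zero within-group variance with real
between-group spread returns F = ∞, p = 0.

## Pipeline and seeding

`run_pipeline` chains screen → PLS screen → factor retention → custom
design → PLS + subset search → ensemble → optimizer. The retention rule
is: keep factors with VIP ≥ 0.8 **and** positive coefficient (inhibitory
and non-significant ingredients drop out; judgment calls like merging
buffer salts are outside the scope of an automated rule). One top-level
seed fans out to per-stage seeds via `numpy.random.SeedSequence.spawn`
in a fixed order, so each stage is independently reproducible and a
rerun with the same config reproduces every artifact.

## What the synthetic validation shows — and what it does not

The acceptance suite replays the full second-iteration procedure 100
times at paper-scale replication (3 biological × 2 technical), with a
fresh D-optimal design, fresh noise and fresh block effects per seed,
and requires: all non-null terms flagged at VIP ≥ 0.8 with correct
signs in ≥ 95 replications; null factors' median VIP < 0.8; a planted
3-term regression model inside the Δᵢ < 2 set in ≥ 95 replications; and
the optimized formulation placing the strongest chelator-like factor in
the bottom quarter of its range (coded < −0.5) in ≥ 95 replications —
the threshold was fixed in advance after checking that the argmax of the
*true* response surface satisfies it essentially always. The seed sweeps
run the subset search at max_terms = 3 and the single full-depth
9,531,039-model sweep runs once; these problem sizes keep the whole
suite comfortably on one CPU while exercising every code path at the
reference dimensions (56 runs, 45-term basis, 19-row holdback, 5000
candidates).

Designs are regenerated per replication deliberately: with n = 56 rows
against 52 model columns, any single design carries residual
main-vs-interaction correlations that deterministically leak importance
onto particular null factors; conclusions about *the method* require
averaging over designs, and conclusions about *one design* should use
its alias/correlation diagnostics directly.

The generator emulates endpoint Δ*OD₆₀₀* tables with additive block
effects, iid replicate noise and a smooth saturating ceiling. It does
not emulate: culture aggregation and lysis (non-monotone curves), pH
drift or buffer chemistry, evaporation gradients within plates,
heteroscedastic or correlated replicate error, or any mechanistic
lag/exponential/stationary dynamics. Passing recovery tests therefore
demonstrates that the statistical chain is implemented correctly and is
sensitive at realistic effect-to-noise ratios — not that the chain is
robust to those unmodelled biological effects. The per-seed holdback R²
of the ensemble is noisy (19 validation rows), so only its aggregate
behaviour across seeds is asserted.

## Known limitations

* Screening designs require power-of-two run and block budgets; no
  Plackett–Burman or definitive screening fallback.
* D-optimality only; no A-/I-optimal criteria, and the exchange is a
  local search — optimality is certified only on tiny instances.
* The subset search enumerates ≤ 6-term models; it is exhaustive, not a
  heuristic, so the term cap is a hard computational boundary
  (max_terms = 7 would multiply the sweep ~6×).
* The ANN ensemble is a fixed tiny architecture; no hyperparameter
  search, regularization-path selection or uncertainty quantification.
* The optimizer is pure random search over a box; no mixture
  constraints, acquisition functions or sequential design.
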