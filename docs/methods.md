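# Methods

This note documents the models and procedures implemented in `tripcausal`,
the assumptions they rest on, and the design choices made where the
underlying study left details open.

## Variables and causal stages

The analysis operates on per-trip tables of 14 named variables in five
temporal stages:

| stage | variables | role |
|---|---|---|
| predetermined | sun, weekend, occupants, commute | known before the trip; exogenous |
| emotion_before | before_arousal, before_valence | affect sliders, 0–100 |
| behavior / trip_factor | steering, braking, sudden_events / length, speed, flow | measured during the trip |
| emotion_after | after_arousal, after_valence | affect sliders after the trip |

The source study counts 13 variables but names 14; we carry all 14 named
variables (configurable) rather than silently dropping one. The temporal
ordering defines the a-priori forbidden edges: later stages never cause
earlier ones, behavior and trip factors never cause pre-drive emotion, and
nothing causes a predetermined factor. Behavior and trip factors share a
stage and may influence each other in either direction.

## The synthetic trip generator

A linear-Gaussian structural equation model: each node j is

    X_j = Σ_i W[i,j] · X_i + σ_j · ε_j,    ε_j ~ N(0, 1),

sampled ancestrally in topological order. Binary predetermined factors are
exogenous roots drawn Bernoulli(p) and standardized to mean 0 / variance 1
before feeding children, so the closed-form covariance
Σ = (I − Wᵀ)⁻¹ D (I − Wᵀ)⁻ᵀ holds exactly. Raw-scale output maps affect
columns through their published slider moments and clips to [0, 100]
(clipping shifts the raw mean down by ~0.5 and shrinks the SD by a few
percent relative to the nominal moments — the standardized scale used by the
analysis is unaffected); binary columns revert to 0/1 flags. A Laplace noise
switch (variance-matched) supports heavy-tail robustness experiments.

**The `table1` preset** sets the direct weights to the study's 15 published
significant effect sizes and solves the noise scales σ_j so every node has
unit marginal variance. Prevalences: weekend 0.18 and commute 0.24
(published); occupants 0.30 (not published; a plausible share of
accompanied trips, configurable).

One structural caveat, worth stating precisely because it shapes several
expected values below: published effect sizes from an adjusted-regression
workflow are **total** effects, and re-using them as **direct** weights
double-counts mediated paths. Concretely, the parents of `after_valence`
(occupants 0.37, before_arousal 0.19, before_valence 0.77) then explain
1.0351 units of variance — more than a unit-variance node can carry — so no
nonnegative noise scale exists. The preset floors that node's noise at zero
(an explicit flag; by default an infeasible node raises an error), leaving
`after_valence` with marginal SD 1.0174 and the other 13 nodes exactly unit.
Since the pipeline standardizes columns empirically, downstream estimates
are unchanged; the one visible consequence is that `after_valence` is an
exact linear function of its parents, so regressions of it on a superset of
those parents have near-zero residual variance (degenerately tight CIs).

The generator's defaults are the study conditions throughout: 1638 trips at
the study scale, the published prevalences and slider moments, Gaussian
noise. Benchmark SEMs for structure recovery are drawn separately: random
10-node/12-edge DAGs, weights uniform on ±[0.5, 1.5], per-node noise SDs
uniform on [0.8, 1.2] (unequal by design, fixed once).

What the generator does *not* emulate: driver-level clustering (trips are
exchangeable), temporal autocorrelation across a driver's consecutive trips,
nonlinearity, measurement error in the sliders, and the discreteness of
real slider responses. Passing tests therefore demonstrate correctness of
the machinery under the linear-Gaussian pooled-trips assumptions the
analysis itself makes — not that those assumptions hold on road data.

## Signal features

Per-second traces (1 Hz canonical; higher-rate input is averaged per
second) yield the behavior variables. Rates are second-to-second
differences, so a trace of n seconds has n − 1 transitions:

- *steering ratio*: share of transitions with |Δ angle| above 2°/s;
- *braking ratio*: share of seconds with the brake pedal engaged;
- *sudden events per hour*: local maxima of |acceleration| and |steering
  rate| above 2.5 m/s² and 90°/s respectively (SciPy peak detection with
  boundary padding), merged across channels when closer than 2 s, divided
  by trip hours;
- *flow*: mean of min(speed / limit, 1) per second — speeding cannot raise
  flow above 1, and a standstill second under a zero limit contributes 0.

The study names thresholds without printing them; these defaults are
reproducible stand-ins and all are configurable. The scenario generator
injects braking episodes, moderate turning, and isolated super-threshold
steering jerks with known counts, so every extractor has an exact ground
truth (a jerk-and-return produces two adjacent super-threshold flanks that
plateau into a single detected peak — one event, as intended).

## Standardization

Sample mean/SD with the n−1 convention, per column; parameters kept for the
inverse map. Binary 0/1 columns are standardized like continuous ones by
default because all effects are reported per SD (a switch leaves them raw,
since it is unclear whether the original analysis standardized its flags).
Missing data are handled by complete-case deletion — the study reports
complete questionnaires, so no imputation machinery is warranted.

## Structure learning

Score-based continuous optimization of the weighted adjacency matrix:
least-squares loss (1/2n)‖X − XW‖²_F plus λ₁‖W‖₁, subject to the smooth
acyclicity constraint h(W) = tr(e^{W∘W}) − d = 0, minimized by an augmented
Lagrangian (dual ascent on α; penalty ρ escalated ×10 whenever h fails to
shrink by 4×) with L-BFGS-B on the positive/negative part decomposition of
the free entries. Implementation notes:

- **Masking by parameter elimination.** Forbidden entries (temporal rules
  and the diagonal) are not free variables, so they are bitwise zero in the
  result — not merely small.
- **Gram-matrix loss.** The loss and gradient are computed from XᵀX, making
  each evaluation O(d³) independent of n.
- **Scale sensitivity.** The least-squares score is not scale-invariant;
  the fit refuses unstandardized input unless explicitly overridden (as the
  raw-scale recovery benchmark does).
- Defaults λ₁ = 0.1, ω = 0.3, ρ₀ = 1, ρ_max = 1e16, h_tol = 1e-8 — the
  customary settings of the reference algorithm, all config-exposed. With
  effects as small as the study's (0.06–0.38 SD), λ₁ shrinkage plus the
  ω = 0.3 cut prunes most true edges; recovering such graphs needs gentler
  settings (the README example uses λ₁ = 0.01, ω = 0.08). Failure to reach
  h_tol raises a nonconvergence error carrying the best iterate.
- On standardized equal-noise two-node problems the score cannot
  distinguish edge direction; tests requiring identifiability use masks or
  unequal noise.

## Graph reasoning

d-separation is a linear-time reachability sweep over (node, direction)
states (the Bayes-ball construction): chains and forks block when their
middle node is conditioned on, colliders block unless the collider or a
descendant is conditioned on. Backdoor sets are found by exhaustive subset
enumeration over non-descendants of the source, testing d-separation in the
graph with the source's outgoing edges removed — affordable at the study's
14 nodes, and checked in the test suite against an independent
path-enumeration oracle on every 4-node DAG and random 6-node DAGs. The
*minimal* set is the smallest valid set with lexicographic tie-break, making
the pipeline deterministic (the study does not state how its sets were
chosen). With every variable observed, each DAG edge is identifiable (the
source's parents always satisfy the criterion), but non-identifiable
requests raise a dedicated error and effect-table rows are flagged rather
than dropped.

## Effect estimation

One OLS per directed edge — target on source plus the minimal backdoor set,
with intercept — rather than one joint system, matching the
regression-per-effect workflow. CIs and p values use the t distribution
with n − |Z| − 2 degrees of freedom; significance is judged at α = .05 on
raw p values (a Benjamini–Hochberg switch exists but is off by default, as
is a cluster-robust option for per-driver error correlation, since the
study pools trips). Rank-deficient designs raise an error naming the
collinear columns.

Backdoor-adjusted regression identifies the **total** effect of source on
target. For edges with mediated paths the expected estimate is the path-sum
(I − W)⁻¹ − I entry rescaled by the marginal SDs, not the direct weight:
e.g. in the `table1` preset, before_arousal → after_arousal has direct
weight 0.74 but total effect 0.8014 (adding paths through speed, through
before_valence→after_valence, and through after_valence), and that is what
the pipeline — correctly — recovers. The unmediated spotlight pairs
(occupants → before_valence, speed → after_arousal) recover their published
values exactly.

## Refutation

Robustness to unobserved confounding and mild misspecification is probed by
appending an independent N(0,1) column to the adjustment set and
re-estimating. For a genuinely independent regressor the coefficient change
is O(1/n); at 1638 trips the per-draw change is ~6e-4 and the mean over the
default 20 draws is well under the 1e-3 scale. The mean of signed changes
is reported (a single draw is noisy); the generator distribution is
standard normal, independent of all columns. Deterministic given its seed.

## Problem sizes and numerical choices

The shipped experiments use: 100 replicates × 5000 trips for parameter
recovery; 1638 trips × 20 confounder draws × 15 edges for the robustness
bound; 10 seeds × 2000 trips for the 10-node structure-recovery benchmark;
200 000 trips for the covariance-identity check; exhaustive enumeration of
all 543 labelled 4-node DAGs (×48 conditioning triples each) plus 50 random
6-node DAGs for oracle equivalence. Monte-Carlo tolerances follow from
these sizes (e.g. ±0.01 on a mean of 100 × n=5000 estimates, whose standard
error is ~1.5e-3). Acyclicity uses h_tol = 1e-8 on the matrix-exponential
constraint during optimization, but structural checks (spec validation,
post-threshold verification) use exact support-based cycle detection, which
cannot underflow for tiny weights.

## Known limitations

- Structure learning is score-based and offers no uncertainty over graphs;
  a wrong graph propagates to identification and estimation. The robustness
  test probes the estimates, not the graph.
- Linear-Gaussian assumptions throughout; no nonlinear or interaction
  effects, no mediation decomposition, no front-door or instrumental
  identification, no latent-variable (ADMG) machinery.
- The generator's `table1` preset inherits the total-vs-direct mismatch of
  published effect sizes described above; it is a structural property of
  re-using adjusted estimates as direct weights, not a removable bug.
- Trips are treated as independent; per-driver heterogeneity is only
  available through the (off-by-default) cluster-robust standard errors.
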