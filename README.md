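# tripcausal

Causal analysis of driving behavior and well-being from observational trip
tables.

Field studies of everyday driving record, per trip, the driver's affective
state before and after the drive (arousal and valence on a 0–100 slider),
driving-behavior summaries (steering ratio, braking ratio, sudden events per
hour), trip-dependent factors (length, average speed, flow) and predetermined
factors (sunlight, weekend, occupants, commute flags). Because nothing is
randomized, cause–effect claims need more than regression: `tripcausal`
implements a complete causal-inference workflow for such data, aimed at
researchers in mobile health and traffic psychology who want to identify
*states of vulnerability* (e.g. drowsiness-inducing monotony) that could
trigger in-vehicle well-being interventions.

## The method

1. **Structure learning.** A weighted causal DAG over the d variables is
   learned from the standardized trip table X (n × d) by continuous
   optimization (the NOTEARS approach):

       min_W  (1/2n) ‖X − XW‖²_F + λ₁‖W‖₁    s.t.  h(W) = tr(e^{W∘W}) − d = 0,

   solved by an augmented Lagrangian with dual ascent. Temporally impossible
   effects (post-drive emotion → anything earlier; behavior or trip factors →
   pre-drive emotion; anything → predetermined factors) are excluded a priori
   by a mask enforced through parameter elimination, so masked entries are
   exactly zero. Edges with |w| < ω are pruned.
2. **Identification.** For each edge X → Y of the DAG, the *backdoor
   criterion* selects a covariate set Z containing no descendant of X that
   blocks every path entering X through an arrow (d-separation in the graph
   with X's outgoing edges removed). The package enumerates all valid sets
   and uses the smallest (lexicographic tie-break).
3. **Estimation.** OLS of Y on {X} ∪ Z with intercept, all variables
   standardized: the coefficient of X is the causal effect size (**CE**) in
   SD-per-SD units, with a t-based 95% CI and two-sided p value.
4. **Refutation.** Each estimate is recomputed with an independent standard
   normal "confounder" appended to Z (20 draws, mean reported). For a robust
   estimate this changes the coefficient by O(1/n) — the study scale puts it
   below 0.001.

Because the original field data are not public, the package ships a
linear-Gaussian SEM simulator whose `table1` preset reproduces the study's
causal structure: direct standardized weights equal to the 15 published
significant effects, binary exogenous factors at the published prevalences
(18% weekend, 24% commute), affect sliders at the published raw moments
(e.g. before-drive arousal 73.66 ± 18.24), and noise scales solved so node
variances are unit wherever the published weights permit.

## Worked example

```python
import tripcausal as tc

spec = tc.table1_spec()                      # ground-truth SEM of the study
trips = tc.simulate_trips(spec, n=1638, seed=11)
model = tc.CausalEffectsModel(
    trips,
    categories=spec.categories,
    options=tc.NotearsOptions(lambda1=0.01, omega=0.08),
)
results = model.fit(seed=11)
print(results.summary())
```

```
Causal effect estimates (standardized, SD per SD)
  trips: 1638    edges: 13    refutation seed: 11

source          target               CE            95% CI        P    robust.  adjustment
----------------------------------------------------------------------------------------
before_arousal  steering           0.12      [0.07, 0.17]    <.001   +0.00006  (empty)
before_arousal  speed             -0.12    [-0.16, -0.07]    <.001   -0.00007  (empty)
braking         after_arousal      0.12      [0.07, 0.17]    <.001   +0.00007  (empty)
length          after_arousal     -0.19    [-0.24, -0.14]    <.001   +0.00007  (empty)
speed           after_arousal     -0.17    [-0.20, -0.15]    <.001   +0.00006  before_arousal
occupants       before_valence     0.38      [0.34, 0.43]    <.001   +0.00005  (empty)
sun             before_arousal     0.15      [0.10, 0.19]    <.001   +0.00016  (empty)
occupants       after_valence      0.66      [0.62, 0.69]    <.001   +0.00003  (empty)
sun             after_arousal      0.25      [0.21, 0.30]    <.001   +0.00005  (empty)
before_arousal  before_valence     0.18      [0.13, 0.23]    <.001   -0.00007  (empty)
before_arousal  after_arousal      0.80      [0.77, 0.82]    <.001   -0.00004  sun
before_arousal  after_valence      0.32      [0.28, 0.37]    <.001   +0.00015  (empty)
before_valence  after_valence      0.75      [0.75, 0.75]    <.001   +0.00000  before_arousal;occupants
```

Reading the output: from 1638 simulated trips the learner recovered 13 of
the 15 true edges at these sparsity settings. The `CE` column is the change
in the target (in SDs) caused by a 1-SD change in the source: e.g. an extra
occupant raises pre-drive valence by 0.38 SD, and higher average speed
lowers post-drive arousal by 0.17 SD — the latter only after adjusting for
pre-drive arousal, which causes both. Adjusted regressions identify *total*
effects, so pairs connected through mediating paths (e.g. before-arousal →
after-arousal, direct weight 0.74 plus paths through speed and valence) read
higher than their direct weight. The robustness column shows that no
estimate moves by more than ~1e-4 when a random confounder is injected.

The same workflow runs from the shell against a config file:

```bash
tripcausal all --config config.yaml --out run1/ --seed 11
```

writing `effects.csv`, `dag_edges.csv`, `dag.graphml`, `dag.dot`,
`standardization.json` and a `run_log.json` with every effective parameter.
Subcommands `simulate`, `features`, `learn`, `estimate`, `refute` run the
individual stages; `tripcausal features` turns per-second sensor traces
(speed, steering angle, brake pedal, speed limit) into the per-trip behavior
variables.

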