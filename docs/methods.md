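# Methods

## The competition model

The dynamical core is a mass-action chemostat model of two phage genotypes
and two bacterial compartments under a uniform washout/death rate *w*.
Free bacteria *B* are open to infection; refuge bacteria *R* (wall growth,
or planktonic cells whose surface state blocks adsorption) cannot be
infected but re-enter the free state at rate *h(E)*. Both compartments
grow logistically against a shared carrying capacity applied to *B+R*.
Only the GM phage produces the enzyme *E*, released at lysis with yield
*Z*; the release function

    h(E) = h_max / (1 + shape · decay^E),

with h_max = 0.2/min, shape = 19 and decay = 0.999997, rises sigmoidally
from the no-enzyme baseline h(0) = h_max/(1+shape) = 0.01/min toward h_max.
The three constants are stored as ordinary parameters, so the 0.01 baseline
is a derived check rather than an input.

Lysis is a fixed latent period: a cell infected at time t−L bursts at t if
it survived washout, probability e^(−wL). The burst, infected-class and
enzyme source terms therefore pair the phage and bacterial densities at
t−L exactly as the rate equations are written; no integrated survival of
the infected cohort is attempted. Two modelling consequences worth noting:

* The refuge equation carries no −wR washout term. Refuge bacteria behave
  as wall-bound and immune to dilution, which is also what keeps the
  wild-alone regime at high bacterial density indefinitely.
* Free phage are lost by adsorption to free *and* already-infected cells
  (the −kP(B+I_G+I_W) sink), not only to uninfected ones.

Enzyme "units" are abstract: one lysis contributes Z units, and only the
product shape·decay^E is ever used, so no physical concentration is
implied.

### Parameters

| name | symbol | default | units |
|---|---|---|---|
| adsorption_rate | k | 1e-9 | mL/min per particle |
| washout_rate | w | 0.05 | 1/min |
| burst_gm / burst_wild | b_G, b_W | 17 / 20 | progeny per lysis |
| lysis_time | L | 10 | min |
| max_growth_rate | v | 0.1 | 1/min |
| enzyme_yield | Z | 0.1 | units per lysis |
| carrying_capacity | C | 5e9 | cells/mL |
| release_max / shape / decay | — | 0.2 / 19 / 0.999997 | 1/min, —, per unit |

All rates must be strictly positive; burst sizes and the enzyme yield may
be zero (a zero yield reduces the GM phage to a wild-type control, a
useful limit in tests). Three named burst presets exist:
`gm_disadvantaged` (17 vs 20, the default and the tragedy configuration),
`equal` (20, 20) and `gm_advantaged` (20 vs 17).

## Integration

The solver is fixed-step forward Euler, reference step dt = 1e-3 min.
This is a deliberate choice over an adaptive stiff solver: runs are
bit-reproducible, the delayed lookup is an exact index offset (the step
must divide L evenly, enforced at spec construction), and halving the step
from 2e-3 to 1e-3 moves the competition endpoints by well under 1%.
Larger steps are accepted for exploratory work but logged as a warning.

The history ring holds round(L/dt)+1 states so the delayed record is
exactly L minutes old — never interpolated. Pre-t=0 history is either the
initial state held constant (`hold-initial`, default) or the initial state
with phage and infected classes zeroed (`zero-phage`, phage added at t=0).

Euler undershoot on fast decays can drive a component slightly negative;
such components are clamped to zero and the events counted, with a warning
if more than 0.1% of steps clamp. Non-finite derivatives abort the run
with the offending state attached. Output is thinned to one record per
simulated minute by default (full resolution via `output_thin=1`).

### Scenario defaults

The four presets start from B(0) = R(0) = 2.5e8/mL, each present phage at
1e4/mL, no infected cells or enzyme, and run 1500 min with held-initial
history. These initial conditions and the run length are package choices,
calibrated once so that the four qualitative regimes are reproduced —
wild-alone persistence, GM-alone collapse of total bacteria by several
orders of magnitude, and loss of whichever phage carries the smaller
burst from 50% starting frequency. They are not published values, and
every one is overridable. Endpoint frequencies under these defaults are
regression values of this package, not external targets: by 1500 min the
disadvantaged phage is essentially extinct (~1e-7), further along the same
decline than the ~9–10% endpoints illustrated in the source material's
shorter window.

## Pooled-assay inference

For a reaction pooling n isolates at true transgene frequency T
(U = 1−T), the outcome classes ALL_NEG / ALL_POS / MIXED have
probabilities A = Uⁿ, B = Tⁿ, C = 1−A−B; C is always computed as the
complement so the three sum to one exactly. The log likelihood of a
dataset is the sum over reactions of the log class probability, which
makes heterogeneous pool sizes additive for free; −∞ arises exactly when
an observed class is impossible (e.g. ALL_POS at T = 0).

* **MLE.** Unanimous datasets sit at the boundary (0 or 1) by inspection.
  Otherwise a 10,001-point uniform grid locates the maximum and a bounded
  scalar optimization polishes it within one grid cell; exact ties resolve
  to the smaller T because the first grid maximum wins.
* **Credible interval.** The normalized likelihood on [0,1] is the
  posterior under a flat prior (exactly the "normalized multinomial"
  convention; no other prior is in scope). The density is evaluated on a
  100,001-point uniform grid, normalized by trapezoidal quadrature, and
  the equal-tail bounds are read off the cumulative trapezoid CDF by
  monotone linear inversion. Grid sizes were chosen so conjugate
  closed-form checks agree to 1e-4: unanimous data are Beta(1, N+1) /
  Beta(N+1, 1), singleton-pool data are Beta(Y+1, X+1).
  Equal-tail (not HPD) intervals are used throughout, so for unanimous
  data the MLE lies *outside* the interval's lower 2.5% tail — the
  interval for 60 negative plaques is (0.0004, 0.0587), presented rounded
  as (0, 0.06). Rounding to two decimals happens only at presentation.
* **Frequency-change test.** A Pearson 1-df goodness-of-fit of observed
  positive/negative plaque counts against an expected frequency, without
  continuity correction by default (exposed as a flag; for 36 positives
  in 60 at expected 0.26 the statistic is 36.05).

## Synthetic data and what it validates

The generator draws reaction outcomes directly from the trinomial class
probabilities — the same sampling model the likelihood inverts — with all
randomness flowing from one explicit integer seed through SeedSequence
spawning (no global state). Default design n = 10 plaques per reaction,
R = 6 reactions.

Because generator and likelihood share the sampling model, recovery
experiments validate the *inference machinery*: that the MLE is consistent,
that RMSE falls with replication (R = 6 → 24 → 96), and that 95% interval
coverage stays in [0.90, 1.0] across truths (discreteness makes coverage
conservative, e.g. 0.997 at T = 0.26 where most datasets are all-mixed).
They say nothing about assay realism: PCR failure, primer dropout,
plaque-picking bias and misclassification are all outside the model, so
real-data coverage can be worse in ways these tests cannot detect.
Recovery estimates are memoized on the sufficient statistic (n, X, Y, Z),
so 1000-replicate experiments cost only as much as the distinct count
patterns they contain.

The trajectory-coupled sampler (`assay_from_trajectory`) sets the truth at
each requested time to the simulation's GM frequency, linking the two
threads: one can simulate a tragedy and "screen" the evolving population.

## Numerical and design notes

* Determinism: identical simulation specs produce bit-identical
  trajectories; `simulate` and repeated `euler_step` share the same scalar
  update function and agree exactly.
* GM frequency at zero total phage is NaN (undefined), never imputed;
  outcome classification uses the last *defined* frequency.
* Outcome classification is endpoint-based with a neutral tolerance of
  1e-6 — symmetric runs are exact, so anything larger signals real
  asymmetry. Fitting selection coefficients is deliberately out of scope.
* The strict bound h(E) < h_max holds in exact arithmetic for all finite
  E but is not representable in doubles beyond E ≈ 1.2e7 units, where the
  sigmoid is within half an ulp of its supremum.
* Tabular outputs carry `# key = value` provenance headers (package
  version, full parameter set, spec, seed) and round-trip bit-exactly
  (`%.17g` formatting, `float_precision="round_trip"` parsing).

## Problem sizes

Default test and validation scales: reference-step scenario runs are
1.5e6 Euler steps each (a few seconds in pure Python); property checks use
coarser steps (dt = 0.01) where only direction or ordering is asserted;
recovery experiments use 1000 replicates per truth at the default (10, 6)
design and 300 replicates in quick module tests.

## Known limitations

* Mass action, no spatial structure: the model is the well-mixed limit,
  which is the regime most prone to a tragedy of the commons. Spatially
  structured growth — the classical escape from the tragedy — is not
  modelled, so the simulations cannot address when biofilm architecture
  would rescue the transgene.
* Forward Euler is first-order; quantitative endpoints carry O(dt) bias
  (bounded empirically at <1% for the shipped scenarios). The step must
  divide the latent period exactly.
* The inference assumes perfect classification of pooled reactions and
  exchangeable isolates; no error model is provided.
* Long-run behaviour (bacterial rebound, limit cycles after the phage
  crash) is outside the validated window of the scenario defaults.
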