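# Methods

## Data model and normalization

A stimulation condition is a point (voltage [V], frequency [MHz],
duration [min]) in the treatment box; frequency 0 encodes the
unstimulated control. Viability is CCK-8 absorbance expressed as percent
of the control group's mean absorbance, so the control mean is exactly
100% by construction and `normalize_to_control` is idempotent. Replicates
aggregate to per-condition (mean, sample SD with the n−1 denominator, n).
The packaged study grid holds the 48 treated cells; the control row is
stored separately on the grid (`ResponseGrid.control`) and excluded from
surrogate training by default — the surrogate models the treated
response surface, and a (0, 0, 0) control input would sit far outside
the treated box and distort the input scaling. A flag
(`include_control=True`) adds it for users who want it.

Treated cells may legitimately have SD 0 (noiseless simulations;
single-replicate rows), so zero variance is not restricted to the
control.

## The surrogate network

Topology 3–8–1: three inputs, eight sigmoid hidden units, one linear
output. The output layer is a plain weighted sum minus a threshold — no
output activation — so the network can represent viability values
without saturation; the hidden thresholds a_j and output thresholds a_k
are trained parameters alongside the weights (otherwise they would be
dead constants). A 3–8–2 topology is configurable but the second output
has no measured response to train against.

All fitting happens in scaled space: inputs are min–max mapped to [0,1]
per dimension from the training levels, the target likewise from the
observed viability range; predictions are inverse-scaled before
reporting. A constant input dimension maps to 0.5; a constant target is
widened by ±0.5 so scaling stays defined and the network learns the
constant. A fully degenerate grid (one level in every dimension, or
fewer than two distinct conditions) is refused.

Training is **sequential (per-sample) gradient descent**: each sample is
presented in a fixed order and every weight/threshold is updated
immediately from that sample's error (the classic per-pattern delta
rule, which is how the update equations are written). Fixed presentation
order keeps epochs deterministic. We chose per-pattern over full-batch
updates deliberately: at the fixed budget (η = 0.1, ≤ 1000 epochs) batch
mean-gradient descent stalls around scaled MSE 1e-2 on 48-cell grids,
while summed-gradient batch steps diverge; per-pattern updates reach
~3e-3 and below. The epoch MSE recorded in the trace is the mean of the
per-sample errors evaluated just before each update, and training stops
when it reaches the error goal (1e-4 on scaled targets) or the epoch
cap. A network that already meets the goal stops after one (no-op)
epoch.

Defaults (all configurable): learning rate 0.1, max 1000 epochs, error
goal 1e-4, 8 hidden units. When the GA stage is ablated
(`ga_generations=0`), weights initialize uniformly on [−1, 1] from the
seed.

## The genetic algorithm

Real-coded, maximizing, with: roulette-wheel selection on min-shifted
fitness (degrading to uniform selection on a flat landscape); arithmetic
blend crossover with one uniform mixing coefficient per pair, applied
with probability PC = 0.8; per-gene Gaussian mutation with σ = 10% of
the gene's range, applied with probability PM = 0.1 and clipped to
bounds; one elite copied unchanged per generation. Defaults: population
50, 100 generations. Blend crossover of in-bounds parents cannot leave
the bounds, and clipping after mutation preserves them, so every
individual stays feasible; with at least one elite the per-generation
best fitness is non-decreasing. The operator forms themselves
(selection scheme, blend crossover, Gaussian mutation, elitism count)
were open design choices — the hyperparameter table fixes only
population, iterations, PM and PC — and are all exposed as parameters.

The engine is used twice:

1. **Weight initialization.** Genes are the flattened network parameter
   vector, bounded to [−5, 5] in scaled space — wide enough to saturate
   a sigmoid on [0,1] inputs, narrow enough to search with 50
   individuals — with fitness −MSE over the whole training set. The
   best individual seeds back-propagation.
2. **Input search.** Genes are (voltage, frequency, duration) in the
   stimulation box, fitness the surrogate's predicted viability. The
   initial population is seeded with the training-grid conditions, so
   with elitism the located continuous optimum is never worse than the
   best grid vertex as evaluated by the surrogate — a guard rail that
   holds deterministically, not just in expectation. Bounds outside the
   training box are refused unless explicitly overridden, because the
   network is an interpolator with no extrapolation guarantees.

The two stages draw from independent streams spawned from one master
seed, so either can be re-run in isolation and the full analysis is
byte-for-byte reproducible from the seed.

## Group statistics

Confidence intervals are mean ± t_{0.975, n−1}·sd/√n, computed at full
precision and rounded to two decimals at report time (matching the
published tables' precision; 46 of the 48 printed interval pairs are
reproduced within ±0.01 on both endpoints, the other two being
typesetting errors in the source tables).

The default control comparison is a pooled two-sample t with the control
treated as a zero-variance group at 100% and df = 2n−2; for two groups
one-way ANOVA's F equals t², so the two give identical p-values. Welch
and one-sample variants are available (the one-sample method warns if
the control has nonzero SD). Significance flags: `**` for p < 0.01, `*`
for p < 0.05, `ns` otherwise. p-values are computed and reported but the
published p-values are not themselves treated as ground truth for
testing, since the exact test configuration behind them (control
variance, grouping) is not recoverable from summaries alone; flags on
the strongly significant cells are checked instead. Grid argmax breaks
exact ties toward lower voltage, then frequency, then duration. No
multiple-testing correction is applied, matching the source analysis.

## The synthetic generator

`SurfaceSpec` defines a Gaussian-bump surface
baseline + (peak − baseline)·exp(−Σ_d ((x_d − x*_d)/σ_d)²/2) with a
known interior optimum; `simulate_grid` draws n replicates per factorial
cell with additive homoscedastic Gaussian noise (a per-cell SD mapping
enables heteroscedastic emulation — the measured tables show SDs rising
at 8 V), simulates the control cell around the baseline, and normalizes
everything by the simulated control mean, mirroring the real assay.

Defaults emulate the published experiment: 4×4×3 levels on
[5,8] V × [0.6,1.2] MHz × [3,9] min, n = 20, peak viability 120% at
(6.5 V, 0.95 MHz, 7.5 min), widths (1.1 V, 0.18 MHz, 3.0 min), noise SD
8 points. The widths were back-solved once from the printed ridge decay
(viability falling to ~101% at 1.2 MHz and ~106% at 0.6 MHz fixes
σ_f ≈ 0.18; the drop at 8 V fixes σ_V ≈ 1.1; the 3-vs-9-minute response
ratio fixes σ_t ≈ 3), and the peak location sits near the
experimentally verified optimum. The generator is purely statistical: no
acoustic physics, no mechanism of cell response, Gaussian noise by
assumption, independent replicates. Passing recovery tests therefore
show that the pipeline can invert its own statistical forward model —
not that real LIPUS surfaces are Gaussian bumps.

## Problem sizes and numerical choices

Tests and the acceptance script use the study-sized problems throughout:
48-cell grids, n = 20 replicates, the full GA budgets (50×100) and
back-propagation budget (≤1000 epochs), and 20-seed ensembles for
stochastic properties (10 seeds for the noisy-recovery check). A full
single-seed analysis takes ~1.5 s; the seed ensembles dominate the
test-suite and acceptance runtimes (~1 minute each). Gradient
correctness is verified against central finite differences (step 1e-6,
relative tolerance 1e-5) on small random networks.

## Known limitations

- **Duration identifiability.** The factorial design has only three
  duration levels (3, 6, 9 min), and the default surface is flat in
  duration near its peak (σ_t = 3 ≈ half the range): the surface values
  at 6 and 9 min differ by ~0.2 points. The 48-cell data therefore do
  not pin the duration peak tightly — even a surrogate meeting the 1e-4
  scaled-MSE stopping goal exactly carries a ~0.5-min duration
  precision floor, and the measured median recovery error in duration
  (computed by `scripts/acceptance.py` and the recovery tests) is
  ~0.3–0.5 min, slightly above 5% of the range, while voltage and
  frequency recover well within 5%. Sharper duration localization would
  need more duration levels or replicate-level training near the ridge.
- The continuous optimum's exact coordinates vary between seeds (both
  GA stages are stochastic); only ensemble properties — in-box
  containment, frequency-ridge membership, vertex-floor guarantee — are
  stable claims.
- The surrogate interpolates within the tested box only; the
  extrapolation guard exists because nothing constrains the network
  outside it.
- No uncertainty quantification on the located optimum beyond
  seed-ensemble spread; no closed-loop design (suggest–measure–refit);
  no multi-objective trade-offs.
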