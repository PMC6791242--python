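# lipusopt

Surrogate-assisted optimization of low-intensity pulsed ultrasound (LIPUS)
stimulation parameters for bone marrow mesenchymal stem cell (BMSC)
viability.

## The problem

LIPUS is a noninvasive way to stimulate cell proliferation, but hardware
only offers discrete settings of driving voltage, frequency and exposure
duration. A factorial experiment — here 4 voltages × 4 frequencies × 3
durations = 48 conditions, each measured 20 times by CCK-8 assay and
expressed as percent of an unstimulated (0 MHz) control — tells you which
*tested* condition is best, but the true optimum generally falls between
the grid points. `lipusopt` closes that gap with a GA-BPNN: a small
back-propagation neural network (BPNN) surrogate of the viability surface
whose initial weights are found by a genetic algorithm (GA), followed by a
second GA search of the *continuous* parameter box using the trained
surrogate as the objective.

The package is for experimentalists who have (or simulate) such a
factorial viability grid and want a reproducible, tested pipeline for the
surrogate fit, the continuous optimization, and the accompanying group
statistics.

## The model

The surrogate is a one-hidden-layer network. For scaled inputs
$x_i$ (voltage, frequency, duration mapped to $[0,1]$):

$$y_j = f\Big(\sum_i \omega_{ij} x_i - a_j\Big), \qquad
O_k = \sum_j y_j\,\omega_{jk} - a_k,$$

with $f$ the logistic sigmoid, a linear output, and trained thresholds
$a_j, a_k$. Training is per-sample gradient descent on
$E = \tfrac12\sum_k (d_k - O_k)^2$ with learning rate $\eta = 0.1$, at
most 1000 epochs, stopping when the epoch MSE reaches $10^{-4}$ (scaled).
The weight vector is pre-optimized by a real-coded GA (population 50, 100
generations, crossover probability 0.8, mutation probability 0.1,
elitism) with fitness $-\mathrm{MSE}$; the same GA engine then maximizes
the trained surrogate over the stimulation box
$[5,8]\,\mathrm{V}\times[0.6,1.2]\,\mathrm{MHz}\times[3,9]\,\mathrm{min}$.

Group statistics mirror the experimental report: t-based 95% confidence
intervals $\bar{x} \pm t_{0.975,\,n-1}\, s/\sqrt{n}$, pooled two-sample
t comparisons against the 100% control, and improvement percentages.

## Worked example

The packaged study grid (48 cells, mean ± SD, n = 20) ships with the
package:

```python
>>> import lipusopt as lo
>>> grid = lo.load_study_grid()
>>> from lipusopt import stats
>>> stats.grid_argmax(grid)
(StimulationCondition(voltage=6.0, frequency=1.0, duration=9.0), 119.57)
>>> stats.t_confidence_interval(119.57, 3.85, 20)
(117.77, 121.37)
```

The strongest measured condition is 6 V, 1 MHz, 9 min at 119.57% of
control (a 19.57-point improvement), and its 95% CI is [117.77, 121.37].
The full pipeline from the shell:

```console
$ lipusopt run --seed 1 --out demo_report
optimum: 5.75 V, 0.90 MHz, 9.0 min -> predicted viability 119.24%
```

The located optimum is a *continuous* condition on the grid's
high-viability ridge (frequency between 0.8 and 1 MHz); its exact
coordinates vary a little from seed to seed because both GA stages are
stochastic. `demo_report/` contains `report.json`, the per-cell stats
table `stats.csv` (mean, SD, CI, p-value and significance flag per
condition, reproducing the published intervals), the surrogate
`model.json`, and the GA convergence traces as CSV.

Synthetic data with a known planted optimum, for testing recovery:

```console
$ lipusopt simulate --seed 1 --out grid.csv --replicates
$ lipusopt fit --grid grid.csv --seed 0 --out model.json
$ lipusopt optimize --model model.json --bounds 5:8,0.6:1.2,3:9 --seed 0 --out result.json
```

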