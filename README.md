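# ecophys

Calculations for characterizing slow-growing marine bacterial isolates —
growth kinetics from sparse flow-cytometry growth curves, capsule-geometry
cell morphometrics from electron micrographs, artificial-seawater medium
design, and downstream metagenomic ecology summaries (RPKM abundance, ANI
species clustering). It is aimed at microbiologists characterizing
dilution-to-extinction isolates (e.g. pelagic Roseobacters such as the
CHAB-I-5 lineage) where cultures are counted at a handful of irregular time
points and classical exponential-phase fitting is unreliable.

## The estimator

Growth curves are analyzed on log2-transformed cell densities N(t):

1. every consecutive triplet of time points gets an ordinary least-squares
   fit of log2 N vs. t; the slope is an **instantaneous doubling rate**
   (doublings/day) and its standard error (1 residual degree of freedom) is
   `sqrt(SSE / Σ(tᵢ − t̄)²)`;
2. each window fans out into **nine candidates** — {slope − se, slope,
   slope + se} assigned to the window's start, middle and end times;
3. the **median** candidate rate is taken at each unique time point;
4. the exponential phase is delimited by fitting a decreasing sigmoid
   `r(t) = r_low + (r_high − r_low) / (1 + exp((t − t_inflect)/τ))` to rate
   vs. time and keeping the points before the inflection `t_inflect`; when
   the fit fails, the three rates of largest |r| are kept instead;
5. replicates are pooled per condition (median ± SD of exponential-phase
   rates plus a growth/no-growth call), and condition summaries assemble
   into growth envelopes over temperature, salinity, or carbon.

Cell morphometrics treat each cell as a capsule (spherocylinder) whose 2-D
projection is a stadium of area `S = 2r(l − 2r) + πr²`; inverting S at each
measured radius r gives length `l`, volume `V = πr²(l − 2r) + (4/3)πr³`, and
surface area `SA = 2πr(l − 2r) + 4πr²`. Ecology helpers compute
`RPKM = reads / (genome kb) / (recruited Mbp)`, subcluster-summed
abundances, single-linkage clusters at the ~95% ANI species boundary, the
dereplication quality score `completeness − 5 × contamination`, and
Spearman abundance–environment correlations. A seeded `simulate` module
generates growth curves (logistic/Gompertz with lognormal counting noise),
cardinal-model condition grids, capsule cell populations, and recruitment
tables, so every stage runs end-to-end without downloads.

## Worked example

```python
import numpy as np
from ecophys.simulate import GrowthSimParams, simulate_growth_curve
from ecophys.growth import estimate_rate_series, fit_sigmoid_decay, summarize_condition

p = GrowthSimParams(N0=1e4, K=1e7, mu=1.5, noise_cv=0.01,
                    sample_times=tuple(np.linspace(0, 6, 10)), seed=1)
curve = simulate_growth_curve(p)          # true rate: 1.5 doublings/day
series = estimate_rate_series(curve)      # per-time median candidate rates
fit = fit_sigmoid_decay(series)
summ = summarize_condition([curve])
```

The median rate series starts near the true rate and decays as the culture
approaches capacity:

```
 t (d)  rate
 0.00   1.497
 0.67   1.484
 ...
 5.33   1.259
 6.00   1.180
```

the sigmoid fit converges with `t_inflect = 5.267` days, and the pooled
summary prints

```
representative rate 1.475 +/- 0.057 doublings/day
growth_call: True   fold increase: 338.7
```

i.e. the exponential-phase median recovers the simulated 1.5 doublings/day
to within 2%, and the culture is called growth-positive (rate above
0.1 doublings/day and more than a 4-fold density increase).

The same operations are available from the shell, e.g.

```sh
ecophys media salinity --cl 1          # -> 1.80655
ecophys media carbon --mix met:1:5,gly:5:2,pyr:5:3 --target 300
ecophys growth envelope growth.csv --variable temperature_C
ecophys eco ani-cluster ani.csv --threshold 95
```

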