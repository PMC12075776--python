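# Methods

## Sparse growth-curve rate estimation

The estimator assumes only that cell density grows log-linearly during
exponential phase; it makes no global model assumption about lag or
stationary phase. All regressions are on log2-transformed densities, so
slopes are directly in doublings (divisions) per day.

**Windows.** Windows are consecutive, stride-1 triplets of time points: a
curve of n points yields n − 2 windows and every interior time point sits
in up to three of them. Stride 1 extracts the most information from sparse
curves. Window size is fixed at 3 in this version; a 3-point regression has
exactly one residual degree of freedom, so the slope uncertainty is the OLS
standard error `se = sqrt(SSE / Σ(tᵢ − t̄)²)`. The slope and intercept come
from `scipy.stats.linregress`; the standard error is recomputed from the
residuals because `linregress` reports NaN for zero-variance (perfectly
flat) windows, where the correct value is 0. Densities of zero are rejected
rather than floored: log2(0) is undefined and cytometry counts of a live
culture are positive.

**Candidates and medians.** Each window contributes the Cartesian product
{slope − se, slope, slope + se} × {start, middle, end time} — nine
candidates — and the per-time estimate is the plain median of all candidates
assigned to that time. Candidates are pooled without deduplication or
window weighting; the median is invariant to candidate ordering and to how
batches are split or merged. Negative rates (death phase) are retained
through the median step.

**Exponential-phase detection.** A four-parameter decreasing logistic
`r(t) = r_low + (r_high − r_low)/(1 + exp((t − t_inflect)/τ))` is fitted to
the median rate series by bounded least squares
(`scipy.optimize.least_squares`), initialized at r_high = max rate,
r_low = min rate, t_inflect = mid-span, τ = span/8, with up to 5 restarts
from jittered initials (fixed internal seed, so the fit is deterministic).
The fit is accepted only when the optimizer reports success, t_inflect lies
inside the observed span, and r_high > r_low; series with fewer than 4
distinct times or zero rate range are rejected up front. An accepted fit
delimits exponential phase as the times strictly before t_inflect. On
rejection — or when no time precedes the inflection — the fallback keeps
the three rates of largest absolute value (all of them if fewer than
three), breaking ties on |r| by earlier time. Absolute values matter here
because death-phase rates are negative.

**Condition summaries and envelopes.** Exponential-phase (time, rate) pairs
are pooled across replicates. The representative rate is the pooled median;
dispersion is the pooled sample SD (0 for a single value); the mean and the
min–max range are also reported because published "±" conventions vary
(median ± SD is the primary convention here). A condition is
growth-positive when the representative rate is at least
0.1 doublings/day **and** some replicate at least quadrupled its starting
density; both thresholds are arguments. The envelope over a condition
variable reports the (min, max) of growth-positive values, the non-positive
values, and the arg-max condition; an all-negative grid yields a flagged
empty envelope (NaN max rate) rather than an error.

## Capsule morphometrics

Each cell is measured as one segmented projected area S (pixel², converted
to μm² by the squared image scale) and one or more radii r probed at
different sections. The cell body is modelled as a capsule: a cylinder of
height h = l − 2r capped by two hemispheres. Its projection is a stadium,
`S = 2r(l − 2r) + πr²`, which is inverted per radius to
`l = (S − πr²)/(2r) + 2r`; volume and surface area follow from the closed
capsule formulas. Curvature of bent rods is ignored — a curved tube of the
same axis length has identical volume, and no curvature parameter is
recoverable from (S, r) alone.

A radius measured at a bulge can violate S ≥ πr²; such radii are flagged
invalid and excluded from the per-cell mean/median (the cell fails only if
every radius is invalid). Per-cell representatives default to the median;
population summaries report mean, median and SD of each parameter over the
per-cell representatives and export a long-format table for violin plots.

Known limitation: per-radius inversion of a single shared area is a
nonlinear map, so population means of volumes derived this way need not
match the capsule formula evaluated at mean length and mean radius;
consumers comparing against externally reported mean dimensions should be
aware of this averaging non-commutativity.

## Medium calculators

Chlorinity → salinity uses the classical factor 1.80655 and covers the base
salts only; chloride contributed by nutrient stocks is negligible at the
relevant concentrations and defaults to 0 (an additive term can be passed
by adjusting the input). Two-batch mixing fractions are exact linear
interpolation, `f_hi = (target − lo)/(hi − lo)`. Carbon accounting sums
concentration × carbon atoms per molecule; atom counts are always supplied
explicitly (a reference table covers methionine 5, glycine 2, pyruvate 3,
asparagine 4, and the other substrates used with these media) so that a
typo in a compound name fails loudly instead of silently mis-counting.
`mix_for_target` scales a molar ratio so total carbon hits the target
exactly; it and `carbon_total` are exact inverses. Requested series values
are computed exactly and not re-rounded to match any particular lab's
dilution conventions.

## Ecology summaries

RPKM is reads per kilobase of genome per million recruited read base pairs:
`counts / (length/10³) / (bp/10⁶)`. The per-sample denominator defaults to
the base pairs of reads recruited competitively to the reference set; a
flag switches to total sample base pairs, since pipelines differ in which
denominator they export. RPKM is exactly 0 where the count is 0.
Subcluster abundances are exact sums over member genomes; genomes missing
from the membership map are excluded with a warning to tolerate partial
subcluster definitions.

ANI clustering symmetrizes a possibly asymmetric matrix (arithmetic mean by
default, elementwise min by flag), draws an edge wherever symmetrized
identity reaches the threshold (default 95%, the conventional bacterial
species boundary), and takes connected components — single linkage, so the
threshold constrains edges, not all within-cluster pairs; the within-cluster
minimum and median and the between-cluster min/max are reported as
statistics. fastANI-style long input is pivoted to a square matrix; pairs
fastANI left unreported (below its reporting range) are filled with 0,
which cannot create spurious edges. The genome quality score is
completeness − 5 × contamination, in percent. Abundance–environment
association uses Spearman rank correlation with pairwise-complete samples
(≥ 3 required); constant abundance is flagged undefined rather than
reported as 0.

## Synthetic data

The generators define the study conditions for all recovery tests and are
deterministic given their seed.

* **Growth curves**: N(t) = N0 before the lag, then logistic growth toward
  carrying capacity K at true rate μ (doublings/day); Gompertz is available
  by flag but logistic is the default truth model since the estimator only
  assumes log-linear early growth. Observation noise is multiplicative
  lognormal with coefficient of variation `cv`
  (σ = sqrt(ln(1 + cv²)), so E[observed] = N(t)·e^{σ²/2}), matching the
  scaling of cytometry counting error. Defaults: N0 = 10⁴ cells/ml,
  K = 10⁷ cells/ml (a typical oligotroph culture yield), μ = 1.5
  doublings/day, cv = 1%, 10 samples over 6 days — a sparse sampling design
  with ≥ 8 points spanning exponential phase.
* **Condition grids**: the cardinal (CTMI-form) response maps temperature
  (or a salinity analogue) to μ, equal to μ_opt at T_opt and 0 at and
  outside (T_min, T_max); it was chosen over a quadratic because real
  thermal envelopes are asymmetric. Per-condition/replicate seeds are
  derived from the base seed.
* **Cell populations**: true (l, r) are lognormal (defaults: median length
  1.65 μm, median radius 0.23 μm, GSDs 1.25/1.15 — small-coccobacillus
  scale) with l ≥ 2r enforced by resampling; the emitted area is the exact
  stadium projection, and each of the per-cell radius measurements carries
  multiplicative lognormal noise (cv 3%).
* **Recruitment tables**: log abundance = baseline + slope × environment +
  Gaussian noise per genome and sample, normalized per sample and converted
  to read counts by flooring against the per-sample base-pair budget (so
  counts × read length never exceed it). The normalization makes the model
  compositional: only slope *differences* between genomes are identifiable
  downstream, which is why the default gives the first two genomes a
  steeper negative environment response than the last two.

What the simulations do not emulate: real cytometry gating artifacts,
autocorrelated plate/batch effects, cell-shape classes other than capsules,
genome-content-driven recruitment bias, and compositional zeros from
detection limits. Passing recovery tests therefore demonstrates
correctness of the estimators under their stated assumptions, not
robustness to every artifact of real data.

## Problem sizes

Recovery experiments use 200 seeds for the growth-rate chain (10-point
curves), a 9-point temperature grid with 2 replicates for the envelope, 50
samples for the correlation sign check, and matrices up to 20 genomes for
the clustering cross-checks — sizes at which the brute-force oracles are
exact and the full suite runs in well under a minute.
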