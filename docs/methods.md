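# Methods

## Simulation model

A simulated dataset is a matrix of `n_series` features by
`n_timepoints × replicates` columns on an evenly spaced grid. Times follow
the half-open convention `[0, duration)`: a 48 h experiment at 2 h
resolution has 24 timepoints T00…T46. This convention makes the derived
designs compose exactly — keeping every other timepoint of 48 h @ 2 h *is*
48 h @ 4 h (12 points), and the first half of that *is* 24 h @ 4 h
(6 points) — and it keeps duplicated-and-concatenated grids evenly spaced.

Rhythmic series follow `y(t) = M + A·cos(2π(t − φ)/T) + ε` with
`T ~ U[period_min, period_max]`, `A ~ U[amp_min, amp_max]`,
`φ ~ U[0, T)`, and `ε ~ N(0, noise_sd²)` i.i.d. per cell; arrhythmic series
are `M + ε`. Exactly `round(frac_rhythmic · n_series)` series are rhythmic
(a seeded random subset — the count is a design constant, not a binomial
draw). Negative amplitudes are legal and equivalent to a half-period phase
shift; the signed draw is stored in the truth table. Arrhythmic truth
parameters are NA, never 0. One `numpy` generator stream seeds the whole
dataset, consumed in a fixed order (truth, then noise, then outliers), so
config + seed reproduces the matrix bit-for-bit.

Defaults: mesor 10 and noise SD 1 in arbitrary expression units (the mesor
merely has to sit far enough above zero for fold changes to be defined;
both are configurable), amplitude range 1–3 (signal-to-noise 1–3, spanning
barely- to easily-detectable rhythms), period fixed at 24 h, 1000 series,
half rhythmic. Optional outliers replace each cell independently with
probability `outlier_rate` (default 0.01) by `value ± outlier_magnitude ·
noise_sd` (default magnitude 5, sign equiprobable) — a simple, severity-
controlled mechanism.

What the generator deliberately does **not** emulate: batch effects,
clustered or non-uniform phase distributions, trends and autocorrelated
("red") noise, asymmetric or pulsed waveforms, and count-distribution
artifacts of sequencing. Passing benchmarks here therefore demonstrate
behaviour under clean sinusoid-plus-Gaussian conditions; real data are
harder, and absolute power numbers should be read as upper bounds.

## Rhythm detection

### Statistic

For a candidate (period, phase) the reference template is
`cos(2π(t − phase)/period)` evaluated at each column's time. Columns with
equal template values (all replicates of a timepoint, plus symmetric points
of the cosine) form tie groups; groups are ranked by template value. The
test statistic is the tie-aware Kendall score

    S = Σ_{pairs (i,j) in distinct groups} sign(y_j − y_i)·sign(rank_j − rank_i).

Pairs tied in the template are excluded; pairs tied in the data contribute
zero (ties are almost surely absent in simulated Gaussian data, and tied
real data are thereby handled conservatively).

### Exact null

Under the null that all orderings of distinct data values are equally
likely, the number of cross-group discordant pairs of a uniform random
ordering is distributed as the coefficients of a Gaussian q-multinomial,
which factors into independent Mann–Whitney blocks: inserting a tie group
of size `m` after `s` already-placed columns adds an exactly
`U(m, s)`-distributed count. Each block PMF is built with the classical
two-sample recursion (all-positive, numerically stable) and the blocks are
convolved; `S = max_pairs − 2·discordances`. The distribution depends only
on the multiset of tie-group sizes and is cached by that signature. The
computation is exact for any design here; a hard cap of 256 columns guards
against pathological requests, raising an explicit capacity error. The test
suite verifies the construction against full permutation enumeration for
every tie signature up to six columns.

### Search, p-values and conventions

The phase grid spans the **full** cycle at `phase_step_h` resolution
(default: the sampling interval) and tails are **two-sided**:
`p = P(|S_null| ≥ |S_obs|)`. A template and its half-period shift then give
identical two-sided p-values, so the Bonferroni factor
`p_adj = min(1, n_alternatives · min p)` double-counts that redundancy.
This is intentional: it reproduces the convention of the widely used JTK
implementation, whose extra factor ≈ 2 of conservatism is precisely what
keeps null hit rates at adjusted p < 0.05 well under the nominal level
(measured here at ≈1.5% for the 48 h designs, and *exactly zero* for the
6-point 24 h @ 4 h design, whose smallest attainable adjusted p is
6 × 1/90 ≈ 0.067). The convention is logged at INFO on every run.
`q_bh` applies Benjamini–Hochberg across series to the per-series `p_adj`.

The winning alternative is the minimal-p template, ties broken toward
positive S; if S < 0 the reported phase is shifted by half a period. The
reported `best_phase_h` is the template grid phase — deliberately at
phase-grid granularity, which is what makes dense sampling measurably
better than replication for phase estimation at equal sample count.
Amplitude, mesor, fold change and R² come from the cosinor fit at the best
period (below). Constant series yield S = 0 everywhere, `p_adj` = 1 and an
NA phase.

`p_raw` (the minimum over alternatives) is *not* a calibrated p-value —
with ~12 correlated alternatives `P(p_raw ≤ 0.05)` on null data is ≈0.15.
The calibrated quantities are the per-alternative exact p (when one
alternative is searched, `p_raw` equals it) and `p_adj`; the acceptance
suite checks both bounds, exactly on the null distribution and empirically
on 10⁴ simulated noise series.

## Cosinor regression

`y = M + b_c·cos(ωt) + b_s·sin(ωt)` by ordinary least squares at a fixed
period, then `A = √(b_c² + b_s²) ≥ 0`, `φ = atan2(b_s, b_c)/ω mod T`,
R² as variance explained (0 for constant series), and fold change
`(M + A)/(M − A)` defined only for a positive fitted trough (NA otherwise).
Designs whose sampling times alias modulo the period (rank-deficient
design matrix, or fewer than three distinct timepoints) are rejected.

## Design manipulations

`duplicate_concatenate(ds, k)` tiles the matrix to `k` total copies, copy
`c` spanning `[c·duration, (c+1)·duration)`; "first concatenation" = 2
total copies. Values per original timepoint are replicated exactly and the
ground truth is untouched. Time labels continue in absolute hours (T48,
T50, …) so the tiling is visible in any exported file, and the operation
logs itself as a malpractice simulation. `downsample(ds, k)` keeps every
k-th timepoint; `truncate(ds, H)` keeps times below H. All manipulations
preserve truth and series count and append to the dataset provenance.

## The false-positive-inflation experiment

`run_inflation_experiment` simulates 1000 pure-noise series on 48 h @ 2 h,
derives 48 h @ 4 h (every other timepoint) and 24 h @ 4 h (its first half)
from the *same* noise draw, and for concatenation levels 0–3 (1–4 total
copies) runs the detector (period set {24 h}) and tabulates the hit rate at
adjusted p < 0.05 plus its fold change versus the design's own level-0
baseline. The 24 h @ 4 h design has a structurally zero baseline (see
above) and is excluded from cross-design fold-change minima, which is why
those minima are taken over designs with a nonzero baseline.

Because a fold change divides by a baseline of only ~15 expected hits per
1000 series, a single run of the protocol carries ~25% relative noise on
the level-1 fold. The experiment therefore supports pooling: the identical
1000-series protocol is repeated on independent noise draws (replicate
seeds derived from the master seed) and hit counts are pooled before rates
and ratios are formed. The acceptance script and acceptance tests use 16
replicates (16,000 series per design), bringing the fold-change noise to a
few percent; per-replicate conditions, thresholds and bounds are unchanged
by pooling.

## Numerical choices

- Template tie grouping rounds cosine values to 9 decimals before grouping,
  so replicates and symmetric grid points merge robustly.
- Exact-null block PMFs use the all-positive Mann–Whitney recursion in
  float64; probabilities are renormalized once after convolution (the sum
  is 1 to ~10⁻¹⁵ anyway).
- Ties in the winning-alternative choice break toward the largest S, then
  the first alternative in grid order.
- Grid arithmetic (divisibility, truncation multiples) tolerates 10⁻⁹
  absolute error to absorb float time arithmetic.
- BH adjustment delegates to `statsmodels`; inputs are validated to (0, 1].

## Known limitations

- The detector searches a discrete (period, phase) grid; period resolution
  is whatever the user supplies (default: the single period 24 h), so
  period-recovery error reflects grid granularity, not estimator variance.
- Exact p-values are discrete; at very small designs (6 points) the test
  cannot reach adjusted p < 0.05 at all. That is faithful to the underlying
  method and is precisely the power cost of short experiments, but it means
  "power" at such designs is exactly zero rather than merely small.
- The Gaussian noise model understates false-positive rates expected under
  autocorrelated noise; inflation results here are therefore conservative
  for real data.
- Fold change requires a positive fitted trough; low-mesor simulations can
  produce many NA fold changes.
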