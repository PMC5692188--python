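# circabench

Benchmarking toolkit for genome-scale biological-rhythm detection.

Omics time courses (transcriptomics, proteomics, metabolomics) are routinely
screened for circadian rhythmicity, and the outcome depends heavily on
experimental design — duration, sampling interval, replication — and on the
statistics applied afterwards. `circabench` lets you measure those effects
empirically instead of guessing: it simulates expression-like time series
with known ground truth, detects rhythmicity with an exact nonparametric
test plus cosinor parameter estimation, applies the design manipulations
people actually (mis)use — duplication/concatenation, down-sampling,
truncation — and scores everything against the truth.

It is aimed at anyone planning or reviewing a rhythm-screening experiment:
how many false positives does my pipeline produce on pure noise? How much
power do I lose by sampling every 4 h instead of every 2 h? What happens to
the false-positive rate if someone tiles a 24 h series into a fake 96 h one?

## The statistics inside

**Simulator.** Each rhythmic series is a cosine
`y(t) = M + A·cos(2π(t − φ)/T) + ε`, with period `T` and amplitude `A`
uniform in user ranges, acrophase `φ` uniform over the cycle, mesor `M`
common to all series, and i.i.d. Gaussian noise `ε ~ N(0, σ²)` per
(timepoint, replicate) cell. Arrhythmic series are mesor plus noise.
Exactly `round(frac_rhythmic·n)` series are rhythmic and the truth (period,
phase, amplitude) is stored alongside the values. Optional symmetric
outlier spikes can be superimposed.

**Detector.** A JTK-style rank test: the data are compared against cosine
reference templates on a (period, phase) grid via the tie-aware Kendall
statistic `S = Σ sign(y_j − y_i)·sign(r_j − r_i)` over column pairs in
distinct template tie groups. The null distribution of `S` is computed
*exactly* by convolving Mann–Whitney blocks (the Gaussian-multinomial
construction), so p-values need no large-sample approximation. Per series,
`p_adj = min(1, n_alternatives · min p)` Bonferroni-corrects the within-series
search (phases span the full cycle; two-sided tails) and `q_bh` is the
Benjamini–Hochberg FDR across series. Amplitude, mesor, fold change
(peak/trough) and R² come from a cosinor least-squares fit at the best
period; the reported phase is the winning template's, at phase-grid
resolution.

**Benchmark.** Confusion counts (TP/FP/TN/FN), FPR/TPR/observed FDR,
circular phase error `min(|Δφ|, T − |Δφ|)`, period and relative amplitude
errors, and the duplication/concatenation false-positive-inflation
experiment (`run_inflation_experiment`).

## Worked example

```python
from circabench import (SimulationConfig, synthesize_dataset, JTKDetector,
                        classify_hits, confusion_metrics, parameter_recovery)

cfg = SimulationConfig(duration_h=48, interval_h=2, n_series=1000,
                       frac_rhythmic=0.5, amp_min=1.0, amp_max=3.0,
                       noise_sd=1.0, seed=1)
ds = synthesize_dataset(cfg)                      # 1000 x 24 matrix + truth
det = JTKDetector(period_set=(24.0,)).fit_dataset(ds)
print(det.results_.head(5).round(4).to_string(index=False))
```

```
   series_id  p_raw  p_adj  q_bh  best_period_h  best_phase_h   mesor  amplitude  fold_change  r_squared
series_00000 0.3828    1.0   1.0           24.0          10.0 10.1082     0.0819       1.0163     0.0048
series_00001 0.1531    1.0   1.0           24.0          12.0  9.9958     0.3542       1.0735     0.1143
series_00002 0.2401    1.0   1.0           24.0          14.0 10.2861     0.4257       1.0863     0.0668
series_00003 0.4108    1.0   1.0           24.0          10.0 10.1367     0.2963       1.0602     0.0481
series_00004 0.0000    0.0   0.0           24.0          16.0  9.8726     2.2945       1.6055     0.8454
```

Series 4 is a detected rhythm: adjusted p (and q) ≈ 0 at the searched 24 h
period, peaking at ~16 h with fitted amplitude 2.29 around a mesor of 9.87
(fold change 1.61, 85% of its variance explained by the cosine). Series
0–3 are noise or sub-threshold rhythms. Scoring against the truth:

```python
hits = classify_hits(det.results_, 0.05, "q_bh")
s = confusion_metrics(hits, ds.truth, det.results_)
print(f"tp={s.tp} fp={s.fp} tn={s.tn} fn={s.fn}  "
      f"tpr={s.tpr:.3f} fpr={s.fpr:.4f} fdr={s.fdr_observed:.4f}")
# tp=465 fp=2 tn=498 fn=35  tpr=0.930 fpr=0.0040 fdr=0.0043
rec = parameter_recovery(det.results_, ds.truth, hits=hits.to_numpy())
# median circular phase error 0.645 h, median amplitude rel. error 0.085
```

So at q < 0.05 this design recovers 93% of the planted rhythms with 2 false
alarms among 500 noise series, and phase estimates land within ~0.6 h of
truth on average.

The same workflow is available from a shell:

```bash
circabench generate --seed 1 --n-series 1000 --out ds.csv
circabench detect ds.csv --period 24 --out results.csv
circabench manipulate ds.csv --duplicate 2 --out tiled.csv   # malpractice, loudly logged
circabench benchmark ds.csv results.csv
circabench inflation --n-series 1000 --seed 1 --out inflation.csv
```

## Layout

- `circabench.simulate` / `circabench.config` — ground-truth generator
- `circabench.detect` / `circabench.nulldist` — rank test and exact null
- `circabench.cosinor` — cosinor regression
- `circabench.manipulate` — duplication, down-sampling, truncation
- `circabench.benchmark` — scoring and the inflation experiment
- `circabench.io` / `circabench.cli` — CSV dialects, manifests, CLI

See `docs/methods.md` for the model, conventions and limitations.
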