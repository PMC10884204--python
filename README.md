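# microstates

EEG microstate analysis with a built-in reliability layer and a synthetic
ground-truth generator.

Resting-state EEG does not wander continuously between topographies: the
scalp potential field stays quasi-stable for ~40–120 ms, then switches
abruptly to another configuration. These *microstates* — conventionally
five types labeled A, B, C, C′ and D — are candidate markers of large-scale
brain-network dynamics, which makes their **retest-reliability** a first-order
question: a characteristic that does not agree with itself across sessions
cannot index a trait. This package implements the full analysis chain on
already-clean EEG and the statistics needed to study that reliability, for
researchers who want a tested, scriptable alternative to GUI toolboxes:

- **Core model** (`microstates.maps`): montages on the unit sphere,
  average-referenced topographies, recordings; global field power
  (GFP — the spatial standard deviation of the map,
  `GFP(v) = sqrt(mean_c v_c²)` after average referencing), GFP-peak
  extraction, polarity-invariant spatial correlation.
- **Clustering** (`microstates.clustering`): polarity-invariant modified
  k-means and AAHC (atomize-and-agglomerate hierarchical clustering) over
  GFP-peak maps; both maximize the global explained variance
  `GEV = Σ_i (GFP_i · r_i)² / Σ_i GFP_i²` with `r_i` the spatial correlation
  between map *i* and its template. Two-level grand-mean clustering with a
  one-to-one subject↔grand-mean matching constraint, grand-grand-mean
  consistency (the criterion for choosing the number of clusters), and
  template sorting against a normative reference.
- **Fitting** (`microstates.fitting`): grand-mean (GM) and individual (Ind)
  back-fitting — peak labeling by maximal |spatial correlation|,
  nearest-neighbor label interpolation, and window/penalty temporal
  smoothing (default 20 ms window, penalty 1).
- **Characteristics** (`microstates.characteristics`): per-type durations
  (ms), occurrences (/s), coverages (%), the transition excess statistic
  `100 · (observed/s − expected/s) / (expected/s)` with
  `expected_{j→k} = occ_j · occ_k / Σ_{m≠j} occ_m`, plus explained
  variance, mean duration, mean occurrence and mean GFP.
- **Reliability** (`microstates.reliability`): single-measure
  absolute-agreement ICC(A,1) from two-way ANOVA mean squares with F-based
  CIs, Fisher-z averaging of correlations, z-tests for differences between
  correlations, per-type map reliability, retest interval groups
  (1–7 / 8–30 / 31–90 / 91–180 / ≥181 days).
- **Synthetic data** (`microstates.simulate`): quasi-dipolar templates,
  semi-Markov state sequences with gamma dwell times, 10 Hz oscillatory
  envelopes, calibrated SNR at GFP peaks, and subject/session variance
  components with a *designed* true ICC — so every stage of the pipeline can
  be validated against known truth.
- **Orchestration** (`microstates.pipeline`, `microstates.cli`): YAML-driven
  end-to-end runs (`simulate → cluster → fit → stats → reliability`) and a
  thin `microstates` command-line wrapper.

## Worked example

```python
import numpy as np
import microstates as ms

montage = ms.standard_1020_montage()            # idealized 30-channel 10-20 cap
templates = ms.make_templates(montage, K=5, seed=3)
design = ms.CohortDesign(duration_s=60.0, snr=4.0, seed=3)
recording, truth = ms.simulate_recording(templates, design, seed=3)

seq = ms.gm_fitting(recording, templates)       # GM back-fitting + smoothing
stats = ms.compute_stats(recording, seq)
print(round(np.mean(seq.labels == truth.label_sequence), 3))  # 0.972
print(round(stats.explained_variance, 1))                     # 88.7
print(round(stats.mean_duration_ms, 1))                       # 61.1
```

At SNR 4 the five templates capture 88.7% of the GFP-weighted map variance,
97.2% of samples carry their true label (the rest are boundary samples
between GFP peaks), and the recovered mean duration (61.1 ms) sits on the
generator's 60 ms design value. The `examples/` directory walks through each
capability: simulation and ground truth, the two clustering algorithms and
grand means, fitting and characteristics, and a full retest-reliability
analysis with family-average ICCs.

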