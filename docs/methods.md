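# Methods

This note documents the models, numerical choices and known limitations of
the `microstates` package in one place. Everything stated here is computed
by the test suite or the example scripts; nothing is imported from external
results.

## The microstate model

The package treats cleaned, average-referenced resting EEG as a sequence of
quasi-stable scalp potential topographies. A topography is the vector of
channel potentials at one sample; its **global field power** (GFP) is the
population standard deviation of that vector around zero, i.e. the RMS of
the average-referenced map. GFP peaks are moments of maximal
signal-to-noise, and all clustering operates on the maps sampled there.
Polarity is ignored throughout: a map and its sign flip are the same
microstate (the generating dipoles oscillate), so similarity is the
absolute — or, for objectives, squared — spatial Pearson correlation of
average-referenced maps, which for unit-norm centered vectors equals the
cosine of their angle.

**Global explained variance (GEV)** of templates T for maps x_i with
assignments a_i:

    GEV = Σ_i (GFP_i · r_i)² / Σ_i GFP_i²,   r_i = |corr(x_i, T_{a_i})|.

High-GFP maps count more; GEV is the quantity both clustering algorithms
report and (for k-means) optimize across restarts.

## Clustering

**Modified k-means** alternates (a) assigning each map to the template of
maximal squared correlation and (b) re-estimating each template as the
first principal component (leading eigenvector of the outer-product sum) of
its assigned maps, which is the polarity-aware analogue of the cluster
mean. Raw (non-normalized) maps enter the PC update, so high-GFP maps
implicitly carry more weight — consistent with the GEV objective.
Defaults: 20 restarts (initial templates drawn from the data), 200
iterations maximum, convergence when the relative GEV change falls below
1e-6. Restart seeds are spawned from one `SeedSequence`, so the best-of-n
result is reproducible and non-decreasing in the number of restarts. An
emptied cluster is re-seeded from the currently worst-fit map.

**AAHC** starts from singleton clusters and repeatedly dissolves the
cluster whose members contribute least to GEV, reassigns the freed maps to
the most similar remaining cluster map, and re-estimates the affected
cluster maps as first principal components, until K clusters remain. It is
deterministic.

**Two-level (grand-mean) clustering** aggregates per-subject template sets
under a one-to-one constraint: alternating between (a) matching each
subject's K maps to the K grand-mean slots by the permutation maximizing
the summed squared correlation (exhaustive over K!, fine for K ≤ 7) and
(b) updating each grand-mean map as the first PC of its matched subject
maps. Subject maps are unit-norm at this level, so subjects contribute
equally regardless of amplitude. The mean shared variance (mean squared
correlation between subject maps and their matched grand means) is the
convergence monitor and the quality figure reported. The
**grand-grand-mean consistency** — the same construction one level up,
reported as 100 × mean shared variance — is the criterion for comparing
candidate cluster numbers; K = 5 is the package default. Note that for two
sets whose matched maps correlate r, the grand-grand mean is their
bisector, so the consistency is 100·(1+r)/2, not 100·r².

**Template sorting** against a reference (normative maps or another
condition's grand means) uses the same exhaustive matching; signs are
aligned to the reference and near-ties (within 1e-9) are broken
lexicographically with a warning.

## Fitting and smoothing

**GM fitting**: GFP peaks → label each peak map with the template of
maximal |correlation| (ties within 1e-12 go to the lowest template index;
zero-variance maps stay unassigned) → spread labels to all samples by
nearest labeled peak in time (equidistant ties to the earlier peak) →
temporal smoothing. **Ind fitting** first type-matches the subject's own
mean maps to the grand means, then uses those subject maps as the fitting
templates; everything downstream is identical.

Smoothing iteratively relabels sample t with the class k minimizing

    g_t² (1 − r_{t,k}²) − penalty · N_{t,k},

where N_{t,k} counts assigned samples labeled k within ±window/2 around t
(t itself excluded; default window 20 ms, penalty 1) and g is the GFP
normalized by its RMS over assigned samples. The normalization makes the
penalty dimensionless and the labels invariant to rescaling the recording —
an invariant the package guarantees. Iteration runs to a fixed point
(iterated conditional modes) with a sweep cap of 100; penalty 0 disables
smoothing entirely and returns the input labeling. Two caveats are by
design: (1) ICM is a local optimizer — for large penalties the *global*
minimizer of this objective degenerates toward erasing short segments
wholesale, while ICM stays in the basin of the initial labeling, which is
the behavior plugin-style smoothers exhibit; the oracle-equivalence tests
therefore run in the data-dominated penalty regime where the global optimum
is a sensible labeling and ICM attains it (verified against exact dynamic
programming over the banded pairwise objective). (2) Unassigned samples are
excluded from neighbor counts and never relabeled.

Cross-montage work resamples *templates* to the recording's montage (never
the data) with Perrin-style spherical splines: order m = 4, 50 Legendre
terms, ridge 1e-5 on the spline system — standard EEG practice. The splines
reproduce node values to ~1e-3 relative and project smooth dipolar fields
across montages with correlation > 0.99 (tested against analytic fields).

## Characteristics

All rates and percentages use **assigned time** (samples with a label) as
denominator. Per type: duration = mean segment length in ms; occurrence =
segments per second; coverage = percent of assigned samples; these satisfy
coverage = occurrence × duration / 10 exactly. Boundary-truncated segments
(recording edges, gaps) are *included* in duration and occurrence — short
resting recordings make exclusion wasteful — but carry a flag for
sensitivity analyses. The transition statistic compares the observed rate
of direct j→k segment boundaries with the occurrence-expected rate
`occ_j · occ_k / Σ_{m≠j} occ_m` (each type's exits distributed
proportionally to the other types' occurrences) as a percent excess;
transitions across unassigned gaps do not count as observed boundaries, and
cells with zero expected rate are missing values, not zeros. The
expected-rate definition is a documented package decision — published
toolboxes do not all agree on it, which is the main cross-software
comparability risk for transition statistics. Type-independent
characteristics: explained variance (the GEV of the continuous fit, in
percent), unweighted mean duration and occurrence over types present, and
mean GFP (unweighted mean over types of each type's mean sample GFP).

## Reliability statistics

ICC(A,1) — single-measure, absolute-agreement, two-way random — from the
ANOVA mean squares:

    ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n),  k sessions,

with the standard F-based 95% CI; the implementation is cross-checked in
the tests against an independent statistics package. Incomplete pairs are
dropped per characteristic with the count reported; zero total variance
yields a flagged undefined ICC. Categories use half-open bands: poor
below .50, moderate [.50, .75), good [.75, .90), excellent [.90, 1].
Family averages (durations/occurrences/coverages over the 5 types,
transitions over the 20 ordered pairs) use Fisher z-averaging
tanh(mean(atanh r)), since correlations are not additive; values at ±1 are
clamped at 1 − 1e-12 with a warning. Differences between two averaged
correlations are tested with z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) +
1/(n₂−3)); one-sided p follows the stated directional hypothesis and the
two-sided p is always reported alongside. No multiplicity correction is
applied. Retest intervals map to five groups (1–7, 8–30, 31–90, 91–180,
≥181 days).

## Synthetic data: what it emulates and what it does not

The generator produces the signal structure the method assumes: K
quasi-dipolar templates (cosine of the angle between electrode position and
a random dipole axis, average-referenced, unit-norm, pairwise |r| bounded
by a separation parameter); a semi-Markov label sequence with uniform
off-diagonal transitions by default and gamma dwell times (shape 4 —
positive, right-skewed, variance controllable; mean 60 ms by default,
inside the 40–120 ms range typical of resting microstates); a 10 Hz carrier
with random phase per segment whose rectified envelope produces GFP peaks
roughly every 50 ms, as eyes-closed alpha does; and average-referenced
spatial Gaussian noise scaled so that template GFP / expected noise GFP at
envelope maxima equals the design SNR (default 4). Ground truth reports
*realized* (not nominal) statistics of the generated sequence.

Cohorts add the retest structure: per subject and class a trait mean
duration ~ Normal(60, between-SD 8 ms), realized per session with
within-SD 4 ms (floored at 10 ms), giving a designed trait ICC of
b²/(b²+w²) = 0.8 by default; and subject-level template jitter (each map
rotated toward a random direction so |r| to the population map stays in
[0.9, 1]), a subject trait shared across sessions that makes GM and Ind
fitting genuinely different estimators. Defaults were chosen once as
plausible resting-EEG values and are exposed, not tuned.

Not modeled: volume-conducted 1/f background, line noise, artifacts,
non-stationary alpha power, forward head models, or channel-specific noise.
Passing tests therefore demonstrate correctness of the algorithms under the
model's assumptions — recovery of templates, durations, coverages and
designed ICCs — not performance on real recordings, where preprocessing
quality and model violations dominate.

## Problem sizes and seeds

Validation uses desk-scale problem sizes chosen to keep the full suite
fast while leaving the conclusions stable: 20–30 subjects, 2 sessions,
60–120 s recordings at 500 Hz and SNR 4 for end-to-end checks; n = 200
subjects for trait-level ICC recovery; ≤ 10 maps for exhaustive partition
oracles and 30-sample windows for exact smoothing oracles. All randomness
flows from explicit seeds through `numpy.random.SeedSequence` spawning
(per stage, per subject), so any run is reproducible and subject-level
results do not depend on cohort size.

## Known limitations

- ICM smoothing matches the exact objective optimum only in the
  data-dominated penalty regime (see above); with penalty 1 on strongly
  noisy data it is a well-behaved local optimizer, like the tools it mirrors.
- The expected-transition definition is one of several in circulation;
  transition statistics are comparable across software only if that
  definition matches.
- The idealized 10-20 montage is a geometric construction, not a digitized
  cap; spherical-spline resampling between real caps should use measured
  positions (a BESA-style `.sfp` loader is provided).
- `grand_grand_mean_consistency` of a single set is trivially 100% and is
  flagged as such rather than treated as evidence.
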