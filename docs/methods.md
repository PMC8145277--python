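# Methods

This note records the models, numerical choices and known limitations of
the package, in the spirit of a methods appendix.

## Study model

The unit of inference is the paired within-subject contrast: each subject
is measured in two sessions (baseline, follow-up) under several EEG
conditions — two resting blocks (`rest1`, `rest2`), word-pair learning and
recall, virtual-reality learning, and a Simon task whose congruent and
incongruent trials are treated as separate conditions — plus behavioral
measures (Simon reaction times and accuracies, recall counts for two
memory tasks, neuropsychological-style score scales). The resting
conditions use the full cohort (default n = 10); the cognitive conditions
use a subset (default n = 8), mirroring the attrition pattern typical of
such studies. All inference is nonparametric: exact sign-flip cluster
permutation tests for the EEG, Wilcoxon signed-rank plus
Benjamini–Hochberg for the behavioral family.

## Synthetic cohort generator

The generator's purpose is to give every downstream stage input with the
*statistical structure the analysis assumes*, not to be a biophysical
head model.

Continuous EEG per channel is a sum of independent components, all in µV:

- 1/f^`pink_slope` Gaussian background noise (default slope 1, RMS 10 µV);
- an alpha rhythm at `alpha_peak_hz` (default 10 Hz, amplitude 20 µV at
  the occipital maximum) with a waxing–waning envelope and an
  occipital-dominant topography. Only a fraction `alpha_coherence`
  (default 0.4) of the alpha variance comes from a scalp-wide shared
  source; the rest is channel-specific. This matters: a fully coherent
  rhythm is annihilated by common-average referencing, which would make
  any injected rhythm-amplitude effect invisible downstream;
- four band-limited noise components (delta 1–3, theta 3–7, beta 13–30,
  gamma 30–45 Hz) at low RMS.

Artifacts are additive templates with ground truth recorded per event:
blinks (400-ms raised cosine, 150 µV on the EOG channel, frontally
weighted on the scalp), muscle bursts (0.5 s of > 20 Hz noise, 60 µV RMS,
flat-topped Tukey taper, on 4–8 random channels), step transients (200-ms
±300 µV DC pops on 1–3 channels) and 2-s flat segments. The step template
is deliberately short: every 200-ms amplitude window then overlaps an
edge, so the event's full extent violates the detection criteria it is
meant to exercise. Blinks are *not* meant to be caught by the detector;
they are the target of the ocular-correction stage.

Paired structure: subject-level multipliers (alpha amplitude, noise
amplitude, alpha peak offset) are drawn once per subject and shared by
both sessions; smaller independent session-level multipliers provide the
within-pair noise. Seeding uses
`SeedSequence((master_seed, subject, condition_index, session_index))`,
so adding subjects or conditions never perturbs earlier streams, and
every generator is a pure function of (config, seed).

Condition effects are injected *generatively*, by scaling signal
components on an electrode group — never by editing feature values — so
the feature code is exercised honestly:

| feature effect | generative realisation |
|---|---|
| hjorth_activity | all components × sqrt(1 + d·m) |
| power (band) | overlapping band components × sqrt(1 + d·m) |
| brain_rate / hjorth_mobility | beta/gamma × (1 + d·m), slow bands and alpha × (1 − d·m/2) |
| entropy, decrease | slow (0.5–4 Hz) multiplicative burst modulation of depth m |
| entropy, increase | alpha component × (1 + m) |
| hjorth_complexity | broadband × (1 + d·m), alpha × (1 − d·m/2) |

The two entropy directions use different mechanisms because binned
amplitude entropy responds asymmetrically: burst modulation produces
heavy-tailed amplitudes whose outliers widen the per-epoch bin range and
concentrate mass centrally (entropy falls steeply with depth), whereas
rhythm dominance spreads amplitudes across the range (entropy rises, but
slowly). Burst modulation also raises variance slightly (factor
1 + depth²), a documented crosstalk into the activity feature.

Behavioral generators: Simon sessions draw *exact* per-block congruency
counts (60 of 100 congruent), with reaction times from a shifted
lognormal `rt = 200 ms + effect·[incongruent] + exp(µ + 0.3·Z)`, µ set so
the congruent median is 462 ms; the additive effect on the shift makes
the population median difference equal the configured congruency effect
(default 48 ms) exactly. Accuracy is Bernoulli (0.99 congruent / 0.96
incongruent). Recall counts are Binomial(item_total, p) with subject
ability on the logit scale shared across sessions (word-pair: 60 items at
mean p 0.36; virtual town: 40 items at 0.79, putting medians near typical
published task medians). These families are pragmatic stand-ins chosen
for the right support, skew and pairing structure — not estimates of any
patient population.

## Preprocessing

Fixed order: band-pass → downsample → ocular correction → detect →
channel repair → interval repair/exclude → drop TP9/TP10 → segment +
re-reference.

- Band-pass: 4th-order Butterworth 0.5–100 Hz applied forward–backward
  (`sosfiltfilt`): zero phase, 48 dB/oct combined asymptotic roll-off.
  Notch: second-order IIR at 50 Hz, Q = 35, also zero-phase.
- Downsampling: polyphase (`resample_poly`) to 256 Hz; requires a
  rational rate ratio; anti-aliasing is implicit in the polyphase filter.
- Ocular correction: per-channel least-squares regression of the EOG
  signal. This replaces interactive ICA review with a deterministic,
  testable stage; its known limitation is that it removes only
  EOG-*correlated* activity and slightly biases channels that genuinely
  covary with frontal sources.
- Artifact criteria are evaluated on sliding windows at 1-sample stride;
  a violating window flags all its samples. Flags merge into maximal
  intervals grown by a ±100 ms guard margin. Flatline intervals use a
  wider ±0.65 s margin: after the zero-phase high-pass, the edges of a
  truly flat segment carry the filter's settling transient, which
  exceeds the 0.5 µV bound without being clean data. The 0.65 s default
  was set from the measured settling profile of the 0.5 Hz high-pass
  (30 µV boundary amplitude decays below the 0.5 µV/100 ms bound in
  ≈ 0.45–0.6 s).
- The flatline criterion is interpreted as peak-to-peak (max − min)
  within the window, matching the difference semantics of the other two
  criteria.
- Channel repair: unweighted mean of Delaunay neighbours (template 10–20
  positions, azimuthal-equidistant 2-D projection); repairs draw from
  pre-repair data, making the operation idempotent. Artifact events
  touching ≤ 2 scalp channels are repaired within the event span;
  everything else is excluded. Overlapping per-channel annotations are
  clustered into events before the channel count is taken.
- Epoch tiling anchors at each clean segment's first sample, half-open
  `[start, start + 256)`; remainders under 1 s are discarded. The common
  average over the 27 retained channels is subtracted per sample within
  each epoch (for a fixed channel set this is equivalent to re-referencing
  before segmentation).

## Features

- Hjorth derivative: first difference × fs, so mobility is in rad/s-like
  units (for a pure sine at angular frequency ω, M → ω and C → 1); only
  ratios matter for M and C.
- Brain-rate band edges are not fixed by the statistic's definition
  (only the centres 2, 4, 6, 10, 18 Hz are); this package uses delta
  [0.5, 3), theta [3, 5), low-alpha [5, 7.5), alpha/low-beta [7.5, 13),
  beta [13, 30), exposed via `BrainRateBands`.
- Entropy: 15 equal-width bins spanning each epoch's [min, max]. The bin
  *count* is the fixed quantity (a cohort-level Freedman–Diaconis grand
  average, recomputable via `fd_bin_count`, which uses type-7 linear
  interpolation quantiles — bin counts are sensitive to that convention);
  the range is per-epoch.
- Power: demean → Hann taper → FFT → 1-Hz bins → band restriction →
  per-epoch normalisation by band mean (normalise *then* average over
  epochs). The default analysis band is 1–40 Hz inclusive — exactly 40
  bins, matching the electrode × frequency matrix the statistics operate
  on; a wider 0.5–45 Hz band is available via config but at 1-Hz
  resolution it yields 45 bins, so the two conventions are mutually
  exclusive and the 40-bin shape was chosen as the default.

## Statistics

- Cluster-forming threshold: two-sided dependent-samples t critical value
  at `cluster_alpha` (default 0.05), df = n − 1 (the common toolbox
  default; the threshold only shapes sensitivity, not validity).
- Cluster statistic: cluster mass (sum of member t-values); permutation
  null: distribution of the maximal |mass| over all 2ⁿ sign-flip
  assignments (exact for n ≤ `max_exact_n`, default 14; seeded
  Monte-Carlo above, observed assignment always included). The observed
  assignment is part of the exact enumeration, so p ≥ 1/2ⁿ.
- Power clusters span electrode × frequency with spatial adjacency within
  a bin plus ±1-bin spectral adjacency per electrode.
- Zero-variance nodes get t = 0 with a warning (no evidence either way).
- Wilcoxon: zero differences dropped, average ranks for ties; exact
  two-sided p by full 2ⁿ enumeration for n ≤ 15 without ties, otherwise
  normal approximation with tie correction; z is always reported from the
  normal approximation so z and r are comparable across methods. Effect
  size r = z/√(2·n_pairs) counts both measurement occasions; with 12
  pairs, z = 3.06 gives r ≈ 0.62.
- The behavioral table is one BH family; EEG cluster p-values are not
  BH-corrected across features/conditions (cluster correction is the
  within-test correction), stated here explicitly.

## Problem sizes and calibration

Desk-scale defaults keep a full synthetic study in the minutes range:
recordings default to 20 s at a native 512 Hz in `StudyConfig` (the
5-minute, 2500 Hz configuration of a real session remains available in
`EEGSimConfig`); the preprocessing contract is rate-agnostic because all
thresholds are in physical units.

The Monte-Carlo calibration studies (`pharmaeeg.calibration`) use one
condition, one feature and 4–10 s recordings per session: 200 null
studies at n = 8 for the cluster-level false-positive rate (checked
against the binomial 95% interval around α = 0.05), and 25 seeded runs
for effect recovery. The entropy-effect magnitude 0.3 used in the
recovery study was fixed by the power-oracle scan in
`analysis/05_power_oracle.py` (0.2 → ~80%, 0.3 → ~100% recovery at the
reduced size); the Simon congruency magnitude is the 48-ms default.

## What passing tests do and do not show

The synthetic cohort has Gaussian-mixture amplitude statistics,
stationary spectra within a session, artifact templates with known shape,
and no volume-conduction structure beyond a smooth topography. Passing
calibration on it demonstrates that the *pipeline machinery* — criteria,
epoching, feature math, exact permutation inference — is correct and
calibrated under the assumed structure. It does not demonstrate
robustness to real-EEG phenomena such as non-stationary drowsiness
effects, correlated artifact families, electrode drift, or reference
asymmetries, and it cannot validate any clinical claim.

## Known limitations

- EOG regression is a linear, single-channel stand-in for component-based
  ocular correction; an optional seeded-ICA mode is not implemented.
- The EDF writer covers the subset of EDF needed here (16-bit, 1-s
  records, µV); it is not a general-purpose exporter.
- The behavioral families are stand-ins (see above); recall-count and
  score effects are exchangeable across "parallel versions" — no version
  effect is modelled.
- Monte-Carlo p-values for n > `max_exact_n` are seeded but sampling-based;
  the exact scheme is preferred whenever 2ⁿ is affordable.
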