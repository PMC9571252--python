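# Methods

## Channel scoring model

A recording is a channels × samples matrix in microvolts. Every channel is
treated as one point in `n_samples`-dimensional space — its activity vector;
electrode geometry plays no role. Two distances are supported:

* **euclidean** — plain L2 between activity vectors.
* **seuclidean** (standardized Euclidean, the default) — each sample
  dimension is scaled by the standard deviation of that dimension computed
  across **all** channels (ddof = 1, the convention of MATLAB's and scipy's
  `seuclidean`). A per-pair standard deviation would be degenerate for
  two points, so the cross-channel convention is used. Time points where
  all channels agree exactly (zero cross-channel spread) are rejected with
  an error naming the offending dimensions. The standardized metric makes
  the score insensitive to global amplitude: at each instant a channel is
  judged against how much the montage disagrees with itself, which is why it
  generalizes across recordings with different gains and noise floors.

Given a neighborhood size `k`, the Local Outlier Factor machinery is the
classical density-ratio construction: the reachability distance
`max{k-distance(o), d(p,o)}` smooths distance fluctuations inside
neighborhoods; the local reachability density (LRD) is the inverse mean
reachability distance to the `k` nearest neighbors; the LOF of a channel is
the mean neighbor LRD divided by its own LRD. Channels in a density-
homogeneous cluster score 1 (exactly 1 for a regular simplex); isolated
channels score > 1. Everything is computed densely in double precision —
montages are at most a few hundred channels, so the O(n²) distance matrix
is trivial and no approximate neighbor search is used.

### Neighborhood conventions

* Neighborhoods have **fixed cardinality k**: ties at the k-th distance do
  not expand the set (k-NN-search semantics; the original expanded-set
  variant changes nothing on continuous EEG data, where exact ties occur
  only between duplicated channels).
* k-NN ties break toward the lower channel index (stable sort), making the
  scores deterministic and permutation-equivariant.
* **Duplicate channels** (identical vectors, e.g. two dead channels stuck at
  the same constant) give a zero mean reachability distance; the LRD is
  capped at 1/ε with ε = 1e-12 distance units so the LOF ratio stays
  finite. Detection of such channels is the flat-line detector's job, not
  LOF's.

### Data-driven k (natural-neighbor search)

`k = "auto"` runs the natural-neighbor loop: in round r = 1, 2, … every
channel nominates its r-th nearest neighbor; the loop stops at the first
round where every channel has been nominated at least once (has a "reverse
neighbor"), or where the number of never-nominated channels stops changing
between rounds, and returns that round index, capped at n − 1. The
stopping count is evaluated after each round against the previous round; an
all-identical montage has no meaningful neighborhood scale and returns k = 1
with a warning. On the benchmark simulation the loop settles at k ≈ 3–5.

## Detection pipeline

1. *(optional)* zero-phase FIR band filtering (below);
2. flat-line detection: a channel is flagged when successive-sample absolute
   differences stay ≤ `tolerance_uV` (default 1e-8 µV, i.e. exact
   constancy; raise it for quantized hardware) over at least
   `min_duration_s` (default 5 s);
3. LOF scoring of the **non-flat** channels only;
4. flags = flat-line flags ∪ (LOF > threshold), with per-channel provenance.

Flat channels are excluded before scoring — not just flagged afterwards —
because identical flat vectors are zero-distance duplicates that distort
both the standardized-Euclidean scale and the local densities of their
neighbors; their badness is already established. Detection needs at least
3 non-flat channels, and a warning is emitted below 32 channels: with few
channels the "local cluster" a channel is compared against is no longer
meaningfully local, and the benchmark shows the method degrading there.

The default threshold is 2.5, appropriate for noisy (e.g. neonatal)
recordings; cleaner adult data typically calibrate to ≈ 1.4–1.6. The
threshold is the one parameter users should calibrate (below) rather than
guess.

### Filtering

The optional band filter follows common practice for low-frequency
paradigms: a 40 Hz low-pass (Kaiser-design FIR, 5 Hz transition) and a
high-pass with transition band [0.1, 0.35] Hz, both at 80 dB stop-band
attenuation. Filters are linear-phase FIRs applied once by FFT convolution
with reflect padding and group-delay compensation, i.e. zero net phase.
Filtering is **off by default** inside `detect_bad_channels` — band limits
belong to the dataset, not the detector — and is applied by the CLI only
when `--filter` is passed. The high-pass needs ≈ 5000 taps at 250 Hz, so
recordings shorter than ~20 s are rejected rather than filtered badly.

## Threshold calibration

With annotated recordings, the threshold is found by exhaustive grid search
(default 1.0–5.0 in steps of 0.1) maximizing the F1 score
`2·TP / (2·TP + FP + FN)`, wrapped in repeated-split cross-validation
(default 10 folds, 50 % test size). Conventions:

* confusion counts are **pooled across recordings** within a split before
  F1 is computed (stable when single recordings contain no bad channels);
  F1 is defined as 0 when TP = FP = FN = 0;
* grid ties resolve toward the **smallest** threshold — the more sensitive
  detector, a deliberate bias toward recall given that bad channels are the
  rare class;
* splits are drawn over recordings with `ShuffleSplit`, or
  `GroupShuffleSplit` when subject ids are given, so that no subject's
  recordings appear on both sides of any fold;
* all randomness enters through an explicit integer seed.

For detector comparison, per-channel measures are min-max normalized to
[0, 1] per recording, the decision threshold sweeps 0 → 1 in steps of
0.005, and the ROC curve (FPR, TPR per threshold, anchored at the corners)
is integrated by the trapezoid rule into an AUC. Because of the fixed
sweep grid the AUC is invariant to monotone transforms of the measure only
up to grid quantization (≲ 0.02 for moderate channel counts).

## Comparison detectors

Re-implemented at the bad-channel stage only, at the granularity their
pipelines describe:

* **Kurtosis** — per-channel sample kurtosis, z-scored across channels,
  flag z > 5 (one-sided: artifacts raise kurtosis). Channels with zero
  variance have undefined kurtosis; they are excluded from the statistics
  and never flagged by this detector.
* **FASTER-style** — mean absolute inter-channel correlation, variance, and
  rescaled-range (R/S) Hurst exponent, each z-scored; flag any |z| > 3.
  The R/S estimate uses log-spaced window sizes between 10 % and 50 % of
  the series length and the log-log slope of segment-averaged R/S.
* **CRD-style** — union of (a) the flat-line detector, (b) a line-noise
  criterion (z > 4 across channels of the power ratio in mains ± 1 Hz over
  broadband, skipped above Nyquist; mains frequency and cutoffs
  configurable), and (c) a low-correlation criterion evaluated in 5 s
  windows: a channel is flagged when its maximum absolute correlation with
  any other channel falls below 0.8 in more than 40 % of windows. The
  windowing matters: continuous motion noise decorrelates every window,
  while a few seconds of step artifacts corrupt only a minority of windows
  and correctly escape this detector.
* **HAPPE-style** — average log10 Welch power (1 s windows, 50 % overlap)
  over 1–125 Hz (capped below Nyquist); flag channels deviating more than
  3 SD from the cross-channel mean; remove the flags and repeat once; union
  over passes. Spectral powers are floored at 1e-12 × the median positive
  power so exactly flat channels appear as huge finite low outliers rather
  than −∞.

Percentile-based measures (IQR) use linear interpolation between order
statistics (numpy default), which the worked examples in the tests assume.

## Synthetic benchmark recordings

The generator emulates, directly in channel space, a frequency-tagging
recording contaminated with the three canonical artifact classes. Design
(defaults in parentheses):

* **Background**: 48 independent 1/f² ("brown", knee 0.1 Hz) noise sources
  mixed through smooth Gaussian spatial profiles (width 0.12 of the channel
  line) with row-normalized gains, plus per-channel independent brown
  sensor noise at 0.35 × the mixture SD, scaled to 20 µV. Neighboring
  channels correlate ≈ 0.9 like physically adjacent electrodes; the log-log
  PSD slope over 0.5–20 Hz is −2.0 ± 0.1. Source-space head modeling is
  deliberately not used: channel-level detection depends only on
  channel-level statistics, and the smooth mixing reproduces the relevant
  geometry (a locally dense, spatially correlated cloud of channel vectors).
* **SSVEP**: a 0.8 Hz fundamental plus a 0.25-amplitude second harmonic,
  posterior-weighted Gaussian gain profile, peak amplitude 0.25 × the
  background SD — a clear narrowband spectral peak of the same order as the
  background at the tag frequency, without affecting detection geometry.
* **Flat channels** (2): replaced by a constant (0 µV).
* **Motion channels** (2): additive band-limited 0–10 Hz noise at 10 × the
  channel SD — continuous, large, spatially uncorrelated.
* **Aperiodic channel** (1): 4 step-like potential shifts at random times,
  ± (10–14) × the channel SD, plateaus of 2–3.5 s with 0.3 s cosine ramps.
  The long smoothed plateaus put almost all artifact energy below 1 Hz:
  large time-domain offsets (high kurtosis, large LOF distance) with almost
  no in-band average-log-power shift — the signature that separates
  spectral detectors from local-density detection.

All randomness flows through a single seeded generator; recordings are
bit-reproducible per seed. Default length 120 s at 250 Hz — comfortably
above the 5 s flat-line criterion and several hundred cycles of the 0.8 Hz
tag. Fixed artifact assignments for the 64-channel montage are 1-based
channels {1, 49} flat, {6, 35} motion, {16} aperiodic; the 32- and
16-channel presets keep the same relative layout with valid indices
(documented in `DEFAULT_ARTIFACT_CHANNELS`).

Under these conditions the standardized-Euclidean LOF misses the flat
channels by the same mechanism as on real data: the cross-channel spread
that standardizes every time point is dominated by the shared background
(and any motion channels), so a flat channel's distance to the cloud is only
~1.5–2 × the typical inter-channel distance — below any reasonable
threshold — while motion (LOF ≈ 13) and step channels (LOF ≈ 4–5) are far
outliers. This is why the flat-line pre-detector is part of the pipeline.

### What the generator does not emulate

Realistic head geometry and lead fields; stereotypical ocular/cardiac
artifacts; non-stationary background (drowsiness, state changes); hardware
quantization and line noise on clean channels; annotation noise (labels are
exact by construction). Passing the simulation benchmarks therefore
demonstrates correctness of the machinery and the qualitative separability
structure, not field performance on any particular EEG system; on real data
the threshold must be calibrated per acquisition setting.

## Problem sizes in tests and acceptance runs

The acceptance script averages the pipeline F1 over 10 seeds at 32 and 16
channels with the default 120 s recordings (a few seconds total). The test
suite uses 10-seed batches at 64 channels for the detection-pattern checks,
50 random instances (5–40 channels, 10–80 samples) for oracle equivalence,
and six 60 s recordings for calibration recovery — sizes chosen so the
whole suite runs in well under a minute while every stochastic claim is
averaged over enough seeds to be stable.

## Known limitations

* LOF compares a channel to its k nearest channels; on montages ≲ 32
  channels the neighborhoods stop being local and sensitivity drops (the
  16-channel benchmark typically misses the step-artifact channel, F1 0.89).
* A cluster of ≥ 2 mutually similar bad channels (e.g. two channels shorted
  together) supports its own density and scores near 1 — the flat-line
  stage covers the constant case, but correlated non-constant failures
  remain hard for any local-density method.
* The HAPPE-style detector's motion sensitivity on the simulation sits near
  its 3 SD criterion; across seeds it occasionally flags only one of the
  two motion channels (the flats and the absence of false positives are
  stable).
* Distances are computed on the raw (optionally filtered) time series; no
  windowing or decimation is applied before scoring. For very long
  recordings the cost is linear in samples and remains negligible next to
  filtering.
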