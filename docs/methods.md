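# Methods

## Pipeline overview

The package classifies subjects (PD vs control) from multichannel
resting-state EEG via texture statistics of Hankel-embedded signal
windows. Stages, each a module:

1. **I/O** (`eegtexture.io`) — recordings are channels × samples in µV.
   EEGLAB `.set` and EDF are read through mne; a CSV layout (one channel
   per row, channel name in the first column) with a YAML sidecar
   (`subject_id`, `fs`, `label`, `eyes`, `drug`) serves as the plain-text
   interchange format. Channel subsetting is an explicit, user-supplied
   list (`select_channels`): the common-channel set of any multi-site
   study is a property of that study's montages, so it is configuration,
   never hard-coded.
2. **Preprocessing** (`eegtexture.preprocess`) — 4th-order Butterworth
   band-pass, 1–50 Hz by default, applied forward–backward (zero phase,
   reflection padding, no samples dropped), then average re-reference
   (subtract the instantaneous cross-channel mean). Order: filter first,
   then re-reference. ICA-based artifact rejection is deliberately out
   of scope; the package expects cleaned input or tolerates basic
   filtering only.
3. **Feature extraction** (`eegtexture.texture`) — see below.
4. **Selection** (`eegtexture.selection`) — chi-square ranking, top-k.
5. **Evaluation** (`eegtexture.evaluation`) — repeated stratified k-fold
   and LOOCV with per-fold refitting of selection and standardization.
6. **Synthetic cohorts** (`eegtexture.synthetic`) — seeded generator
   used by the tests and the acceptance script.

## Hankel–GLCM–Haralick features

Each channel is segmented into `n_windows = 50` equal, non-overlapping
windows of length `L = floor(N / n_windows)`; the trailing remainder is
discarded. Windows are assumed non-overlapping — the simplest reading
consistent with a fixed window count.

A window `X₁` becomes the `L×L` Hankel matrix with first column `X₁`
and last row `reverse(X₁)` (`scipy.linalg.hankel(X₁, reverse(X₁))`).
The matrix is quantized to `G = 8` gray levels by equal-width binning
over the image's own min–max range:
`q = min(G, floor((x − lo)/(hi − lo)·G) + 1)`, upper edge clamped to
`G`, constant images mapping to level 1. Per-image min–max limits make
the features invariant to positive rescaling of the window — amplitude
information is intentionally discarded at this point and class
information must enter through waveform shape.

The GLCM counts co-occurrences of gray levels at a single offset,
default `(0, 1)` (horizontal right-neighbor, distance 1),
non-symmetric; both are configurable. Counts are normalized to a joint
distribution `p(i, j)` with marginals `p_x`, `p_y`, the sum distribution
`p_{x+y}(k), k = 2..2G` and difference distribution
`p_{|x−y|}(k), k = 0..G−1`.

Nineteen statistics are computed per window (autocorrelation, cluster
prominence/shade, contrast, correlation, difference entropy/variance,
dissimilarity, energy, entropy, homogeneity, two information measures
of correlation, inverse difference, maximum probability, sum
average/entropy/variance, sum-of-squares variance). Conventions, all
test-pinned against an independently coded literal-formula oracle:

- levels are indexed 1..G; all entropies use the natural logarithm with
  `0·log 0 := 0`;
- `difference_variance` is the variance of the `p_{|x−y|}` distribution
  (not the 1973 alternative phrasing);
- `sum_of_squares_variance` uses the x-marginal mean µx;
- `correlation := 0` when either marginal variance is zero; `imc1 := 0`
  when both marginal entropies are zero; the `imc2` radicand is clamped
  at 0 against floating-point undershoot;
- the 19 features are emitted in fixed alphabetical order so feature
  provenance triples `(channel, window, feature)` are deterministic.

Feature vectors are channel-major: channel, then window, then the 19
names — `channels × n_windows × 19` values per subject.
`HankelTextureExtractor` exposes the extraction as a stateless sklearn
transformer.

## Chi-square selection

Each feature is discretized into `n_bins = 10` equal-width bins over
its observed range (constant features: one bin, score 0); the score is
the Pearson statistic `Σ (O − E)²/E` over the bins × classes table,
cells with `E = 0` skipped, no Yates correction (scores are only used
for ranking). Equal-width binning over the observed range makes scores
invariant to positive affine rescaling of a feature. Ties in the
descending ranking break toward the lower feature index, so top-k sets
nest. Bin edges are fit on whatever rows are passed in; inside
cross-validation `Chi2TopK` receives only training rows.

Whether selection should be refit per fold or once globally is a real
design fork: this package defaults to **per-fold** selection (no test
information in the ranking) and keeps a `selection_mode="global"` only
as an explicitly leaky diagnostic; `audit_fold_selection` recomputes
every fold's ranking from its training rows to prove the default honest
and to demonstrate the audit detects the leaky mode.

## Classifiers, CV, metrics

Three untuned classifiers: linear SVM (box constraint 1), 1-NN
(Euclidean), and a feed-forward net with one hidden layer of 10 ReLU
units. Selected features are z-scored per training fold before SVM,
1-NN and the net — necessary for a unit-kernel-scale linear SVM on
µV-derived features of wildly different magnitudes. For the net,
scikit-learn's adam optimizer is run with `max_iter=1000`: at the
default 200 iterations it is visibly unconverged on training folds of a
few dozen subjects, and the intent of a fixed small architecture is a
*trained* network, so training runs to convergence (seed-pinned).

CV schemes: stratified k-fold (5 or 10 folds) redrawn `n_repeats = 10`
times, and LOOCV (deterministic, one repetition). Stratification keeps
the balanced class ratio in every fold. Metrics per repetition are
computed from the confusion matrix pooled over that repetition's folds;
AUC is the rank-based area under the ROC from continuous decision
scores (midrank ties): signed hyperplane distance for the SVM,
`d₀ − d₁` (distance to nearest class-0 minus nearest class-1 training
point) for 1-NN, output activation for the net — hard 1-NN labels carry
no ranking information, so a continuous surrogate is required. Ratios
with zero denominators are reported as NaN with a warning. Summaries
give each metric's mean and (min–max) range across repetitions; the
range is labeled min–max in all outputs.

## Synthetic cohorts

Each channel is an independent sum of band-limited Gaussian noise
(white noise band-passed to delta 1–4, theta 4–8, alpha 8–13, beta
13–30 Hz; RMS defaults 8, 6, 10, 5 µV — an eyes-closed-like,
alpha-dominant spectrum) plus 1/f pink noise (4 µV RMS). PD-class
subjects have the beta component's RMS multiplied by
`1 − beta_reduction` (default 0.5) and the finished channel by
`1 − amplitude_reduction` (default 0.3); the effects compose
multiplicatively. Cohorts are balanced, and a given seed reproduces the
cohort bit for bit.

What the generator does **not** emulate: spatial covariance between
channels (the feature extractor treats channels independently anyway),
ocular/muscle/line artifacts, drug- or eye-condition effects,
non-stationarity. Passing tests therefore demonstrate that the pipeline
recovers a known beta-power class difference from realistic-scale noisy
signals with honest cross-validation — not that it attains any
particular accuracy on clinical recordings.

One measurement subtlety: the total 13–30 Hz Welch power ratio between
classes at the full default mix is ≈ 0.15–0.16, not the pure component
ratio `((1−0.5)(1−0.3))² ≈ 0.1225`, because pink noise and the alpha
band's roll-off also occupy 13–30 Hz. The mechanism is therefore
verified on a beta-only configuration (where the measured ratio matches
0.1225 to within Welch estimation error) plus a strong-reduction check
(ratio in 0.10–0.25) at the full mix.

Note that because quantization is per-image min–max, the amplitude
reduction alone is invisible to the texture features; class
separability in the end-to-end experiments is carried by the beta
reduction's effect on waveform shape.

## Problem sizes used in tests and the acceptance script

The end-to-end experiments run on a scaled cohort — 60 subjects
(30/class), 8 channels, 20 s at 500 Hz, effect sizes at the generator
defaults, 10×10-fold CV with per-fold top-1000 selection — chosen so
the full suite and the acceptance script each complete in well under a
minute while keeping the study's subject count and CV protocol. At
these conditions the linear SVM separates the classes perfectly (mean
ACC 1.0) and the label-permutation null sits at chance (≈ 0.5). The
feature-dimension checks use the full 57-channel layout on short
recordings.

## Known limitations

- GLCMs use a single offset; no rotation averaging or multi-distance
  aggregation.
- The chi-square discretization (10 equal-width bins) is one of several
  toolbox conventions; `n_bins` is exposed.
- 1-NN decision scores are a package convention (see above), needed
  because hard labels admit no ROC.
- `.set` support is read-only and limited to variants mne parses;
  unsupported files fail loudly.
- Runtime scales as `channels × n_windows × L²` in the window length
  `L`; full-length 57-channel minutes-long recordings take tens of
  seconds per subject.
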