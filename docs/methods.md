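# Methods

`phosdec` implements an end-to-end pipeline for asking whether single EEG
trials carry decodable information about phosphene-like visual stimuli —
solid gray shapes on a black background, the kind of percept a visual
neuroprosthesis can produce — and how much is gained by pooling evidence
across repeated presentations. Because no public recording accompanies
this experimental design, the pipeline is exercised entirely on a synthetic
generator whose structure mirrors the qualitative effects reported for
such stimuli. This note documents the models, the defaults and their
units, and what the synthetic results do and do not show.

## Stimulus and task design

The visual field is a 5×5 grid (166 × 93 cm screen at 40 cm viewing
distance; row 0 at the top, i.e. the superior field). A stimulus is a set
of lit cells at gray level 0.5 on black. The default registry holds
exactly 60 stimuli: 25 single blocks, 5 full-column and 5 full-row bars,
5+5 centered three-cell bars (both orientations), 5 two-by-two and 5
three-by-three blocks (four corners plus center), and 5 ring/center shapes
(full border ring, border edges, corners-only, middle ring, center cross).
The exact composition is configuration, not dogma: any registry satisfying
the task memberships can be substituted via YAML.

Ten decoding tasks partition (subsets of) the registry into M mutually
exclusive classes: left-vs-right and superior-vs-inferior (M=2, from the
stimulus centroid relative to the grid center), five-level vertical- and
horizontal-bar position tasks (M=5), corners (M=4), outer-vs-middle (M=2,
by Chebyshev ring distance of the centroid), bars and blocks size tasks
(M=3), luminosities (M=5 lit-area levels), and outer-vs-center (M=2).
A task is *balanced* when its largest class holds at most 1.5× the
stimuli of its smallest; that flag selects the cross-validation scheme.

The outer-vs-center memberships deserve a note: outer = {border ring (16
cells), border edges (12), corners-only (4)} versus center = {center cross
(5), middle ring (8), center block (1)}. The lit-area levels of the two
classes deliberately overlap, so once the generator's eccentricity
attenuation is applied, luminosity and eccentricity effects partially
cancel and the task becomes the hardest of the set — the regime expected
when stimulus size and peripheral location co-vary.

The presentation schedule is two sessions of 30 sub-sessions × 50
presentations: 25 repetitions of each stimulus per session, 3000 total.
Stimuli last 750 ms; the inter-stimulus interval is continuous-uniform on
1.0–1.25 s (no distribution beyond the range is implied by the design, so
the simplest one is used), giving onset gaps in [1.75, 2.0] s.

## Synthetic EEG generator

Channels come from the standard 10-05 montage (a fixed 10-20 core
including the posterior O*/P* sites plus evenly spaced extra sites;
homologous left/right pairs are mirror-symmetrized so hemispheric
contrasts are exact). The evoked template of a stimulus is the sum of two
Gaussian-windowed components, in µV:

* negative component: latency 150 ms, width 50 ms, base amplitude 14 µV,
  amplitude *shrinking* 9 %/extra lit cell (floored at 15 %), boosted on
  the hemisphere contralateral to the stimulated hemifield
  (laterality gain 0.6) and for inferior-field centroids (elevation gain
  0.5);
* positive component: latency 300 ms, width 80 ms, base amplitude 8 µV,
  *growing* 35 %/extra lit cell.

Both components are attenuated with eccentricity, 1/(1 + 0.8·ē) with ē the
mean normalized distance of lit cells from the grid center (foveated-retina
proxy), and weighted toward posterior channels (quadratic in the
anterior–posterior coordinate, floor 0.15). The latencies are deliberately
atypical — this stimulus class does not show the canonical N70/P100 — and
every knob is a dataclass field.

Background noise is per-channel independent Gaussian 1/f^α noise (α = 1,
std 7 µV), generated by spectral shaping; optional blink-like ocular
transients (raised-cosine, 400 ms, weighted toward frontal channels) are
off by default, since the ocular-artifact control analysis is out of
scope. Electrode impedances are simulated with exactly `n_bad` channels
above the 100 kΩ rejection threshold.

The amplitude/noise defaults were fixed once so that the scaled binary
location study lands in the 65–80 % single-trial accuracy range — the
regime in which both above-chance and near-chance behavior are reachable
through the single `amplitude_scale` knob (0 gives identical templates
and drives everything to chance).

What the generator does **not** emulate: spatial correlation of the noise
across channels, trial-to-trial amplitude/latency jitter, non-Gaussian
artifacts, volume-conduction physics, or inter-subject variability.
Passing tests therefore show that the *pipeline* is correct and
well-calibrated, not that real EEG would yield these accuracies.

## Preprocessing

1. Channels with impedance > 100 kΩ are dropped.
2. The continuous recording is bandpass filtered 0.5–30 Hz with a
   one-pass, zero-phase Hamming-window FIR (window-method design).
   Transition bandwidths follow lower = min(max(0.25·l, 2 Hz), l) and
   upper = min(max(0.25·h, 2 Hz), fs/2 − h), so the half-amplitude
   (−6 dB) cutoffs sit at 0.25 and 33.75 Hz for the default band at
   1 kHz; the realized taps are verified against these points to within
   0.02 Hz. The symmetric taps are applied in one pass with the
   linear-phase delay compensated (edge-padded convolution).
3. Epochs cover (−0.3, 0.75) s: ⌊1.05·fs⌋ samples starting ⌊0.3·fs⌋
   samples before the onset sample, 0-based, epoch sample 0 at exactly
   −0.3 s. Windows that fall off the recording are dropped with a
   warning (downstream code tolerates small count mismatches).
4. Baseline correction subtracts each trial/channel's mean over
   (−0.3, −0.1) s (the first ⌊0.2·fs⌋ samples).
5. aRMS rejection: per channel, the mean over trials of the within-trial
   RMS; channels strictly outside the Tukey fences
   [q1 − 1.5·IQR, q3 + 1.5·IQR] across channels are dropped. Quartiles
   use linear interpolation by default (Tukey hinges via
   `quartile_method="hinges"`); the convention matters at small channel
   counts, so it is explicit. The statistic is indexed by channel and
   subject only, so epochs of both sessions are pooled before rejection.

## ERP statistics

Class ERPs are plain trial means. The cluster-based permutation test is
implemented directly (all knobs in config): pointwise one-way F across
classes, cluster-forming threshold at the F quantile for α = 0.05,
contiguous suprathreshold runs scored by summed F, null distribution =
maximum cluster mass over 1024 random relabelings (vectorized over
permutations), p = (1 + #{null ≥ mass})/(1 + n_permutations). Channels
are tested independently with no cross-channel correction, over the
posterior selection (names containing "O" or "P", case-insensitive —
"Fp*" channels match the literal rule and are returned flagged so callers
can exclude them). Significance bands label each sample with the
strictest of the configurable levels (default 0.05/0.01/0.001) met by a
covering cluster. On null data the realized type-I rate of the test is
0.03–0.05 (slightly conservative due to the +1 correction), checked by
simulation.

## Decoding

Features are the raw epoch samples, flattened channel-major (all samples
of channel 0 first) — every channel, not only posterior ones.
Standardization is per *channel*: mean and SD pooled over all training
trials and time points of that channel (N−1 denominator), fitted on the
training fold only and applied unchanged to the test fold.

The classifier is an RBF-kernel SVC (C = 1, `gamma="scale"`, i.e. the
1/(n_features·var) convention; no hyperparameter search by default)
wrapped in sigmoid (Platt) calibration with 5 internal stratified folds
on the training data. Balanced tasks use stratified tenfold CV;
unbalanced tasks use 10 Monte Carlo resamplings, each subsampling every
class without replacement to the smallest class size and then making a
stratified 90/10 train/test split. Z-scoring, calibration and the model
are refitted inside every fold; a hash of the fitted state verifies that
test labels cannot influence it.

Chance level is empirical: a fold-matched random decoder draws uniform
labels over the M classes. Real-vs-random accuracy is compared with a
one-sided paired Wilcoxon signed-rank test over the 10 fold pairs
(rank-sum is available via config since the pairing is a choice), exact
null when ties permit; Bonferroni correction multiplies p by the number
of subjects, capped at 1. Shapiro–Wilk normality of each accuracy set is
reported but never gates the test. Identical accuracy vectors are flagged
degenerate with p = 1.

## Multi-trial aggregation

Given calibrated probabilities p_{i,k} for N same-class trials, the
aggregate is p_k ∝ ∏_i (p_{i,k}/p_{i,M})^{1/N}, normalized over classes —
evaluated in log space after clipping entries at 1e−12 and renormalizing.
The reference class (the last, index M) is immaterial: the expression
equals the normalized geometric mean, and the identity is asserted to
1e−12 over random simplex inputs. Aggregation is permutation-invariant,
maps uniform rows to uniform output, and preserves dominance.

Accuracy-vs-N curves slide an overlapping window (stride 1) of N
same-true-class trials over each fold's class-shuffled test set for
N = 1..15; the window prediction is the aggregate argmax, and N = 1
reproduces single-trial accuracy. Windows never mix classes: a window
models repeated presentations of the same percept, and cross-class
windows have no ground truth to score. Classes with fewer than N test
trials are skipped and recorded. The delta regression (OLS of the
N=15-minus-N=1 accuracy change on single-trial accuracy, two-sided t-test
on the slope) and fold-averaged row-normalized confusion matrices
complete the analysis. When probabilities are uninformative the curve
fluctuates around 1/M — aggregation helps only when single-trial
performance is above chance.

## Sensitivity maps

Feature importance of a fitted RBF machine is the mean over data points
of the squared analytic gradient of its decision function (the formula in
`sensitivity_mapping`); the analytic gradient is verified against central
finite differences to 1e−4 relative error. Calibrated wrappers are not
differentiated: the decoder keeps plain one-vs-rest RBF machines fitted
on the same training data (a single binary machine for M = 2), and
multi-class maps average the per-class maps. Maps are computed on the
training data by default (the evaluation set is an argument). Reducing
the channels × samples view by mean over time gives the spatial map and
by mean over channels the temporal map; on the default generator the
spatial map concentrates on posterior channels and the temporal map peaks
near the 150 ms component.

## Problem sizes

The canned study (`phosdec.pipeline`) uses 32 channels at 250 Hz with 300
trials per binary task, 2 impedance-bad channels, and the default
generator; the statistical-calibration studies use small instances
(2 × 30 trials × 200 samples for the cluster-test null; 60-trial null
decodes for the chance pipeline). These sizes are the package's own
defaults for a complete, reproducible desk-scale analysis; the full
experimental scale (128 channels, 1 kHz, 3000 trials) is reachable by
configuration.

## Known limitations

* The synthetic generator's independence assumptions (noise across
  channels, trials) make decoding easier than on real EEG at matched SNR;
  absolute accuracies are regime choices, not predictions.
* The ICA ocular-artifact control is not implemented; the generator's
  artifact hook exists so such a control could be added.
* No spatio-temporal (channel-adjacency) clustering or TFCE; the cluster
  test is per-channel by design.
* Multi-trial windows assume same-class repetitions; mixed-class
  windowing is undefined here.
* Impedances are simulated at the layout level, not measured; the
  rejection threshold (100 kΩ) is a fixed contract.
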