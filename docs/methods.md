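# Methods

`hiegrade` grades the severity of hypoxic-ischaemic encephalopathy (HIE)
from the background activity of multichannel neonatal EEG. An hour-long
epoch is reduced to a single grade in {1, 2, 3, 4} (normal/mild, moderate,
major, inactive) by a pipeline of: bipolar montage derivation, low-pass
filtering and resampling, quadratic time-frequency transformation of
overlapping 5-minute single-channel segments, a convolutional network that
classifies each time-frequency image, and majority voting that fuses
segment grades into the epoch grade. A two-stage amplitude detector
quantifies movement artefact, and an evaluation layer provides accuracy,
Cohen's kappa, Markov grade-transition matrices, and subject-resampled
bootstrap comparisons.

## Signal conditioning

The analysis montage is the 8-channel bipolar set F4-C4, C4-O2, F3-C3,
C3-O1, T4-C4, C4-Cz, Cz-C3, C3-T3 derived from the 9 standard NICU
electrodes; O1/O2 fall back to P3/P4 when a site records parietal
electrodes instead. Each channel is low-pass filtered at 30 Hz with a
4001-tap Hamming-window FIR applied symmetrically (the constant group
delay (taps-1)/2 of the linear-phase kernel is compensated, giving net
zero phase), then polyphase-resampled to 64 Hz. The filter is designed at
the input rate, so any rate >= 64 Hz is accepted. Passband tones below
25 Hz are preserved within 1 percent in amplitude and phase; the
resampler's own anti-alias filter adds attenuation only above ~28 Hz.
Epochs are cut into 300-second windows with 50 percent overlap; only fully
contained windows are kept, so a 60-minute epoch yields 23 segments per
channel (184 over 8 channels) of exactly 19 200 samples.

## Time-frequency front end

Each segment x[n] is pre-whitened by the forward first difference
y[n] = x[n+1] - x[n] (zero-padded to preserve length), which flattens the
steep 1/f spectrum of neonatal EEG, and converted to its analytic
associate z[n] via the Hilbert transform.

The quadratic TFD is the Wigner-Ville distribution (WVD) of z smoothed by
a separable kernel. Discrete conventions, which the package fixes as
normative:

* instantaneous autocorrelation K[n, m] = z[n+m] z*[n-m] with integer lag
  m and zero padding beyond the record edges;
* frequency axis f_k = k fs / (2L) for a length-L DFT over lag, spanning
  [0, fs/2) for the analytic signal;
* the kernel is applied multiplicatively in the Doppler-lag (ambiguity)
  domain: a Hann window g(nu) of 127 samples over Doppler and a Hann
  window h(tau) of 63 samples over lag, both symmetric (endpoint zeros,
  unit centre) and centred on the origin;
* scaling such that the full-grid smoothed TFD satisfies
  sum(rho) = sum(|z|^2) when the window peaks are 1.

Because g and h are short, the smoothed distribution is band-limited in
Doppler and lag; sampling it on the 256 (time) x 128 (frequency) output
grid is then *exact*: folding the Doppler
spectrum modulo 256 and the lag axis modulo 128 cannot alias as long as
the window supports (127 and 63 samples) fit inside the respective grids.
The fast path exploits this: it touches only the 63 lag columns of K
(each processed by one length-N FFT, a windowed extraction of 127 Doppler
bins, and one length-256 inverse FFT), so the cost is O(lag_len x N log N)
and the intermediate memory O(lag_len x n_time) -- the full 38 400 x
19 200 oversampled plane (0.01 percent of whose entries the decimated
grid retains) is never materialised. A brute-force reference that *does*
materialise the full plane is kept for verification; the test suite
checks entrywise agreement to 1e-8 relative error for N up to 256, and
the all-pass (boxcar, full-grid, odd-N) kernel limit reproduces the plain
WVD exactly.

The window lengths are interpreted on the decimated grids (127 of 256
Doppler bins, 63 of 128 lag bins). Two presets exist: development
(127/63, the default) and validation (123/59, a grid-searched variant for
multi-centre use), selectable in the pipeline configuration.

Finally the 8 bins in [0, 2) Hz and the 8 bins in [30, 32) Hz are removed
(wrap-around regions of the discrete transform), giving a 256 x 112
matrix, and the log of the absolute value is taken with floor
eps = 1e-12 x matrix maximum (1 if all-zero) so all-zero inputs stay
finite. No further per-image normalisation is applied; the network's
batch-normalisation layers are the only normalisation downstream.

## Network

Three parallel branches read the 256 x 112 image with 10 filters each:
8 x 1 kernels (time direction), 1 x 8 (frequency direction) and 8 x 8
(joint). Each branch applies conv -> ReLU -> max-pool (4 x 4 window,
2 x 2 stride) -> batch norm, giving (128, 56, 10). The concatenated
(128, 56, 30) map passes a 60-filter 4 x 4 convolution with 2 x 2 stride
(-> 64 x 28 x 60), ReLU, 2 x 2 pooling and batch norm (-> 32 x 14 x 60),
a 2 x 2 convolution, ReLU and 2 x 2 pooling, a global average (60
values), and two fully connected layers (60 and 4 neurons) with a softmax
over the four grades.

The architecture is pinned down by its feature-map dimension flow
(256 -> 128 after one conv+pool stage, a 128 x 56 x 30 concatenation, and
so on); that flow is only consistent with size-preserving convolutions
and ceil(size/stride) pooling, so same-padding is used throughout and the
dimension flow is treated as normative. The constructor re-derives every
intermediate shape and refuses to build a network that deviates, naming
the offending stage.

The layers are implemented directly on numpy arrays (float32, NCHW) with
explicit forward/backward passes; convolution is one im2col plus a batched
BLAS product, and scratch buffers are reused across steps so a single CPU
core trains the network in minutes. Weights initialise from a seeded
uniform fan-in distribution, so runs are exactly reproducible; batch-norm
inference uses running statistics frozen at the end of training.

## Training

Categorical cross-entropy, SGD with Nesterov momentum 0.9, batch size
128, initial learning rate 0.01 multiplied by 0.8 every 5 epochs. The
decay rule's "every 5 iterations" is read as epochs by default
(configurable to optimiser steps). No early stopping. Every segment of an
epoch carries the epoch's single expert grade; cross-validation is
leave-one-subject-out, and the splits are asserted subject-disjoint.
`max_epochs` defaults to 60 for desk-scale runs; on clinical-scale data
convergence is typically seen within a few thousand optimiser steps,
which informs the default but is not a stopping rule. The trainable core is also exposed as the
sklearn-compatible classifier `TfdCnnGrader` (fit / predict /
predict_proba / get_params), so it composes with sklearn model selection.

## Voting

Per channel, the seven segments fully contained in each 20-minute period
vote for a period grade, giving the 8 x 3 matrix M_cn (with 23 segments,
0-based segments 0-6, 8-14 and 16-22; the two segments straddling period
boundaries vote in no period). One-step voting takes the global majority
of all 24 cells; two-step voting first takes the per-period majority
across channels (SM_n) and then the majority of the three period grades.
Ties break towards the more severe grade -- no tie rule is standard, and
a severity-biased error is the clinically conservative choice; the rule
is configurable. Periods with fewer than their seven segments are marked
missing and excluded from later votes rather than imputed; epochs too
short for the 20-minute structure fall back to a plain majority over all
segment grades. Two-step voting is the default scheme; the reduced
2-channel mode (below) uses one-step voting.

## Reduced 2-channel mode

To mirror 2-channel aEEG-style cot-side montages, grading can run on
F3-C3 and F4-C4 alone. Channel-independent training makes this a pure
channel-selection change: every stage is shared with the 8-channel path.

## Artefact detection

Each channel is band-passed 0.5-10 Hz (5th-order Butterworth, applied
forward-backward so the phase is untouched) and its envelope taken as the
magnitude of the analytic signal. Stage 1: any envelope sample above
300 uV flags [t - 10 s, t + 10 s] on every channel of the same hemisphere
(such artefacts are rarely confined to one electrode). Stage 2: on each
channel's residual (samples at or below 300 uV), envelope samples above
100 uV flag [t - 3 s, t + 3 s] on that channel only. Collars clip at the
record edges; the final mask is the union, summarised as %artefact per
channel and pooled per epoch. "Peak" is read as every suprathreshold
sample (contiguous runs merge through the collar union), the simplest
reading consistent with the collar description. Each bipolar channel
inherits the hemisphere of its electrodes; Cz-containing pairs take the
side of their lateral electrode (there are no midline channels in the
montage).

## Synthetic data

No clinical recordings ship with the package; a generator realises the
grading scheme's defining features so everything is testable end to end:

* grade 1 -- continuous coloured noise (power ~ 1/f^1.5 over 0.5-30 Hz),
  25 uV RMS;
* grade 2 -- bursts (50 uV RMS, 3-8 s) alternating with interburst
  intervals of 2-8 s at 3 uV RMS;
* grade 3 -- bursts of 2-6 s with interburst intervals of 10-60 s;
* grade 4 -- continuous activity below 10 uV (low-amplitude mode; each
  channel is rescaled if its peak would reach 10 uV) or, alternatively,
  interburst intervals above 60 s.

Burst timing is shared across channels -- an HIE injury is global --
while the noise is independent per channel; burst edges are raised-cosine
ramps (0.5 s). The amplitude constants are plausible-scale choices made
for class separability, not published values, and are never used as
acceptance numbers. Sleep-wake cycling, asynchrony, seizures, electrode
pops and cooling trends are deliberately not modelled: passing tests show
the pipeline's mechanics and the classes' learnability, not clinical
performance. A movement-artefact injector adds Hann-windowed 4-8 Hz
transients (0.2-2 s, default 320-600 uV) at Poisson times with ground
truth returned, for round-trip validation of the detector. Datasets are
written as 16-bit EDF (physical range +/-800 uV) with a manifest CSV; all
generation is deterministic under its seed.

## Evaluation

Accuracy is 100 x trace/total of the 4 x 4 confusion matrix; Cohen's
kappa uses the marginal-product chance correction (flagged undefined when
chance agreement is 1). Epochs for which the system produced no estimate
("void") occupy a trailing confusion-matrix column: they count in the
total and never as correct. Grade-transition matrices are
maximum-likelihood Markov estimates pooled over subjects' consecutive
recording time-points, treating postnatal age as categorical (gaps are
ignored). Bootstrap comparisons resample *subjects* (not epochs) with
replacement, 1000 replicates by default; the two-sided p is the fraction
of replicates crossing zero, doubled and floored at 1/n_boot. The
published clinical figures (development 88.9 percent, kappa 0.84;
validation 69.5 percent, kappa 0.54) come from private cohorts and are
context only -- nothing in this package claims to reproduce them.

## Verification scale

The test suite runs at desk scale on one CPU: TFD oracle equivalence at
N <= 256, the artefact oracle on one hundred 60-second spike trains,
voting against exhaustive counting on one thousand random matrices, and
the end-to-end learnability check on 16 synthetic subjects with 10-minute
epochs (8 training subjects, 8 held out, 8 training epochs, 3 seeds);
these sizes are the package's chosen verification conditions and are
stated here so they can be scaled up deliberately rather than
accidentally.

## Known limitations

* The numpy network trains on one core; it is sized for the 48k-parameter
  grading architecture, not general deep learning.
* The EDF writer covers the synthetic-data use case (one rate, +/-800 uV
  physical range); arbitrary clinical EDF+ files are read, not written.
* The synthetic generator's four classes are far more separable than
  clinical EEG grades; learnability results on it say nothing about
  performance on real cohorts.
* Grade-0 (normal) recordings are folded into grade 1, following the
  4-grade scheme.
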