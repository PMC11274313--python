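# Methods

`beatsource` re-implements, as a tested pipeline on synthetic data, a
method for deciding whether the heart rate displayed by a cardiotocograph
(CTG) originates from the fetal heart or from a maternal vessel.  CTG
monitors derive the fetal heart rate (FHR) by autocorrelation of the
Doppler-ultrasound (DUS) signal; when the transducer drifts onto a maternal
vessel, the autocorrelation output silently becomes the maternal heart rate
(MHR), and the clinical record looks healthy while the fetus is unmonitored.
The method classifies raw 2-s DUS windows as *fetal* or *vessel* with a
small 1D-CNN and compares it against four classical single-number
discriminators by ROC/AUC.

## Signal model and the synthetic generator

The study whose design this package follows used private bedside
recordings; the generator replaces them with parametric recordings carrying
per-sample ground truth.  A recording is a 1 kHz DUS amplitude signal plus
4 Hz FHR/MHR traces in bpm.

**Beat trains.**  Beats occur at the instantaneous rate of the driving
heart-rate trace (piecewise-constant interpolation, Gaussian onset jitter,
default σ = 10 ms).  Each *fetal* beat contributes two Gaussian-envelope
bursts — the "galloping horse" of the two valve sounds — with envelope
σ = 25 ms, separated by 0.35 of the beat period, the second at 0.85 relative
amplitude.  Each *vessel* beat contributes one wider burst (σ = 70 ms).
Burst amplitudes are jittered with CV 0.15.

**Carrier.**  Bursts modulate a carrier at 250 Hz, inside the audible band
and below the 500 Hz Nyquist limit of the 1 kHz sampling rate.  The carrier
frequency wanders slowly (low-pass-filtered Gaussian noise, 1 Hz cutoff),
with a wider spread for fetal signals (σ = 30 Hz) than for vessel signals
(σ = 25 Hz): cardiac wall and valve motion spans a wider range of Doppler
velocities than laminar vessel flow.  Because the wander is slower than
either burst, each burst keeps a nearly constant carrier and a
transform-limited spectral line; across bursts the lines spread over the
class's velocity band.

**Gain and noise.**  Each beat train is normalised to a fixed RMS of 0.18
(recording-level automatic gain, as monitors equalise their audio output),
the peak is capped at 0.98, and white noise is added at 10 dB SNR.
Amplitudes live in [−1, 1); quantization to the 16-bit integer grid happens
only at WAV I/O, so arithmetic is resolution independent.

**Episodes.**  Four interval types compose a recording: *crossing* episodes
switch the DUS source to a vessel train driven by the MHR and make the
displayed FHR follow the MHR (the failure mode of interest); *coincidence*
episodes model maternal tachycardia by pulling the MHR to within ±2 bpm of
the fetal FHR, which is what lets genuinely fetal segments pass the
coincidence selection rule; *dropout* episodes scale the signal to ≤ 1 % of
nominal; *artifact* episodes replace it with broadband noise at twice the
nominal RMS.  Episodes must not overlap across categories.  Ground truth is
a per-sample source track (fetal / vessel / artifact / silent).

**What the generator does not emulate.**  Transducer beam geometry, tissue
acoustics, uterine-contraction channels, multiple pregnancies, and the
amplitude/frequency statistics of real bedside data.  Passing tests
therefore demonstrate that the pipeline's logic and learning machinery work
on data with the assumed morphological structure — not that the reported
clinical performance transfers to real recordings, whose AUC values are
properties of the private dataset.

## Candidate selection and dataset assembly

Recordings are cut into non-overlapping 10-s segments from t = 0 (trailing
remainder discarded).  A segment is a candidate when |FHR − MHR| < 5 bpm
(strict) holds on at least 6 s of *consecutive* 4 Hz samples (24 samples);
missing readings break runs, and a recording without an MHR trace is not
simultaneously monitored and excluded.  "At least 6 s" is read as a
sustained run, not cumulative time, since a sustained coincidence is what
makes maternal masquerade plausible.

Synthetic segments are labelled from ground truth: pure-fetal segments are
*fetal*, pure-vessel *vessel*, and any segment overlapping an artifact or
dropout episode — or mixing sources — is *not determinable* and excluded,
operationalising the auditory labelling criteria the original data were
labelled with.

Each labelled segment yields 2-s windows shifted every 100 ms.  The window
count is `max(1, floor((T − W) / stride))`: 80 windows per 10-s segment
(offsets 0…7900 ms).  The final flush-with-the-end start position is
excluded by this rule; an inclusive endpoint would give 81.

Splits follow the 23 : 2 : 2 design: per class, `round(n × 2/27)` segments
are drawn at random into the held-out test set (2 of 27 vessel and 28 of
377 fetal at published scale; at least one per class is required).  The
remaining windows are balanced by duplicating the minority class
`round(majority/minority)` times (14 at published scale; round-half-up),
then pooled and split 92 % / 8 % into train/validation uniformly at random
*at the window level*.  The window-level split replicates the original
design and lets overlapping windows of one segment land in both train and
validation; a leakage-free segment-level split is available behind
`PipelineConfig.segment_level_split=True`.  Test windows are never
duplicated, and no segment contributes to both test and any other split.

## Classical discriminator scores

Per 2-s window: **peak amplitude** (max |x|), **average amplitude**
(mean |x|), **central frequency intensity** (power at the fundamental), and
**half-power bandwidth**.  The spectrum is a one-sided FFT power spectrum
of the raw signal after mean removal only — no taper, 0.5 Hz bins —
normalised so bin powers sum to signal energy.  The fundamental is the
highest-power non-DC bin, ties broken toward the lowest frequency; it is
computed on the signal itself, not a demodulated envelope (the envelope
reading is a defensible alternative, but the direct reading matches the
description of computing it "from the frequency characteristics").  The
half-power band is the maximal *contiguous* region around the fundamental
with power ≥ half the fundamental's, edges linearly interpolated between
bins — "width" in the singular implies one interval, not a union of bands.
Mean removal prevents DC from masquerading as the fundamental.  Silent
windows have no defined spectral scores and are signalled, not scored.

## The 1D-CNN

Four blocks of (valid 1-D convolution → ReLU → max-pool 2) with kernel
size 9 and channel widths 16/32/64/128, then a fully connected layer to two
logits and softmax.  The channel/kernel/pool choices are a conventional
doubling pyramid — the original architecture diagram is not recoverable
from text — and all are config-exposed.  Training minimises cross-entropy
with Adam at the fixed learning rate 6.066 × 10⁻⁴ (the published value; an
adaptive optimizer is implied by a tuned rate of that precision), batch
size 64, default 100 epochs; shuffling is seeded; the delivered model is
the epoch checkpoint with the best validation loss.  Raw amplitudes in
[−1, 1) are fed directly with no per-window standardisation, preserving
amplitude information, and class imbalance is handled entirely by the
pipeline's duplication, not loss weighting.  The network, its
backpropagation and Adam are implemented in numpy (im2col convolutions,
argmax-routed pooling), float32 throughout.

## Evaluation

The confusion matrix is over (true, predicted) fetal/vessel pairs.
Accuracy, precision, recall and F1 are reported as percentages with
TP/TN/FP/FN mapped by an explicit positive class.  **The default positive
class is vessel**: the published worked example (accuracy 97.9, precision
82.3, recall 86.9, F1 84.5 from the matrix 2210/30/21/139) is reproducible
only under that convention, although the accompanying prose describes TP as
fetal–fetal; both conventions are computable.  Reported percentages use a
two-stage half-up rounding — the proportion is rounded to 0.01 % and then
to 0.1 % — which is the convention that reproduces all four published
figures (a single-stage rounding of 139/169 = 82.2485 % would print 82.2).
The F1 harmonic-mean identity holds exactly before rounding.  Zero
denominators leave a metric undefined and flagged, never silently zero.

ROC curves are computed over all score thresholds with trapezoidal AUC
(scikit-learn's implementation), which equals the Mann–Whitney statistic
P(score⁺ > score⁻) + ½ P(equal) under ties; the test suite checks this
against an exhaustive pairwise oracle.  Baseline scores take an explicit
orientation argument since neither discrimination direction is canonical;
`discrimination_auc` reports the orientation-free max(AUC, 1 − AUC).

The quality timeline classifies consecutive 2-s windows along a recording
and colours them blue (p_fetal ≥ p_vessel) or red, aligned to the trace
time axis for plotting next to FHR/MHR.

## The default synthetic study

Tests, examples and the acceptance script use one standard configuration
(`default_study_config`): 27 recordings of 160 s, each with one 40-s
crossing episode and one 40-s coincidence episode aligned to the 10-s
segment grid.  This yields 108 labelled segments per class, of which the
2/27 rule allocates 8 per class to test (640 windows each side) and leaves
8,000 train+validation windows per class — large enough for stable AUC
estimates while a full run (simulation, selection, training at 2 epochs,
evaluation) completes in a few minutes on one CPU.  Two epochs suffice
because the synthetic classes are morphologically well separated; the
100-epoch default remains on `CnnConfig` for study-scale fidelity.

On this study the expected structure, verified across seeds: the CNN's
test AUC ≈ 1.0 exceeds every classical score; average amplitude is the
strongest classical score (the envelope duty cycle differs between one
wide and two narrow bursts per beat); half-power bandwidth is moderately
informative (wider fetal spectral lines); peak amplitude is weaker (gain
normalisation leaves only crest-factor differences); and central frequency
intensity is closest to chance, because the per-class spectral peak density
— energy divided by velocity-band spread — is nearly equal by construction.
This reproduces the qualitative ordering of the original comparison, not
its numeric AUCs, which depend on the private data.

## Numerical and design notes

* All randomness flows through named `numpy` Generator streams derived from
  integer seeds; identical configs give bit-identical recordings, splits,
  initial weights and training trajectories on one machine.
* Time is 0-based seconds; intervals are half-open [start, end); the 4 Hz
  and 1 kHz tracks share their start, so trace sample i covers DUS samples
  [250 i, 250 (i+1)).
* Heart-rate traces serialise missing readings as empty CSV cells; the
  50–240 bpm device range is validated on read.  WAV input must be PCM16
  mono 1000 Hz; anything else is rejected, never resampled silently.
* Rounding of split sizes and the balancing factor is round-half-up.
* Prediction ties (p = 0.5 exactly) resolve to the fetal majority class.
* Known limitations: no real-data validation; the classical-score AUC
  values depend on generator parameters and should not be quoted as
  estimates of clinical performance; the CNN is intentionally small and
  CPU-trainable, not an architecture search result.
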