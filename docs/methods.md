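# Methods

`lungsound` implements a complete lung-auscultation classification
pipeline around a CNN-LSTM fusion network: synthetic annotated corpora,
signal conditioning, mel-spectrogram features with disease-specific band
weighting, waveform augmentation, subject-wise cross-validated training
and evaluation, and Grad-CAM attribution. This note records the model,
the choices made where the design was open, and what the synthetic
experiments do and do not demonstrate.

## The classification model

Input is a per-segment mel-spectrogram: 2.5 s of audio at 8 kHz, 25 ms
Hann windows every 10 ms (left-aligned, tail zero-padded, so exactly
250 columns), a 128-filter HTK-style triangular mel bank from 0 Hz to
Nyquist, power converted to dB with an 80 dB floor relative to the frame
maximum and min-max scaled to [0, 1] — a (128, 250, 1) array.

The network applies three valid 3x3 convolutions (16/32/64 filters,
stride 1, ReLU), each followed by 2x2 max pooling, giving spatial maps
(63, 124) -> (30, 61) -> (14, 29). The pooled map is read as a
29-step temporal sequence whose step vector stacks the 14 frequency
positions x 64 channels, and passed through two stacked 128-unit LSTM
layers with the standard gates

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        (forget)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        (input/update)
    c^_t = tanh(W_C [h_{t-1}, x_t] + b_C)          (candidate)
    C_t = f_t * C_{t-1} + i_t * c^_t               (cell)
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)        (output)
    h_t = o_t * tanh(C_t)                          (hidden)

A `cell_variant="printed"` switch drops the `i_t` factor from the cell
update (C_t = f_t C_{t-1} + c^_t); it exists only for compatibility
experiments — the standard form is the default and the one trained,
since the update-gate definition makes sense only when the gate is used.

The final hidden state (128) is concatenated with the global average
pool of the last conv map (64), passed through a 64-unit ReLU dense
layer and a softmax output. Training minimizes cross-entropy plus an L2
penalty `lambda * sum(W^2)` over weight matrices (biases excluded),
lambda = 1e-4, with Adam (beta1 = 0.9, beta2 = 0.999, eps = 1e-8),
batch size 32, up to 50 epochs with early stopping on validation loss
(patience 5, best-validation parameters restored). The learning-rate
grid {0.1, 0.01, 0.001, 0.0001} is searched on validation loss;
0.001 is the default. Initialization is seeded uniform Glorot with a
+1 forget-gate bias. Gradients are clipped to a global L2 norm of 5
before each update: backpropagation through the 29-step LSTM stack
occasionally produces exploding gradients that would otherwise undo
several epochs of progress in one step.

The forward/backward passes and Adam are implemented directly in NumPy
(buffered patch-gather + GEMM convolutions, mask-based pooling
gradients, full BPTT through both LSTM layers). A structurally
independent scratch route (`model/reference.py`: per-channel-pair
`scipy.signal.correlate2d`, per-element gate equations) exists solely to
cross-check the vectorized implementation in tests; the two agree to
1e-5 on random parameter draws at the default architecture.

## Band weighting

Crackles (brief broadband transients, energy above 1 kHz) indicate
pneumonia-type disease; wheezes (sustained 200–800 Hz tones) indicate
asthma/COPD. When a segment carries annotations, mel rows with center
frequency above 1 kHz are multiplied by 1.5 if the crackle flag is set,
and rows with centers inside 200–800 Hz by 1.3 if the wheeze flag is
set. The two weightings are independent, applied to the feature matrix
(not the loss; a `weighting: features|off` switch and per-class loss
weights cover the alternative reading), and deliberately not
re-normalized, so they commute and are exactly invertible.

The alternative "loss" reading of the weighting — per-class loss
weights (crackle-annotated classes 1.5, wheeze-annotated 1.3) instead
of feature scaling — is available through the trainer's class-weight
support and the experiment's `weighting="loss"` switch.

Because annotation flags encode ground truth, applying them at
inference time would leak label information. We verified this
empirically: a model trained on weighted features classifies perfectly
when test features are also weighted from ground-truth flags, but
collapses on honest unweighted inputs — the weighting becomes the
label. The end-to-end experiment therefore trains and evaluates with
weighting off; `run_synthetic_experiment(weighting="features")`
reproduces the weighted protocol and reports both evaluation modes, and
a user with genuine (detector-derived, not ground-truth) annotations
can apply the weighting without leakage.

## Synthetic corpus

The generator emulates the structure of public auscultation corpora
with per-class recording counts (defaults: healthy 300, pneumonia 200,
asthma 150, COPD 100 for the ICBHI-like flavour; healthy 200, pneumonia
150, asthma 100, COVID-19 100 for the Coswara-like flavour), WAV + tab-
separated per-cycle annotation sidecars + CSV manifest, and subjects
contributing 1–5 recordings each (making subject-wise splits
non-trivial). Breath noise is 1 kHz low-passed white noise shaped by a
raised-sine respiratory envelope at 12–24 cycles/min. Crackles are
exponentially damped 1.2–2.5 kHz sinusoids (8–40 ms) over a 5 ms click,
at 8x the breath-noise amplitude — brief transients must stand well
above the noise floor to be audible, and at lower amplitudes they are
statistically invisible in the recording spectrum. Wheezes are pure
envelope-modulated tones with mild vibrato, spanning the configured
fraction of each respiratory cycle; coughs are broadband bursts with a
sharp attack. Asthma and COPD are separable by design: asthma wheezes
draw fundamentals from 420–800 Hz with a 0.5 duty cycle, COPD from
200–380 Hz with a 0.3 duty cycle — the clinical contrast between
higher-pitched asthmatic wheeze and low-pitched rhonchi; bronchiectasis
is a crackle+wheeze mixture; COVID-19 recordings carry coughs only.

What this does **not** emulate: airflow or acoustic propagation
physics, heart sounds, ambient noise, sensor variation, intra-subject
disease progression, or the heavy class overlap of real auscultation.
Passing the synthetic experiments shows the pipeline is wired correctly
and can learn band-localized acoustic signatures — it says nothing
about clinical accuracy on real recordings, which is why the published
real-data accuracies are not reproduction targets here.

## Problem sizes and numerical choices

- Experiments use 3.0 s recordings (one 2.5 s frame after trimming);
  the generator default is 10 s. The full per-class composition
  (750 recordings) then trains in minutes on one CPU core.
- The end-to-end experiment trains fold 0 of the 5-fold subject-wise
  split with augmentation applied to the training fold only
  (multipliers: pneumonia 1.5x, asthma/COPD/COVID 3x, healthy 1x),
  capped at 15 epochs.
- Resampling is polyphase (`scipy.signal.resample_poly`); the high-pass
  is a 4th-order Butterworth applied forward-backward (zero phase), so
  stopband attenuation doubles to ~48 dB one octave below cutoff.
- Normalization uses the population standard deviation and is applied
  per recording before segmentation (a per-frame switch exists).
- Silence trimming uses 50 ms windows at -40 dB relative to the peak
  window RMS; fully silent inputs are an error, not an empty return.
- Segmentation: hop = frame x (1 - overlap); a too-short signal yields
  one zero-padded frame with a warning rather than rejection (keeps
  short cough recordings usable).
- STFT length 1024 (25 ms window zero-padded) so that every mel filter
  spans at least one FFT bin and every bin feeds at least one filter.
- Time stretching is a phase vocoder (1024-point STFT, 256 hop) with
  tie-break-free phase accumulation; pitch shifting resamples then
  stretches back, preserving length exactly. "Noise injection (10%)"
  is implemented as noise RMS = 10% of signal RMS (20 dB SNR),
  configurable.
- AUC uses a threshold sweep with simultaneous steps on tied scores,
  equal to pairwise concordance with half credit for ties; undefined
  metrics (0/0) propagate as NaN and are excluded from macro averages
  with a warning, never coerced to zero.
- Segment probabilities are aggregated to recordings by the mean before
  argmax; per-class "accuracy" is one-vs-rest, overall accuracy is
  trace/total, macro averages are unweighted.
- Grad-CAM differentiates the pre-softmax class score w.r.t. the last
  conv layer's ReLU activations, upsamples bilinearly to 128 x 250 and
  min-max normalizes (all-non-positive maps normalize to zeros).
- The scratch-vs-backend equivalence suite runs its 100 random draws at
  a reduced architecture plus a few draws at the full default: the
  scratch route is intentionally naive and its cost would otherwise
  dominate the suite without adding coverage.

## Known limitations

- Grad-CAM attribution reflects whatever evidence the classifier uses,
  including *negative* evidence: because only pneumonia-type recordings
  carry energy above 1 kHz, the model partly identifies the wheeze
  classes (COPD in particular) by the absence of high-band energy, and
  their heatmaps place substantial mass in that empty region rather
  than on the wheeze fundamental. The wheeze-band localization
  statistic should be read with this in mind; it is a property of the
  task's class geometry, not of the attribution implementation.
- The NumPy trainer is single-device and unoptimized beyond GEMM
  batching; it is meant for desk-scale experiments, not production
  training.
- The generator's class separability is optimistic; cross-dataset
  experiments here probe protocol correctness (shared-class
  restriction, direction asymmetry under distribution shift), not
  realistic generalization gaps.
- SHAP/LIME-style attributions and ResNet/VGG or transformer backbones
  are out of scope.
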