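# Methods

This note documents the models implemented in `wbdecode`, the choices made
where the design was genuinely open, the synthetic benchmark conditions, and
the limits of what the synthetic results establish.

## Wavelet front end

Each channel of the raw recording is decomposed with the Morlet continuous
wavelet transform, mother wavelet ψ₀(η) = π^(−1/4)·e^(iω₀η)·e^(−η²/2) with
non-dimensional frequency constant ω₀ = 6. The transform is evaluated in the
Fourier domain with the analytic Morlet filter (one FFT per channel, one
inverse FFT per band), using the standard Fourier-wavelength relation
λ = 4πs/(ω₀ + √(2 + ω₀²)) to convert each bank frequency to a scale.
Edge effects are handled by reflection padding of half the longest wavelet
support (4 scale-widths per side). The frequency bank is generated
analytically as f_k = f_max·2^(−k/2) down to f_min — never copied from a
printed list — giving 26 bands from 15 kHz to 2.59 Hz at the full scale, and
the corresponding sub-bank when the data rate is lower (the bank is anchored
at the session Nyquist, e.g. 15 Hz for 30-Hz calcium traces).

Stored coefficients are magnitudes |W| by default (power |W|² is a flag):
the subsequent per-(channel, band) MAD normalization makes the decoder
insensitive to both the magnitude/power convention and the CWT normalization
constant, but magnitude keeps the dynamic range tame in float32. The
downsampling step is a non-overlapping block mean of length M along time
(a fixed-weight averaging convolution with kernel and stride M), taking
30 kHz to 30 Hz at M = 1000; normalization statistics (median and median
absolute deviation per channel × band) are always fitted on training
partitions only, with zero-MAD series mapped to zeros.

## Shared-weight convolutional decoder

The decoder consumes windows of the normalized tensor shaped
(T timesteps × F bands × C channels); T = 64 at the full scale (2.13 s of
30-Hz tensor). All convolutions are 3×3. The first block (8 layers, 64
filters) convolves the (time, frequency) plane with weights shared across
channels — channels fold into the batch axis — with stride-2 downsampling
alternating between the time and frequency axes from layer 2, stopping when
an axis reaches size ≤ 2. The second block (6 layers, filters doubling every
2 layers) convolves the (frequency, channel) plane with weights shared
across the remaining timesteps, downsampling the channel axis only — which
is why a 64-channel input uses exactly one fewer stride-2 step than a
128-channel input. A fully connected trunk (256 units by default) feeds one
linear head per decoded variable. Gaussian noise (σ = 1) is added to the
inputs during training only.

The 256-unit trunk is a deliberate proportion choice: with a wide trunk the
fully connected layer dominates the parameter budget and the economy of
weight sharing is obscured; at 256 units the convolutional stack dominates
and the unshared-to-shared parameter ratio of the default 128-channel
configuration is ≈ 6×, in line with the published ~7× economy of this
architecture family. Both the width and every other architecture field are
configurable.

Losses: position is trained with the squared Euclidean objective (its
reported error is the mean 2-D distance in cm), speed with MAE, angles with
cyclical MAE (circular distance min(|d|, 2π−|d|), the only nonnegative
reading of the printed cyclical form). The quadratic position objective is
what keeps the regression head calibrated — with pure distance gradients the
head develops heavy-tailed test-time excursions that wreck the variance-
based score while barely moving the mean error. Two further stabilizers:
targets are standardized per head during training (one scalar scale per
head, preserving Euclidean geometry; angles are never rescaled) and
predictions are clamped to the training-target range (a linear head can
extrapolate wildly on uninformative windows; the clamp is part of the
decoder's prediction transform).

Performance is scored with FVAF, R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² with no
rescaling of predictions (α = 1, β = 0): at most 1, zero for predicting the
mean, unbounded below.

Training: Adam (learning rate 7·10⁻⁴), 15 epochs × 150 batches × 8 windows
(= 18 000 windows) at the full scale, sampled uniformly with replacement
from the training region; the learning rate is multiplied by 0.2 when the
validation loss (last 10 % of training windows) fails to improve for three
epochs. Cross-validation uses five contiguous equal partitions with a 2-s
gap: a training window is excluded whenever its span comes within the gap
of the test block, so train and test are fully independent; the decoded
value of a window is assigned to its final timestep (causal alignment).
The whole network — forward, backward, Adam — runs on numpy arrays in
float32 and is bit-deterministic given its seed.

**Chance model.** The no-information baseline retrains the identical
architecture, seeds and schedule after circularly shifting the behavior by
half the session relative to the tensor (maximally decorrelating and
reproducible; a zero shift reproduces normal training bit for bit), and is
evaluated against the shifted targets.

## Bayesian baseline

The classical Poisson decoder on spike times: per-unit ratemaps on 2-cm
bins (Gaussian-smoothed spike counts over Gaussian-smoothed occupancy,
σ = 1.5 bins, both restricted to training time and movement > 3 cm/s;
unvisited bins masked and given zero prior), and per 0.5-s window
P(x|K) ∝ P(x)·Πᵢαᵢ(x)^kᵢ·e^(−TΣᵢαᵢ(x)) evaluated in log space with argmax
readout (ties broken by first bin index). The optional continuity prior
multiplies the posterior by exp(−‖x−x_{t−1}‖²/2σ_t²) with σ_t = v_t·V,
V = 1 s, v_t estimated from the previous four decoded steps and floored at
one bin (2 cm) so the prior never collapses to a delta while the decoder
stalls; decoded (not true) positions drive v_t by default. The same
machinery decodes head direction on 36 angular bins with circular error.

## Influence analyses

*Shuffle influence*: for each index along a chosen axis (frequency band,
channel, or within-window timepoint), that slice of the evaluation windows
is permuted across the evaluation set — jointly over channels by default,
preserving within-slice marginals — decoding is repeated without
retraining, and the relative error change (e_s−e_o)/e_o is averaged over
`n_repeats` (default 10) permutations; a time-constant slice has exactly
zero influence. Shuffling is confined to the held-out fold.

*Event-locked elimination*: the named bands are overwritten within ± one
effective-rate bin of each event time by the band's per-channel training
median (a random-permutation "scramble" fill is available; note that
scrambling injects spike-band power at event times and can masquerade as
false unit activity when bands are spectrally adjacent). Events can be
given per channel for surgical elimination at each channel's own unit spike
times.

*Single-band models*: one reduced decoder per band (all other bands
zeroed), with the per-band FVAF rank-correlated against the joint model's
shuffle influence.

## Downstream analyses

Interneuron classification requires all four of: trough half-width
< 0.15 ms, rebound/trough amplitude ratio ≤ 0.4, session rate ≥ 4 Hz, and
first/second-half spatial-map correlation ≤ 0.75. Head-direction
modulation: occupancy-normalized polar ratemap (36 × 10° bins, 1-bin
circular smoothing) restricted to motion (> 10 cm/s) and the arena centre
(> 25 cm from the long walls, > 20 cm from the short walls); tuning depth is
the KL divergence against the uniform circle; the null circularly shifts
the spike train by ≥ 20-s uniform offsets (≥ 1000 shifts at full scale);
stability is the Pearson correlation of first/second-half maps with its own
shuffle p; a unit counts as modulated only when both p < 0.01. Ripples:
150–250 Hz band-pass (4th-order Butterworth, zero-phase), Hilbert envelope,
10-ms Gaussian smoothing, z-scored; events seed at ≥ 5 SD, expand to the
0.5 SD crossings, and are kept when ≥ 60 ms and stationary (< 3 cm/s)
throughout — all thresholds SD-relative, hence gain-invariant. Replay
statistics per candidate event: mean Euclidean decode error, summed path
length, and coherence deviation (mean distance to a degree-2 polynomial in
time fitted per coordinate); the null re-places the events (lengths kept)
uniformly over stationary periods 1000 times, with one-sided p-values
(error and length: observed ≥ null; coherence: observed at least as
coherent).

## Synthetic data

The generator produces what the decoder assumes real sessions contain:

* an Ornstein–Uhlenbeck velocity walk (correlation time 1 s) reflected at
  the walls of a 1.75 × 1.25 m arena, sampled at 30 Hz; head direction is
  the velocity heading and speed its magnitude;
* Poisson place cells (Gaussian fields, peaks 8–20 Hz over a 0.1-Hz floor)
  and interneurons (6–12 Hz baseline, optionally von-Mises head-direction
  modulated), each with a biphasic extracellular template — a narrow
  negative trough plus a broad rebound (rebound/trough ≈ 0.35), exactly
  zero-mean so the spectral energy is band-passed. The place trough
  (σ = 0.15 ms, half-width 0.35 ms) puts the template's dominant wavelet
  energy in the 469 Hz band; the interneuron trough (σ = 0.02 ms) lands in
  the 3750 Hz band. When the sampling rate cannot resolve a trough
  (σ·fs < 0.5) the template falls back to the discrete high-pass kernel
  [0.5, −1, 0.5], concentrating its energy at the highest representable
  band rather than degenerating into a broadband impulse;
* tetrode-like channel mixing (each unit has one home channel at gain 1,
  0.05 elsewhere), a theta sinusoid whose instantaneous frequency is
  f₀ + 0.05·speed (f₀ = 8 Hz) on every channel, and white noise;
* the wavelet-level "simulated behavior": selected bands of a coefficient
  tensor are replaced by f_old·β·y_sb(t), with y_sb uniform on (0.05, 1]
  (the lower bound avoids zeroing bands). `synthetic_wavelet_tensor`
  provides a band-realistic carrier for this: lognormal amplitude envelopes
  whose temporal correlation follows each band's own timescale (AR(1) with
  time constant 10 cycles) and whose amplitude falls off as 1/√f, so slow
  bands are smooth and large while spike bands are fast and spiky.

An important subtlety: the modulation is applied to the tensor *after* the
MAD statistics are fitted (as when modulating already-preprocessed
wavelets). Refitting the normalization on modulated data removes β exactly
— multiplicative gains cancel in (X−X̃)/MAD — and the expected dominance of
the β = 2 band over the β = 1 band cannot then arise; with pre-modulation
statistics the stronger band keeps twice the post-normalization amplitude
and wins against the fixed σ = 1 training noise.

## Benchmark conditions

The desk-scale benchmarks (in `wbdecode.benchmark`, used by the test suite
and the acceptance script) run on one CPU in minutes:

* sessions of 10 min; neural rate 3750 Hz for decoding benchmarks (the
  469/663 Hz place bands sit below Nyquist) and 7500 Hz for the elimination
  benchmark, where the interneuron band (3750 Hz) must sit two octaves above
  the place bands — at 3750 Hz sampling the two classes crowd spectrally
  and the contrast degrades;
* 4 channels, 20 place cells with broad overlapping fields (σ 18–30 cm,
  peaks 15–30 Hz) and, where needed, 6 interneurons at 5–9 Hz; white-noise
  SD 0.07, the spectral density of a 0.2-SD floor at 30 kHz;
* benchmark foraging speed 18 cm/s so that every 2-min cross-validation
  partition covers the arena, as the real 40-min sessions do (the
  generator's default is a calmer 12 cm/s);
* a reduced decoder (3 + 2 conv layers, 8 filters, T = 32, 64-unit trunk)
  trained for 5–6 epochs of 75 × 16 windows; evaluation on fold 0.

What passing these benchmarks shows: the full pipeline — synthesis, CWT,
normalization, gap-separated CV, training, chance control, influence,
elimination — is wired correctly and recovers planted structure (place
fields, band-level modulations, class asymmetries, HD tuning) from raw
signal alone. What it does not show: performance numbers comparable to real
128-channel recordings (errors here are ~25–40 cm rather than ~17 cm;
sessions are 4× shorter, channels 32× fewer, and the model far smaller),
robustness to real noise structure (drift, movement artifacts, correlated
noise, waveform diversity), or anything about spike-sorting quality, which
the synthetic Bayesian baseline sidesteps by receiving ground-truth spike
times.

## Numerical notes and limitations

* All randomness flows through `numpy.random.default_rng` seeds; training,
  synthesis and permutation tests are bit-reproducible.
* The CWT filter is truncated where the Gaussian factor is below e^(−40);
  FFTs run in complex64.
* Permutation p-values use the add-one estimator (1 + #null ≥ obs)/(1 + n).
* Ties in Bayesian argmax go to the first bin index; zero-MAD bands
  normalize to zeros; underflowed posteriors fall back to uniform over
  visited bins with a warning.
* The trajectory model has no pauses or wall-following; real occupancy is
  less uniform. Spike templates do not burst, adapt, or overlap-resolve.
  Interneuron templates at reduced sampling rates are band-limited kernels,
  not realistic waveforms — adequate for spectral-class contrasts, not for
  waveform-shape analyses (the classifier tests use 30 kHz templates).
* The exact stride placement and trunk width of the full-scale published
  architecture are not public; the printed full-scale parameter totals are
  therefore not exactly reproducible, and the sharing economy is asserted
  as a ratio instead.
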