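# Methods

## Scope and model

`eegmusic` implements a parametric spectral feature-extraction pipeline for
multichannel EEG emotion classification.  A windowed EEG channel `y(n)` is
modeled as `p` sinusoidal components in additive white noise.  The biased
sample autocorrelation lags

    g(k) = (1/N) * sum_n y(n) y(n+k),   k = 0..L-1

form a symmetric Toeplitz matrix `R` of order `L`.  The biased normalization
(divide by `N`, not `N-k`) is deliberate: it guarantees `R` is positive
semidefinite, which the subspace split requires.  The eigendecomposition of
`R` (eigenvalues sorted descending) is partitioned into a signal subspace
(leading `d` eigenvectors) and a noise subspace (trailing `L-d`); the noise
variance is estimated as the mean of the trailing eigenvalues.  The MUSIC
pseudospectrum probes candidate angular frequencies `w = 2*pi*f/fs` with the
steering vector `s(w) = [1, e^{jw}, ..., e^{j(L-1)w}]`:

    P_MUSIC(w) = 1 / sum_{k > d} | s(w)^H v_k |^2

Peaks of `P_MUSIC` mark frequencies nearly orthogonal to the noise subspace.
Pseudospectrum values are *not* calibrated power densities; given peak
frequencies `w_1..w_p`, per-component powers are recovered from the
Pisarenko harmonic system `sum_i cos(k w_i) P_i = g(k)`, `k = 1..p`, solved
as an exact `p x p` linear system with the residual and condition number
reported.  (A least-squares variant over more lags would also be defensible;
the exact solve matches the square form of the system and the residual
makes any misfit visible.)

Design choices inside this core:

* **Squared magnitude.**  The estimator uses `|s^H v|^2` in the denominator,
  the standard MUSIC form; an unsquared variant is available
  (`squared_magnitude=False`, `--eq7-literal` on the CLI).  Peak positions
  are identical; only peak heights differ.
* **One correlation order.**  A single order `L` (default 20) controls both
  the autocorrelation matrix and the steering-vector length; mixed
  conventions for the two are dimensionally inconsistent.  `L = 20` at
  200 Hz exceeds twice the number of modeled real tones with margin while
  keeping the per-window eigenproblem cheap; it is configurable.
* **Counting the signal dimension.**  A real sinusoid occupies two
  complex-exponential eigen-dimensions, so three modes ship:
  `real_sinusoids` (`d = 2p`, the correct count for real signals; default),
  `complex_dims` (`d = p`, the literal one-dimension-per-band reading with
  `p = 3` for the alpha/beta/gamma bands), and `noise_threshold`
  (`d` = eigenvalues above a cut, no prior count needed).
* **Frequency grid.**  124 uniform bins spanning 8-40 Hz, matching the
  fixed per-channel feature length of the classification stage; bounds and
  size are configurable.

The non-parametric baseline is Welch's method (averaged Hamming-windowed
modified periodograms), density-normalized so the integral over the
half-band approximates the signal variance.

## Preprocessing

Two workflows feed feature extraction.  The full-montage path notch-filters
and bandpasses all channels.  The lobe-reduction path extracts the five
analysis lobes (prefrontal, frontal, central, parietal, occipital),
notch-filters, drops QC-flagged corrupt channels, bandpasses, and collapses
each lobe to its first principal-component time series, cascading the five
series into a 5 x N trial.

* **Filters.**  Powerline notch: 2nd-order Butterworth IIR bandstop, 48-52
  Hz half-power edges.  Band of interest: 500-tap Hamming-window FIR
  bandpass, 8-40 Hz (the alpha-through-gamma range; delta/theta carry no
  task-relevant information here).  Both are applied forward-backward
  (`filtfilt`), giving exactly zero phase so that time alignment across
  channels — which the PCA mixing step assumes — is preserved.  A 500-tap
  (even-length) linear-phase FIR has a non-integer group delay of 249.5
  samples, so integer-shift delay compensation cannot be exact; the
  forward-backward application sidesteps this.  Consequence: the effective
  magnitude is the *square* of the designed response (stopband attenuation
  doubles in dB; the single-pass -3 dB edges become -6 dB points).  The
  designed single-pass responses are exposed for verification
  (`notch_frequency_response`, `bandpass_frequency_response`) and the filter
  contracts are stated against them.
* **Edge handling.**  `filtfilt`'s default odd-reflection padding; trials
  shorter than three filter lengths are rejected rather than silently
  dominated by edge transients.
* **PCA reduction.**  Channels are variables, time points observations;
  rows are mean-centered; the component sign is fixed so its correlation
  with the channel-mean series is non-negative.  Spectral features are
  sign-blind, but the fixed convention makes runs reproducible.
* **Eye blinks.**  Blink removal is a caller-supplied hook
  (`eyeblink_removal`), not built in: blink energy lives below 8 Hz and the
  bandpass removes most of it; dedicated wavelet-ICA cleaning can be plugged
  in without changing the pipeline.

## Channel quality control

Clean scalp EEG occupies roughly 10-100 uV; EMG bleed-through and electrode
leakage produce channels peaking at 0.6-10 mV.  Screening is per-trial on
the per-channel maximum absolute amplitude (matching the "ranges up to"
character of such faults; an RMS screen would under-weight brief
excursions).  The default threshold of 500 uV sits inside the gap between
the two regimes and is exposed everywhere.  Raising the threshold can only
remove flags (monotonicity), and re-screening a masked trial is clean
(idempotence); both are property-tested.

## Feature tensors

Each channel is cut into 50%-overlapping windows (default 1024 samples,
about 5 s at 200 Hz — long enough for stable lag estimates at `L = 20`,
short enough for many windows per trial); the estimator runs per window;
per-window spectra are averaged and evaluated on the 124-bin grid.  For
Welch, averaging single-segment modified periodograms over this window plan
*is* Welch's estimate for the whole channel, computed stepwise on the same
plan MUSIC uses, so the two estimators differ only in the spectral estimate
itself.  MUSIC runs through a batched path: stacked Toeplitz assembly, one
batched `eigh`, and a single complex matrix product projecting the steering
vectors onto the smaller of the two eigen-subspaces (using
`sum_noise |s^H v|^2 = L - sum_signal |s^H v|^2`, valid because
`|s(w)|^2 = L`), which is what makes it fast on long multichannel trials.  Stacking trials yields a
`trials x channels x 124` tensor: `45 x 62 x 124` for a 45-trial full-montage
subject, `45 x 5 x 124` on the lobe-reduced path.  Features are linear
spectrum values by default with an optional log10 transform.  The 124-bin
axis is interpreted as spectral bins (the tensors are spectra over
channels); window spectra are averaged, not concatenated, since
concatenation would not produce a fixed-length feature row.

## Classifier and evaluation protocol

A two-hidden-layer perceptron (512 and 248 ReLU units) with a 3-way softmax
head, trained by mini-batch SGD (batch 16, the smallest defensible default
optimizer — no momentum or adaptivity hidden behind the protocol):

* max 500 epochs; early stop when validation loss has not improved for 20
  consecutive epochs, best weights restored;
* 10% of the training split held out (stratified) as the validation set;
* initial learning rate 0.001; after 10 consecutive stagnant epochs the
  rate is multiplied by 1.25.  Increasing the rate on plateau is an
  unusual rule, most plausibly intended as a decay, so the factor is
  configurable (0.75 recommended when decay is wanted).  With patience 20,
  at most one adjustment fires before stopping, so the choice is benign;
* per-feature standardization fitted on each training split only — held-out
  folds never touch the scaler (verified by a mutation test);
* categorical cross-entropy by default.  "Binary cross-entropy with a
  softmax head" is internally inconsistent; a `per_class_bce` option keeps
  the literal reading (mean BCE across the three softmax outputs,
  backpropagated through the full softmax Jacobian).

Evaluation is stratified 5-fold cross-validation (every trial tested exactly
once), reporting per-fold and mean accuracy, per-class precision/recall/F1
from pooled confusion matrices, and full training histories.  Tensor rows
are flattened channels-major (channel index varies slowest).  The trainer is
written directly on NumPy so the epoch-level protocol (patience counters,
rate schedule, histories) is explicit, deterministic given the seed, and
inspectable; weights are single-precision, which halves the linear-algebra
cost at these layer sizes without affecting the protocol.  Training splits
too small to spare a stratified validation example fall back to monitoring
the training loss.

## Synthetic data

The generator emulates a 62-channel, 200 Hz emotion-recognition recording:
each clean channel is a sum of band-limited oscillations (alpha 10 Hz, beta
20 Hz, gamma 35 Hz by default) whose amplitudes depend on the emotional
state, over 1/f background noise (power ~ 1/f, exponent 1, synthesized by
spectral shaping of white noise), 50 Hz common-mode powerline pickup, and
0.3 s raised-cosine blink pulses on prefrontal/frontal channels only.
Default per-state band amplitudes (uV):

| state | alpha | beta | gamma |
|---|---|---|---|
| negative | 22 | 8 | 4 |
| neutral | 12 | 12 | 7 |
| positive | 6 | 18 | 11 |

These place clean-channel peaks well below 200 uV while separating the
states strongly in band power.  Corrupt channels add an EMG/leakage-like
artifact — a slow 0.5 Hz drift plus broadband noise at 0.3 relative
amplitude, rescaled to the requested millivolt peak (0.6-10 mV).  The
broadband part matters: it floods the 8-40 Hz analysis band the way real
EMG-contaminated channels do, so corrupt channels both trip the amplitude
screen and dominate feature rows until masked.  All randomness flows from a
single master seed; trial `k` draws from an independent stream seeded by
`(master_seed, k)`, so any subset of a dataset is reproducible alone.

Default trial length is 20 s.  That is far shorter than a film-clip trial
(about 5 minutes), chosen so a 45-trial dataset builds in seconds; the
spectral structure per window is unchanged, and full-length trials run
through the identical code path.  What the generator does *not* emulate:
dipole-source geometry and volume conduction (channels are independent
draws, so spatial covariance is unrealistic and per-lobe PCA concentrates
less variance than on real data), non-stationarity across a trial,
subject-to-subject variability, and realistic artifact diversity.  Passing
tests therefore demonstrate correctness of the pipeline's mechanics and its
behavior under known spectral ground truth — not expected accuracy on real
recordings.

## Verification design

Every numerical stage is checked against an independent oracle: biased
autocorrelation against a direct double-loop sum and the closed form for
cosines; the eigensolver against characteristic-polynomial roots
(Faddeev-LeVerrier coefficients + polynomial root finding) on random PSD
matrices; MUSIC peak location against dense-grid evaluation and known tone
frequencies; Pisarenko against closed-form lags and hand elimination;
Welch against Parseval; filters against direct transfer-function
evaluation; classifier metrics against hand arithmetic and scikit-learn.
The end-to-end check trains the full protocol on the 45-trial synthetic
dataset (accuracy >= 0.95 expected) with a label-permutation control that
must stay in the 3-class chance band.

Problem sizes in the test suite (2000-sample records for frequency
recovery, 10-20 s trials, 8-62 channels, 50-replicate Monte Carlo) are
chosen so the whole suite runs in minutes on a single CPU while keeping
every statistical margin wide.

## Known limitations

* MUSIC pseudospectrum *values* are uncalibrated and high-variance
  (resonance heights behave like the reciprocal of a small projection);
  peak *locations* are the stable quantity.  Consistency under window
  averaging is therefore stated for Welch values and MUSIC peak locations,
  not raw MUSIC values.
* On close tones in heavy noise, Welch's lower-variance features can
  classify *better* than raw MUSIC features even though MUSIC resolves the
  frequencies more precisely: the parametric advantage is in frequency
  estimation (peak RMSE below the Welch bin width, property-tested), and it
  does not automatically transfer to discriminability of raw feature rows.
  The runtime advantage of the batched MUSIC path over per-window Welch is
  real but implementation-bound, and absolute benchmark times are
  hardware-dependent — only relative ratios are reported, and only their
  sign is asserted.
* The exact `p x p` Pisarenko solve degrades for closely spaced frequencies
  (the cosine system becomes ill-conditioned); the condition number is
  capped and reported rather than silently accepted.
* The montage-to-lobe table is a best-effort reconstruction for extended
  10-20 caps, shipped as editable configuration (YAML), not code.
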