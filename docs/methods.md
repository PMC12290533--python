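# Methods

This note documents the models, numerical choices and limitations
behind `freqtag`. It covers, in order: the stimulus model, the
synthetic EEG/behavior generator, the preprocessing chains, the ITPC
and FFR estimators, the behavioral scorers, and the orchestration
layer.

## Stimulus model

A tagged sequence presents one token every `soa` seconds (default
0.2 s → 5 Hz) for `total_duration` seconds (default 96 s → 480 events).
Tokens come from a 2×2 grid: tones at F0 = 110.88 / 124.72 Hz and
70 / 175 ms (a matched "vowel-placeholder" grid carries the natural
vowels' values 110.88 / 124.40 Hz and 70.58 / 175.83 ms but is rendered
as a harmonic complex — no speech resynthesis is attempted). Each token
is a four-harmonic equal-amplitude complex with 10-ms raised-cosine
on/off ramps, peak-normalized.

Each dimension alternates between its two levels every *k* sounds
(pitch k=2 → 2.5 Hz, duration k=3 → 1.67 Hz at the 5-Hz rate; 2 and 3
sounds at the 2-Hz attention rate → 1 and 0.67 Hz). The
level stream is built from *slots* of *k* sounds; a **repetition**
merges two consecutive slots into one run of 2k sounds — the level
holds through one scheduled change point and the change phase resets —
and the flag marks the first sound of the held slot. Repetition slots
are drawn uniformly among interior slots with the min-gap transform
(sorted distinct draws from a shrunken index range, re-expanded), which
samples uniformly over admissible non-adjacent configurations with no
retries. Two adjacent repetitions are disallowed because they would
merge into an unflaggable triple run. Default: 20 repetitions per
dimension per tagging sequence; exactly one per flagged dimension in
attention trials (the task asks about *a* repetition).

**Oddballs** scale a token to 25 % linear amplitude
(20·log₁₀ 0.25 = −12.04 dB; the dB figure is taken as authoritative
over a "decreased by 25 %" reading, which would be −2.5 dB). Placement
uses the same min-gap transform on the event grid so that no oddball
falls within 4.8 s of the sequence edges or of another oddball. The
default is 2 per 96-s sequence: the source description of "3–5 per
sequence, 32 in total over 16 sequences" is arithmetically
inconsistent, so the count is a parameter and the default keeps 32
total over a 16-sequence session. Tokens alternate polarity (+1/−1)
event to event.

Musical-beat stimuli are 6-tone patterns repeated 3 times (18 events,
tones back to back), with four pitch patterns over A4 = 440 Hz,
B4 = 493.9 Hz, C#5 = 554.4 Hz and four duration patterns over
50/100/200 ms, ordered from strongly-three-grouping to
strongly-two-grouping. The intermediate levels are stored as the
printed constants, not computed morphs.

## Synthetic EEG

**Cortical.** Channels follow the 32-channel 10/20 montage plus two
earlobe references (A1/A2). Each steady-state component is a sinusoid
whose phase is re-drawn once per 1.2-s analysis epoch as
base + wrapped-normal jitter of SD σ; its expected ITPC is therefore
exactly exp(−σ²/2), which the ground-truth record stores. Wrapped
normal was chosen over von Mises for this closed form. The topography
defaults to gain 1.0 over the nine frontocentral sites
(AF4, F3, Fz, F4, FC1, FC2, FC5, Cz, C3), 0.3 elsewhere on the scalp,
and 0.0 at the earlobes — so average-earlobe re-referencing is testably
neutral for signal amplitude. Background noise is Gaussian, spectrally
shaped to 1/f^α (α = 1 by default), RMS-normalized per channel
(default 5 μV); earlobes carry noise but no signal. Artifacts are
Hann-shaped bursts (default 150 μV peak, 0.3 s, Poisson-timed, one
random scalp channel each) whose times are recorded for rejection
tests.

The default simulation rate is **600 Hz**, so a 1.2-s epoch is exactly
720 samples and the tagged rates 2.5 and 1.6667 Hz fall exactly on DFT
bins 3 and 2. Real-data mode (e.g. 512 Hz after decimation) uses the
nearest-bin read-out instead; see below.

One consequence of the paradigm worth knowing: with 1.2-s epochs the
two tagged rates occupy *adjacent* DFT bins (0.833-Hz spacing), and the
Hann window's kernel is 0.5 at ±1 bin, so a strong component leaks into
its neighbor's bin. In simulations with one clean and one heavily
jittered component this visibly couples the two read-outs; it is a
property of the epoch length, not of the estimator.

**FFR.** A Cz-dominant recording at 8 kHz (the 70–3000-Hz band needs
the headroom; the acquisition-rate 16 384 Hz is supported but slower).
Within every stimulus whose F0 matches the analysis F0 (110.88 Hz),
each consecutive 3-cycle window carries a harmonic complex with its own
wrapped-normal phase jitter plus white non-phase-locked noise. By
default components are *envelope-following*: they keep their sign
across the alternating stimulus polarity, as the polarity-collapsed
analysis assumes; `fine_structure=True` makes them flip, which the
tests use to verify antiphase cancellation. Default harmonic amplitudes
put energy only at 2·F0 (221.76 Hz), where the analysis band sits.

**Behavior.** Oddball hits occur with probability `hit_prob` at
latencies Normal(0.5 s, 0.15 s) truncated to (0, 1.25]; false alarms
are a homogeneous Poisson process placed outside the hit windows.
Categorization responses are Bernoulli with
logit = b₀ + b_pitch·p̃ + b_dur·d̃ on the 2-SD-rescaled levels, so
configured weights live on the same scale the fitter reports.

### What the simulator does *not* emulate

No head geometry or volume conduction (topographies are plain gains),
no eye blinks or ICA (artifacts are generic bursts), no cochlear or
brainstem nonlinearity (the FFR is an additive harmonic model), noise
is Gaussian and stationary, and behavioral RTs are a single truncated
normal. Passing tests therefore show that the *estimators* recover
known parameters under realistic SNR, epoch counts and rejection rates
— not that they are robust to every pathology of real recordings.

## Preprocessing

- **Downsampling**: integer-factor decimation with a Chebyshev-I
  order-8 anti-alias IIR prefilter applied forward–backward
  (`scipy.signal.decimate`, the same design as MATLAB's `decimate`),
  single-stage even at q = 32.
- **Re-referencing**: subtract the mean of the earlobe channels.
- **Cortical filters**: zero-phase (forward–backward) Butterworth,
  low-pass 30 Hz order 6 then high-pass 0.5 Hz order 4.
- **FFR filters**: zero-phase Butterworth high-pass 70 Hz and low-pass
  3000 Hz. The orders are not dictated by the analysis description;
  order 4 is used for both as a conventional choice.
- **Epoching**: non-overlapping windows of `round(length·fs)` samples
  from t = 0; the trailing partial epoch is dropped. 1.2 s at 512 Hz is
  614.4 samples, so the realized length (614 samples = 1.19922 s) is
  recorded and tagged frequencies are then read from the nearest bin,
  with the mismatch reported. The 600-Hz synthetic default avoids the
  issue entirely.
- **Rejection**: an epoch is masked (reason `"amplitude"`) when |x|
  exceeds the threshold on any channel — ±100 μV cortical, 35 μV FFR
  (the FFR rule is applied to absolute value, mirroring the cortical
  rule). Rejection is idempotent and masks are kept, never deleted.
- **FFR epoching**: each qualifying stimulus of duration d contributes
  ⌊d/(3/F0)⌋ consecutive 3-cycle epochs starting at stimulus onset
  (70 ms → 2, 175 ms → 6; higher-pitch stimuli contribute none). An
  onset offset for transient exclusion exists as a knob and defaults to
  0, since the analysis description is silent on it. Epochs inherit the
  stimulus polarity; `balance_polarity` then retains min(n₊, n₋)
  artifact-free epochs per polarity, dropping a seeded-random subset of
  the majority.

## Estimators

**ITPC** (`cortical.compute_itpc`): Hann-window each retained epoch,
rfft, normalize each coefficient to unit length, average across epochs,
take the magnitude. Bins where an epoch's coefficient is exactly zero
contribute no vector and the mean is renormalized by the count of
non-zero epochs, which avoids 0/0 while preserving the [0, 1] range.
The window is unit-energy normalized, though any positive scaling is
irrelevant to a phase-only statistic. Channel selection ranks channels
by ITPC averaged over the tagged bins and over all supplied
participants' spectra and returns the top k (default 9); ties break by
montage order via a stable sort, for determinism. Selection should be
given *group* spectra: single-recording rankings at realistic SNR are
noisy, while averaging even a handful of participants recovers the
high-gain cluster reliably.

**FFR band ITPC** uses a rectangular window: the epochs span an integer
number of F0 cycles, so harmonics are bin-aligned and tapering is
unnecessary (windowing is specified only for the cortical analysis).
With 216-sample epochs at 8 kHz the bin spacing is 37.04 Hz and the
200–250-Hz band contains the single bin at 222.2 Hz, adjacent to
2·F0 = 221.76 Hz. (The quantity described as the "first harmonic, 225
Hz" is treated as an approximation of 221.76 Hz; the band covers both.)

**Non-phase-locked amplitude**: subtract the across-epoch mean waveform
from every epoch, average the single-sided residual amplitude spectra
2|X|/n across epochs, then across band bins (100–500 Hz). For white
noise of SD s the expected bin amplitude is s·√(π/n)·√(1−1/N), the last
factor from the ERP subtraction — the tests check this closed form.

**Behavioral scoring**: a response within 1.25 s after an oddball is a
hit for the nearest preceding oddball, each oddball creditable once;
everything else is a false alarm, with the non-oddball stimulus count
as denominator. Overlapping hit windows raise an error (they cannot
occur under the 4.8-s guard). d′ applies the loglinear correction
(+0.5 to both counts, +1 to both denominators). Attention accuracy is
determined solely by the attended dimension, also on both- and
no-repetition trials.

**Cue-weight fitting** is maximum-likelihood logistic regression by
IRLS on the intercept plus 2-SD-rescaled pitch and duration levels
(sample SD, ddof = 1, matching R's `sd`); convergence when the
log-likelihood changes by < 1e−8, at most 100 iterations; weights are
floored at 1e−10 to keep the working matrix invertible. Separation is
flagged when every fitted probability saturates at its observed class
or a coefficient exceeds 30 on the rescaled scale, and the fit is then
marked non-converged. Wald SEs come from the inverse Fisher
information. The group-level mixed-effects layer is deliberately out of
scope: the package exports tidy per-participant tables for external
modeling. Participant-exclusion flags use point-biserial correlations
(Pearson r of the binary response against each level column, two-sided
α = 0.05): any significant negative correlation → `"negative"`,
neither significant → `"none-significant"`, else keep. The choice of
point-biserial is an assumption; the exclusion rule's source does not
name its statistic.

## Orchestration and reproducibility

`pipeline.run_all` fans a single seed out to stage-specific child seeds
(`seed·1000003 + crc32(stage) mod 2³¹`), so stages are independently
reproducible and a fixed seed reproduces every output table
byte-identically. Default problem sizes — two 96-s sequences (80 epochs
each) for the cortical stage, one 96-s FFR run (~900 balanced epochs),
160 categorization trials — keep a full run under a second while
leaving Monte-Carlo error well inside the 3·SE bands the tests use;
the acceptance script uses 320-epoch runs where the closed-form
comparisons need tighter error.

## Known limitations

- Tagged-bin adjacency (Hann leakage between 1.67 and 2.5 Hz read-outs
  at 1.2-s epochs) couples the two dimension indices; real analyses
  inherit the same property.
- The jitter → ITPC closed form exp(−σ²/2) holds exactly only without
  additive noise; with noise the measured ITPC is attenuated further,
  so ground-truth "expected" values are noise-free ceilings, not
  predictions of the noisy measurement.
- The IRLS fitter handles the two-predictor design it is written for;
  it is not a general GLM.
- WAV output is mono float32; EEG persistence uses a NumPy container
  rather than EDF.
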