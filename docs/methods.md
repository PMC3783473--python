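# Methods

This note documents the models behind `spellersim`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic data can and cannot establish.

## Synthetic EEG model

All recordings are `[n_channels × n_samples]` blocks in microvolts at a
configurable sampling rate (1 kHz by default, matching common wireless
amplifiers), with 10–20 channel labels. Two montages are built in:
fronto-central/parietal (Fz, FCz, Cz, CP1, CP2, P3, Pz, P4) for the ERP
speller and occipito-parietal (P3, Pz, P4, PO9, O1, Oz, O2, PO10) for
the flicker speller.

**Background noise** is 1/f ("pink") Gaussian noise, spectrally shaped
in the frequency domain and normalized to the configured sigma
(default 10 µV for ERP sessions, 4 µV for SSVEP sessions). A fraction
of the noise variance (`noise_spatial_correlation`, default 0.6) comes
from three shared pink sources with random fixed channel gains; the
rest is independent per channel. The shared sources emulate volume
conduction, which spreads every cortical generator over the whole
montage. This structure is not cosmetic: the SSVEP decoder's
minimum-energy spatial filter works by cancelling spatially correlated
noise, and with fully independent channel noise its minimum-noise
direction is random with respect to the signal topography, so the
retained component intermittently carries no signal at all. Setting the
correlation to 0 restores a fully independent noise model. An optional
50 Hz sinusoid (random phase per channel) models line interference.

**Oddball/P3 sessions.** Target stimuli add a Gaussian bump of
amplitude `p3_amplitude` (default 5 µV at the spatial-profile maximum,
centro-parietally weighted), peak latency 350 ms, FWHM 100 ms — inside
the 200–500 ms window where the component is expected — with Gaussian
trial-to-trial latency jitter (SD 20 ms) truncated so the bump stays in
the 800 ms epoch. Stimulus order is randomized; the oddball protocol
default is 25 targets among 275 non-targets, 100 ms stimuli, pauses
uniform in 100–300 ms.

**SSVEP trials.** Each channel carries the profile-weighted sum of
sinusoids at the stimulation frequency and its harmonics (defaults
2.0 µV and 0.8 µV for harmonics 1 and 2, occipitally weighted) with
phases drawn per trial. Speller sessions entrain each 10 s level
segment at the frequency of the quadrant on the target symbol's tree
path; non-attended quadrant frequencies contribute nothing (a
gaze-dependent idealization).

The defaults are free parameters of the simulation, not estimates of
any cohort: published patient figures are qualitative, so the values
were chosen once to produce accuracies spanning the chance-to-ceiling
range over the speed settings the protocols use.

What the generator does **not** model: eye-blink/EMG artifacts,
realistic head-volume conduction (the mixing is random, not
anatomical), amplitude drift and fatigue within a session,
non-attended-frequency responses, and attention lapses. Passing tests
therefore establish the correctness of the decoding arithmetic and its
statistical behaviour under the assumed signal model, not clinical
performance.

## P3 decoding pipeline

Band-pass 0.3–15 Hz, 3rd-order Butterworth applied forward-backward
(zero phase, double attenuation); epochs 0–800 ms from each onset;
decimation 1 kHz → 100 Hz by keeping every 10th sample — the 15 Hz
band edge is far below the 50 Hz post-decimation Nyquist, so the
band-pass itself anti-aliases. No baseline correction (the 0.3 Hz
high-pass already removes offsets and drift). Epochs of the same
stimulus code are averaged over the first `repetitions` occurrences;
640-dimensional feature vectors (8 × 80) are z-scored with
calibration-set statistics reapplied unchanged at decode time.

The classifier is an L2-regularized hinge-loss linear model
(scikit-learn `LinearSVC`). The regularization parameter is chosen by
stratified 10-fold cross-validation over a logarithmic grid 2⁻¹⁰…2¹⁰
(21 points), ties resolved toward the stronger regularization; folds
are fixed by a seed. Calibration trains at the same averaging level
used at decode time (one averaged exemplar per stimulus code per
supervised selection, 8 selections by default); this is configurable
because a plausible alternative — many exemplars at lower averaging —
fits the same protocol description. Scores are affine in the features;
argmax ties break toward the lowest stimulus code (probability zero
under continuous noise). Row/column decoding intersects the best row
and best column; single-symbol decoding takes the best symbol.

## SSVEP decoding pipeline

Preprocessing: an 8th-order 100 Hz low-pass precedes decimation to
250 Hz (the nominal chain — downsample, then filter — would otherwise
alias), then a 4th-order zero-phase high-pass above 4 Hz and a 50 Hz
IIR notch (Q = 30, zero phase).

**Minimum energy combination.** The sin/cos pairs of *all four*
candidate frequencies and their harmonics (default 2) are projected out
of the analysis window jointly by least squares, so no candidate's
signal leaks into the noise estimate. The residual covariance is
eigendecomposed; eigenvectors are retained from the smallest eigenvalue
up while their cumulative eigenvalue share stays within 10% of the
total (at least one), each scaled to unit residual-noise energy.

**Scoring.** For each candidate, harmonic and retained component:
signal power is the mean-square amplitude of the least-squares sin/cos
fit to the component; noise power is the local level of the projection
residual around that harmonic. The noise level is measured with the
*same* least-squares estimator at a ring of probe frequencies
±0.35–0.95 Hz around the harmonic, skipping probes that fall within
0.25 Hz of any projected-out candidate harmonic. A periodogram-band
estimator was evaluated first and found biased on short windows:
candidates that do not fall on the periodogram grid of the window
length spread their projection notch across the whole band, and
candidates with close neighbours (6.67/7.5/8.57 Hz are 0.83–1.07 Hz
apart) have notched bins inside their noise band; both effects inflate
some candidates' SNR systematically under pure noise. The probe
estimator shares its equivalent noise bandwidth with the signal
estimator, which removes the grid-alignment bias (winner frequencies
are uniform under white noise). A small residual preference for the
lowest candidate remains under 1/f noise because the 4 Hz high-pass
attenuates the below-target probes slightly more than the target; this
shifts *which* wrong candidate wins under noise but not the chance
accuracy, since the attended quadrant is uniform.

The candidate score is the mean power ratio across harmonics and
components; the highest score wins, ties toward the lowest frequency
index. Harmonics at or above Nyquist are skipped with a warning. Three
decisions descend the selection tree; the redistribution of symbols
over quadrants at levels 2–3 is a fixed row-major split (the quarter of
the current candidate set with the chosen index), an arbitrary but
deterministic convention. One whole-level analysis window is used per
decision; a shorter window can be configured, which the window-length
monotonicity analyses exploit.

## Evaluation and statistics

Bitrate `B(P, M)` uses the conventions `0·log 0 = 0` and `B = 0` for
`P < 1/M`: the raw formula reaches zero exactly at chance but rises
again below it (it would credit systematically wrong selections), so
the whole below-chance region reports zero information. A patient's
global ITR pools every symbol and its stimulation time across sessions
and speed settings of one system. Accuracy-by-speed tables flag
settings with fewer than 3 symbols as low-support. RTLX is the plain
mean of the six subscale ratings, reported to 2 decimals. Questionnaire
ingest rejects out-of-range TLX subscales but only *flags*
out-of-range side fields (satisfaction, quality of life, impairment
scores), because transcription artifacts in source tables should stay
visible rather than be silently corrected. Cohort averages omit
excluded patients while keeping their per-patient rows.

Wilcoxon signed-rank: differences `y − x`, zeros dropped (and counted
in the result), mid-ranks on ties, statistic `W = min(W⁺, W⁻)`. For
n ≤ 15 the two-sided p is exact — the probability over all 2ⁿ sign
assignments that `min(W⁺, W⁻)` is at most the observed value, computed
by dynamic programming over half-rank units; larger n falls back to
the tie-corrected, continuity-corrected normal approximation. All
differences zero reports p = 1.

Spearman correlation is the Pearson correlation of mid-ranks.
Significance is permutation-based: the raw observations of `y` are
permuted (20000 times by default, seeded), two-sided exceedance with
the add-one convention `p = (k + 1)/(n_perm + 1)`. For the partial
coefficient `r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))` on
ranks, `y` is permuted while the (x, z) pairing stays fixed — one
standard reading of permuting a single variable's raw observations;
degenerate denominators (|r| = 1 with the covariate) are reported as
undefined rather than inflated.

## Study orchestration

`run_study` mirrors a two-system usability study: per virtual patient
and system, sessions of freely spelled words (drawn from a packaged
list) with a speed-adaptation policy standing in for the human in the
loop — after a fully correct word the next faster setting is used
(fewer repetitions / shorter levels), after a word with ≥ 50% errors
the next slower one. The repetition ladder is 10/8/6/4/3/2/1; the
level-duration ladder 10/7/5/4/3/2 s. Per-run artifacts are decode
reports (TSV; raw signal files optionally, as float32 `.npy` + JSON
header + events TSV), a metrics bundle and a manifest; identical spec
and seed reproduce the bundle byte for byte. A failing patient run is
logged and skipped without aborting the cohort. All seeds derive from
one master seed through `numpy.random.SeedSequence`.

## Numerical choices and problem sizes

Chance-level checks use 500 selections (the binomial 3-SE band around
1/36 or 1/4); recovery checks use 20-symbol runs at generous SNR and
monotonicity checks decode the *same* recordings at nested repetition
counts (1/3/5/10) or window lengths (2/4/10 s), which removes most
sampling variance from the comparison. Simulated sessions are
generated in chunks of 5–25 symbols to bound memory. The analysis
drivers use a 7-patient cohort with 2 sessions per system and 2 words
per session — small enough to rerun casually, large enough for the
paired tests to be informative.

## Known limitations

- The synthetic signal model is idealized (see above); absolute
  accuracies and ITRs say nothing about patients.
- The MEC retention rule (10% cumulative noise energy) typically keeps
  a single component on this 8-channel montage; multi-component
  behaviour is exercised only with retention set higher.
- The exact Wilcoxon enumeration is quadratic in total rank units and
  intended for cohort-sized n; the normal fallback takes over at n > 15.
- Permutation p-values are Monte-Carlo estimates; with 20000
  permutations their SE near p = 0.05 is about 0.0015.
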