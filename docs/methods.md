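# Methods

## Signal model of the synthetic generator

Each synthetic session emulates a cue-paced two-class motor-imagery (MI)
experiment on a 16-channel 10-20 montage (Fp1…Oz, including Pz, C3, C4)
at 250 Hz. A trial occupies a −2.5…3.5 s epoch around the cue; epochs are
separated by 6 s of rest, matching the pacing of standard Graz-protocol
sessions. Per trial `l` the generator superimposes on 1/f background
noise:

* **Parietal alpha** at Pz: a 10 Hz sinusoid with random phase and
  amplitude `A_l` drawn log-normally (default median 3 µV, σ_log = 0.4),
  present throughout the epoch. Trial-to-trial alpha variance in real
  data is not characterized in the literature this package follows; the
  log-normal form is a modeling choice (amplitudes are positive and
  right-skewed) and its parameters are ordinary configuration.
* **Central mu (10 Hz) and beta (20 Hz)** at C3 and C4 (defaults 2 µV and
  1 µV). During the imagery interval 0.5–2.5 s the contralateral
  channel's amplitude is scaled by `1 − d_l` and the ipsilateral one by
  `1 − 0.3·d_l` (the lateralization fraction gives CSP a contrast to
  learn). The envelope transitions with 0.1 s raised-cosine ramps inside
  the interval so the modulation edge does not splatter broadband energy.
* **ERD depth coupling**:
  `d_l = min_depth + (max_depth − min_depth)·(κ·rank(A_l) + (1−κ)·u_l)`,
  with `rank(A_l)` the alpha amplitude's session rank mapped to (0, 1)
  and `u_l` i.i.d. uniform. Rank (not raw µV) keeps the recoverable
  association scale-free, matching the rank-based statistics downstream.
  κ = 0 disconnects ERD from alpha entirely (the null); κ = 1 makes depth
  a deterministic function of alpha rank. `min_depth` defaults to 0,
  which is the plain mixture; setting `min_depth = max_depth` produces a
  constant-depth session for decoder benchmarks.
* **Artifacts**: with probability 0.02 per trial a 300 µV, 0.2 s
  rectangular excursion is written onto one random channel. It is slow
  enough to survive the 1–40 Hz filter and common-average reference and
  so exercises the ±120 µV rejection rule.

Oscillations are amplitude-modulated sinusoids with per-trial random
phase — deliberately the simplest structure whose band power and ERD the
estimators can measure; no autoregressive spectra, no volume-conduction
forward model, no EOG/EMG morphology, no post-imagery ERS rebound. The
one volume-conduction-like effect that *is* present is referencing leak:
the common average subtracts 1/16 of the Pz alpha from every channel.
Passing tests therefore demonstrate correctness of the estimators and
statistics on data with known structure, not robustness to the full
physiology of real EEG.

### Choice of noise scale and montage

The broadband noise scale defaults to 3.0 µV RMS. It was fixed once, by
simulating sessions at the default coupling (κ = 0.8, max depth 0.7)
across candidate scales and keeping the value whose median session-level
Spearman r (≈ −0.4 to −0.5) matches the range of effect sizes reported
for real MI sessions; that emulation is the generator's purpose. The
16-channel montage likewise mirrors real corpora (22–64 channels): with
very few channels the common average reference leaks the Pz alpha source
into C3/C4 strongly enough to bias even uncoupled sessions slightly
negative, while at 16 channels the κ = 0 null is empirically centered
(type-I fraction ≈ 0.04, uniform p-values).

### Cohort design

For group-level analyses, `generate_cohort` lays participants' alpha
amplitude scales on a log-spaced grid (default 0.6–1.8× the base level)
and raises each participant's maximum ERD depth linearly with the log
scale (default 0.1–0.8). A fixed dose-response-style grid, rather than
random scale draws, guarantees that every cohort spans the whole range:
with only ~20 participants, random draws cluster often enough that the
cohort-level rank correlation between alpha metric and decoding accuracy
fluctuates for reasons that have nothing to do with the pipeline under
test. The seed controls the per-participant session seeds.

## Preprocessing

Zero-phase elliptic band-pass (1–40 Hz), common average reference over
all channels, epoching to −2.5…3.5 s, then rejection of any trial whose
absolute amplitude *strictly exceeds* 120 µV on any channel. All
time-to-sample conversions use `round(t·fs)` with half-open `[start,
end)` windows, so an epoch at 250 Hz has exactly 1500 samples and the cue
falls on sample 625.

The elliptic design is order 5 with 0.05 dB passband ripple and 40 dB
stopband attenuation, applied forward–backward (`sosfiltfilt`). The order
and ripple were chosen against two analytic requirements: the two-pass
passband power droop at 10 Hz through the 8–12 Hz stage stays below 2.5%
(a lower-order or higher-ripple design loses up to 18% of a 10 Hz tone's
power after two passes), and a 50 Hz tone retains < 1% of its amplitude
through the 1–40 Hz stage (a lower order leaves 50 Hz in the transition
band). Heterogeneous sampling rates need no resampling because every
per-trial metric is defined over time windows, not sample counts.

## Features

Pre-cue alpha power ᾱ: the −2.5…0.5 s segment at Pz is band-passed to
8–12 Hz, 0.5 s is trimmed from each end against filter edge effects, and
the mean squared amplitude over −2…0 s is returned (µV²). Relative alpha
divides ᾱ by the 8–40 Hz power of the identical window and channel; the
ratio may exceed 1 by filter leakage and is clipped at 1 (values beyond
1.02 on retained trials raise an error). ERD uses the same edge-trim
logic over the full epoch with an 8–30 Hz band; instantaneous power is
the squared band-passed amplitude — no Hilbert envelope, no smoothing —
and the mean over 0.5–2.5 s summarizes the trial. The contralateral
channel is C3 for right-hand and C4 for left-hand imagery.

## Decoding

CSP is fitted per class on trace-normalized spatial covariances of the
band-passed (8–30 Hz) imagery window, by whitening on the principal
subspace of the composite covariance and diagonalizing the whitened
class-1 covariance. The composite is singular by construction after
common-average referencing; directions with numerically zero composite
variance are excluded rather than ridge-regularized, because a
regularized null direction otherwise surfaces as a spurious
"discriminative" component at one end of the eigenvalue spectrum. Six
filters (three per end) feed log-variance features into a pooled-
covariance LDA (scikit-learn's SVD solver, tolerant of collinear
features). Cross-validation is a single seeded, class-stratified 10-fold
split; CSP and LDA are refit inside every fold — the only leakage-free
reading of fold-wise accuracy — and each fold also records the median
relative alpha of its training trials, whose across-fold mean is the
participant-level alpha metric.

## Statistics

Spearman correlations use midranks; p-values come from the t
approximation, replaced by exhaustive permutation for n ≤ 9. The
Mann–Whitney U test enumerates exactly for pooled n ≤ 16 without ties and
otherwise uses the tie-corrected normal approximation. The median split
assigns trials exactly at the median to the lower group (a fixed,
documented tie rule). Shapiro–Wilk is available as a gate/report; the
inferential chain is nonparametric regardless of its outcome. FDR control
is the Benjamini–Hochberg step-up rule; session-level tests are corrected
within one family per hand condition (configurable — the choice of family
is genuinely open), and channel-wise localization is corrected across
channels within participant. All tests are two-sided. Pooled
(hand-agnostic) session analysis is available for designs whose sessions
mix both classes in one report.

For participant-level aggregation, each participant contributes the
across-session average of per-session medians (alpha and ERD), keeping
observations independent. The alpha-vs-accuracy association reports both
Spearman r/p and the R² of a least-squares line of accuracy on the alpha
metric; the R² is purely descriptive and is not a rank-based quantity.

## Problem sizes and determinism

Default validation runs use 40–120 trials per class per session, 100
sessions for null calibration, 20 sessions for coupling recovery and 20
participants for the cohort mechanism chain — large enough for the
statistics to stabilize while a full suite plus the acceptance script
completes in a few minutes on one core. Every stochastic step takes an
explicit seed; a fixed configuration reproduces output files byte for
byte.

## Known limitations

* No forward model: channel correlations arise only from the common
  average reference, so spatial patterns are far cleaner than in real
  EEG; CSP results on this data are an upper bound on separability at a
  given ERD depth.
* Alpha and mu are both 10 Hz sinusoids; spectral shape differences
  between parietal alpha and central mu are not modeled.
* The artifact model is a single rectangular excursion class; graded or
  muscle-band artifacts are out of scope.
* The ERS rebound after imagery offset is not simulated, so the 0.5–2.5 s
  analysis window cannot be invalidated by rebound contamination — a
  failure mode real data do have.
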