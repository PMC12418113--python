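# Methods

## The analysis problem

During virtual navigation, feedback onset is followed by a burst of
right-posterior theta (4–12 Hz) power peaking roughly 200 ms after the
stimulus. Two generative accounts are classically distinguished: a
**partial phase reset** — the ongoing oscillation keeps (most of) its
amplitude but its phase is realigned to a preferred angle — and an
**additive evoked response** — a fixed-latency, fixed-phase transient
superimposed on an undisturbed background. A partial reset predicts
*concomitant* increases in inter-trial phase coherence and in spectral
power relative to baseline, plus a collapse in the spread of single-trial
phase angles. The package implements the full measurement chain for this
question and a second, fusion stage that couples single-trial theta power
to single-trial BOLD amplitude estimates from medial-temporal regions of
interest through a random-intercept mixed model.

## Synthetic generator

`simulate_epoch_set` draws, per trial: a log-normal amplitude (median 1,
sigma 0.2), a carrier frequency `N(8 Hz, 0.5 Hz)`, a uniform initial
phase, and (for the reset mechanism) a post-event phase from a von Mises
distribution with configurable concentration kappa and target angle
(default 180°, matching the circular grand means reported for this
paradigm). Mechanisms:

- **reset** — at the event-to-reset latency the carrier's phase is
  replaced by the von Mises draw. The discontinuity is smoothed with a
  raised-cosine crossfade over one carrier cycle to avoid broadband
  splatter. An optional transient gain (alpha-function envelope,
  `1 + (g−1)·(Δt/τ)·e^{1−Δt/τ}`, τ = 150 ms) models the power increase;
  with `g = 1` the reset is amplitude-neutral — the defining dissociation
  from the additive account.
- **additive** — a fixed-phase, alpha-enveloped damped burst is added to
  the untouched ongoing oscillation.
- **none** — the null mechanism.

Condition structure follows the navigation paradigm: conditions
maze/no-maze, alleys left/right, random reward valence. Alley effects
(reset latency: left 196 ms / right 180 ms; transient gain: left 1.4 /
right 1.55, chosen to land near the printed baseline-relative peak powers
of ≈1.0 and ≈1.24) are applied to the `right_posterior` channel only;
`left_posterior` receives alley-averaged parameters, emulating the
hemispheric asymmetry of the effect. Noise is 1/f (spectrally shaped,
unit-variance, scaled by 1.0 relative to the unit carrier) plus white
noise (0.3). The per-trial frequency jitter makes post-reset coherence
decay, which is what gives the ITC time course a well-defined peak; the
generator would otherwise hold perfect coherence forever, which no real
oscillation does.

What the generator does **not** emulate: volume conduction and channel
covariance, non-stationary background spectra, artifacts (ocular,
cardiac, gradient), bursty/asymmetric oscillation waveforms, and any
behavioural structure. Passing tests therefore certify the estimators'
operating characteristics under a clean oscillatory model, not their
robustness to real-recording pathology.

The BOLD stage (`simulate_coupled_bold`) generates single-trial
amplitudes `y_ij = β₀ + S0_i + Σ_k b_k·P_ijk·[maze] + ε_ij` with subject
intercepts `N(0, 0.5²)` and noise `N(0, 0.85²)`; the default coupling
weights are +0.148 for 7–8 Hz and −0.097 for 5–6 Hz — the standardized
estimates this analysis chain is expected to recover — and coupling is
zero in the no-maze condition. Optionally the amplitudes are rendered as
a TR-gridded BOLD series (events every 3–5 s, 1 s duration, TR 2 s,
canonical HRF), so the LSS stage can be exercised end to end.
`simulate_band_power_table` draws band-power tables directly (single
latent factor, pairwise r ≈ 0.3 — the mild-multicollinearity regime)
for coupling simulations where waveform synthesis adds nothing.

## Time–frequency analysis

Complex Morlet wavelets, 1–50 Hz in 1 Hz steps, seven cycles for the
power analysis. Wavelets are **amplitude-calibrated** (unit response to a
unit sinusoid at the centre frequency) rather than unit-energy: this
makes squared magnitude read directly as squared signal amplitude at
every frequency and lets spectral magnitudes be checked against an FFT
oracle; any consistent normalisation cancels in the ratio baseline.
Epochs (±2500 ms) are transformed full-length and trimmed to
−500..+1000 ms so edge effects fall outside the analysis span;
frequencies whose half-support still reaches the epoch edge are flagged.

Total power is the trial average of single-trial power; evoked power is
the power of the trial-averaged ERP; induced = total − evoked
(non-negative by construction, since the transform is linear and
|mean z|² ≤ mean |z|²). Baseline normalisation is relative change
against the −200..−100 ms pre-stimulus mean, per frequency.

Peak detection: the subject's peak frequency is identified from raw
total power in 4–12 Hz, then the peak of *evoked* baseline-relative
power at that frequency is located in the search window (0–600 ms
default, 50–350 ms preset for the constrained design), ties breaking to
the earliest latency then lowest frequency. Evoked power is used for
latency work because the ERP-based time course has far higher
signal-to-noise than total power, whose argmax on a broad plateau is
unstable.

Single-trial band power (regressor stage): per-trial power, expressed as
relative change against the across-trial mean baseline per frequency
(shared baseline, so between-trial variance is preserved), averaged over
band × 50–250 ms. Bands: 1–4, 5–6, 7–8, 9–10, 11–12 Hz.

## Coherence and phase

ITC is the magnitude of the trial-averaged unit phase vector. Band ITC
averages per-bin ITC across the band's 1 Hz bins (a complex-average
variant is exposed). The coherence/phase spectrogram uses **3-cycle**
wavelets (the convention of the EEGLAB-style coherence analysis this
mirrors), which roughly halves the temporal smearing of the ITC peak
relative to the 7-cycle power analysis; `itc_n_cycles` exposes the
choice.

Phase samples are the per-trial circular mean over a band × 10 ms window.
The partial-reset verdict samples phases at the **measured ITC peak
latency** — the procedure used on real data, where the sampling latency
is the observed peak timing of the effect — with the mirrored negative
latency as the pre-event control. Sampling instead at the generative
reset time would be contaminated by pre-reset phases through the wavelet
support; this is a measurement-physics fact, not an implementation
artifact, and it is also why the *absolute* ITC peak latency sits
~100–150 ms after the underlying reset time. All latency claims are
therefore condition *differences*, which the estimator recovers without
bias (a configured 16 ms offset is recovered at 15.9 ± 2 ms over 40
seeded 200-trial runs).

The composite verdict is `partial_reset` when all three criteria pass:
RVL(post) − RVL(pre) > 0.2, peak band ITC > 0.3, and baseline-relative
band power at peak > 0.2; `indeterminate` when exactly two pass, and
`additive_or_none` otherwise. The thresholds are not taken from any
publication; they were calibrated once on the generator to a ≤5%
false-positive rate under the null mechanism at 200 trials and are all
configurable.

## Circular statistics

Descriptives are the circular grand mean and mean resultant length
(`rvl(n=1) = 1` exactly; antipodal cancellation gives RVL 0 and an
undefined mean). The Watson–Williams one-factor test uses the
concentration-corrected F statistic with `K = 1 + 3/(8κ̂)`; a warning is
attached when κ̂ < 1. The Harrison–Kanji two-factor test decomposes
resultant lengths over rows, columns and cells; for κ̂ > 2 each effect is
an F test against the residual term with the same correction, and for
diffuse data a chi-squared approximation with scale `2/(1−ρ²)` and
`2·(levels−1)` degrees of freedom per effect (each resultant carries a
cosine and a sine component). Both branches hold their nominal 5% level
within simulation error (type-I rates 0.04–0.06 at 1000–2000
repetitions). Degrees-conversion happens only at I/O; all internal math
is in radians.

## fMRI coupling

The canonical HRF is the SPM-style double-gamma (peak ≈ 5 s, undershoot,
32 s support) with its temporal derivative, sampled on the TR grid via
nilearn. High-pass filtering is implemented as discrete-cosine drift
regressors with a 128 s cutoff inside each GLM.

LSS fits one GLM per trial: the trial's own HRF-convolved regressor, one
regressor for all other trials combined, drift terms, and an intercept
(temporal derivatives included by default; the LSA comparison runs
without them because a per-trial-derivative LSA design is rank-deficient
at 96 trials on ~225 scans). Rank-deficient trial designs yield NaN with
a flag. With isolated, grid-aligned events recovery is exact to machine
precision. At the study-like regime — 3–5 s ISIs, 96 trials, TR 2 s,
white noise with SD equal to the clean task-series SD ("SNR 1") — the
recovery correlation is ≈ 0.72, clearly above the least-squares-all
reference (≈ 0.47). The ceiling at this ISI is ≈ 0.83 even without
noise, because the combined other-trials regressor assumes homogeneous
amplitudes; with mean-zero, fully heterogeneous beta-scale amplitudes
that approximation bias is irreducible, consistent with published LSS
simulations at short ISIs.

The coupling model `y_ij = β₀ + S0_i + Σ_k β_k P_ijk + ε_ij` is fit by
maximum likelihood (so nested comparisons remain valid) on
grand-standardized variables — the fixed effects on that scale *are* the
standardized betas. Regressors are mean-centred within subject (between-
subject power offsets belong to the random intercept, not the slopes).
t statistics use a residual-degrees-of-freedom reference (the
conservative fallback; the Satterthwaite approximation is not available
in the backend). p-values are Benjamini–Hochberg-corrected across the
five bands of each model. When the optimizer lands on the zero-variance
boundary the fit is redone with a simplex method (the quasi-Newton path
mis-profiles fixed effects there); a fully degenerate fit (e.g.
noise-free input) falls back to pooled OLS and is flagged, never silent.
With the variance pinned at zero the mixed model reproduces pooled OLS
to 1e-8, and at the study scale (25 subjects × 96 trials × 200
repetitions) the default-truth weights are recovered with mean absolute
error < 0.02 and 100% sign agreement, while no-maze models stay null.

## Group statistics

Wilcoxon signed-rank: zeros dropped before ranking (Wilcoxon's rule),
exact null distribution up to 25 untied pairs (verified against full
2ⁿ sign enumeration), normal approximation with continuity correction
beyond; rank-biserial correlation as effect size. The 2×2
within-subject ANOVA is computed from per-subject contrasts (for a 2×2
design each effect's F(1, n−1) is the squared contrast t), which handles
zero-variance cells deterministically; it agrees with an independent
implementation (pingouin) to 1e-6 on random data. Shapiro–Wilk and
Levene checks are emitted as advisory diagnostics, never as gates.
Bonferroni–Holm is used for post-hoc families.

## Problem sizes

Simulation experiments run at: 200 seeded runs × 200 trials for
detection operating characteristics; 16 runs × 400 trials for latency
recovery; 100 repetitions for LSS; 200 repetitions at 25 × 96 for the
coupling model; 1000–2000 repetitions for test calibrations; 10,000
draws for the circular-statistics oracles. The default end-to-end
pipeline configuration (8 subjects × 64 trials) completes in a few
seconds and is meant as a worked example, not a power analysis.

## Known limitations

- The generator's constant-frequency sinusoid makes "phase" exactly
  well-defined; real theta is nonsinusoidal and bursty, so measured
  RVL/ITC levels on real data will differ from the clean-model values.
- The reset verdict is a thresholded description, not a hypothesis test;
  its thresholds are calibrated to this generator's noise conditions.
- Absolute peak latencies include the estimator's smoothing delay; only
  latency differences are interpretable.
- LSS inherits the homogeneous-others approximation; at ISIs ≲ 4 s,
  correlations with ground truth above ~0.8 should not be expected.
- The mixed model fits a random intercept only (per the target design);
  random slopes for band power are out of scope.
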