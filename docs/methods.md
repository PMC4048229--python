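# Methods

This note documents the models, defaults and design choices behind the
package, and what the synthetic-data validation does and does not show.

## Recording model and amplitude units

The monitor records mono audio at 8 kHz with 8-bit linear PCM resolution;
opening the inhaler starts the recording and a real-time clock stamps it.
Amplitudes are expressed in arbitrary units (AU) defined as the fraction
of digital full scale (8-bit code / 127). This makes the weak-inhalation
threshold of 0.016 AU concrete and portable: it is ~2 quantization steps,
i.e. ≈ −36 dBFS. Files are standard RIFF/WAV; the timestamp and
subject/device identity live in a JSON sidecar so the WAV remains readable
everywhere. 8-bit encoding is linear (not µ-law) — the simplest verifiable
choice. Other sample rates are accepted and polyphase-resampled to the
device rate on request.

## Synthetic signal model

* **Blister click**: a Hann-windowed ~1 kHz burst (10 ms) immediately
  followed by a Hann-windowed ~2 kHz burst (default 25 ms, configurable
  within 20–30 ms), with mild low-frequency amplitude modulation. The
  precursor length is our choice; only the total click duration is
  constrained by the signature.
* **Inhalation**: Gaussian noise band-limited to 300–2500 Hz under a
  slow-attack envelope (raised-cosine rise to a peak at 40 % of the
  duration, floor 0.35 of peak so onset/offset stay audible). The segment
  is rescaled so its median absolute amplitude is *exactly* the inverse of
  the amplitude→flow calibration at the requested flow; zero flow yields
  silence.
* **Exhalation**: a sharp attack (raised-cosine rise within the first 6 %)
  followed by exponential decay, on a carrier whose instantaneous
  frequency falls exponentially from 2 kHz toward 500 Hz. Its "effort" is
  defined as event energy in dB above the recording noise floor, which is
  also the reference level this package adopts for the 1 dB dispersal
  threshold.
* **Noise**: white Gaussian at a configurable floor, default −50 dBFS,
  then the 8-bit quantizer. We chose −50 dBFS rather than a higher floor
  because the method must *measure* median amplitudes near 0.016 AU
  (−36 dBFS); a floor at −40 dBFS would dominate that statistic and make
  the amplitude–flow calibration unusable, while the 8-bit quantization
  floor (≈ −53 dBFS) bounds the realistic minimum. The generator does not
  model room reverberation, speech/cough interference, or real turbulence
  spectra — only the qualitative signatures above — so detector metrics on
  synthetic corpora are an upper bound on real-world performance.

## Event detection

Short-time analysis uses 25 ms Hann frames with a 10 ms hop. Frame energy
is summed over 200–3200 Hz; the noise floor is estimated as the 20th
percentile of frame energy, which makes segmentation invariant to global
gain. Hysteresis opens an event at floor + 12 dB and extends it while
energy stays above floor + 6 dB; gaps < 50 ms are merged; events < 15 ms
dropped. Boundaries are then refined to ~1 ms using a 5 ms RMS envelope
crossing of the exit threshold (needed because frame-level boundaries are
only hop-accurate).

Classification features per event: median and peak absolute amplitude,
energy in dB re full scale, spectral peak (Hann-windowed FFT, ≥ 1024
points), attack ratio (fraction of the duration to the RMS-envelope peak),
and spectral decay (shift of the 400–2500 Hz band-power centroid from the
first to the last third; negative = downward migration).

* **Blister**: duration within 15–50 ms, spectral peak in 1600–2600 Hz,
  and (by default) more ~1 kHz than ~2 kHz power in the opening 12 ms
  (the lever precursor). The upper duration bound is 50 ms, not 30 ms,
  because segmentation merges the contiguous precursor with the click
  into one ~35 ms event.
* **Breaths** (≥ 200 ms): exhalation iff the attack is fast
  (attack ratio < 0.25) *and* the centroid falls by more than 400 Hz;
  inhalation iff neither; on disagreement the spectral behaviour decides,
  as the primary discriminator. Shorter events stay `unknown`.

## Technique rules

Rules run in fixed priority — structural errors (priming/dose count)
before breath-direction errors before amplitude errors — so co-occurring
problems resolve deterministically; the input event order never matters.
Two readings were genuinely open: (a) "double priming" means two blister
clicks with *no* inhalation between (otherwise the canonical double-dose
sequence would be unreachable); (b) a double dose within one recording is
the primary pattern, with a configurable 2-minute cross-recording window.
The weak-inhalation comparison is strict (`< 0.016 AU`): an inhalation at
exactly the boundary is adequate. Non-critical checklist steps never
produce error labels. The logistic dispersal model (50 % at 1 dB effort,
steepness 1.5 dB⁻¹) is used for reporting estimated dose loss only; the
error label follows the categorical any-exhalation-after-priming rule.

## Adherence statistics

The weekly rate is the OLS slope (equivalently r·s_y/s_x) of cumulative
credited doses on day index 1…7. Regressing on the day index — rather than
on cumulative prescribed doses — is what makes perfect twice-daily
adherence a slope of 2; the alternative reading would give 1 for any
prescription. An all-zero week has undefined correlation and is defined as
slope 0. Weeks are consecutive 7-day blocks from the first recording date
(calendar-aligned; a rolling alternative was not adopted); trailing
partial weeks are excluded. Daily temporal credit is capped at the
prescription so excess use cannot inflate adherence (excess is reported
separately); combined credit counts only technique-correct doses, which
guarantees combined ≤ temporal week by week. A double-dose event credits
zero in the combined domain, like every critical error.

## Outcome statistics

Bland–Altman bias and 1.96·SD limits of agreement (SD with n−1), with
Pearson's r reported absent when undefined. Cohen's κ uses
marginal-product expected agreement; the degenerate both-raters-constant-
and-identical case is defined as κ = 1. AQLQ improvers are subjects with
ΔAQLQ ≥ 0.5 (inclusive MCID); PEFR improvers default to any positive
change, config-exposed. The "ANCOVA" comparison is a normal-theory linear
model of weekly rate on week, group and week × group, fitted on
subject-week observations (duplicates averaged within subject-week);
the interaction p-value tests slope equality. Subject-level random effects
are not modelled — a deliberate simplification; the null calibration test
(type-I error 3–7 % at α = 0.05 over 500 simulations) shows it is adequate
for independently generated subjects, but correlated real-world
trajectories would need a mixed model.

## Cohort generator

Defaults emulate a 51-subject, 12-week, twice-daily cohort: per-subject
dose-taking probability Beta(8.9, 1.1) (mean 0.89, matching an
~89 % average adherence), critical-error probability 0.10 per taken dose
with exhalation-after-priming as the dominant error type, dosing slots at
08:00/20:00 with ±90 min uniform jitter. Outcome changes are linear in the
subject's mean combined weekly slope expressed as a fraction of perfect
adherence: ΔAQLQ = 0.7·(slope/2) + N(0, 0.3) and
ΔPEFR = 25·(slope/2) + N(0, 15) L/min by default; AQLQ baselines are drawn
in 2.6–5.2 so ends remain within the instrument's 1–7 range, PEFR
baselines in 250–550 L/min. The linkage is deliberately the simplest
monotone structure; it supports parameter-recovery testing (the planted
coefficient is recovered within ±10 % at n = 200 over 20 seeds) but does
not claim to model real dose–response.

## Determinism, problem sizes and numerical choices

Every random draw flows from an explicit integer seed through
`numpy.random.default_rng`; recordings, logs, cohorts and the whole
pipeline are bit-reproducible per seed, and report CSVs are byte-identical
across reruns. Validation corpora use 100 recordings per scenario preset
plus 100 noise-only recordings (500 total, ~5–8 s to score); the ANCOVA
null calibration uses 500 simulations of 10 subjects/group × 8 weeks; the
power check uses 25 subjects/group × 12 weeks with noise SD 0.3. Log-power
computations are guarded with a 1e-20 floor; empty logs require an
explicit observation window; degenerate fits (zero residual variance,
all-zero calibration amplitudes, fewer than 3 agreement pairs) raise or
are defined explicitly as documented above.

## Known limitations

* Synthetic audio validates the *pipeline*, not field performance:
  real recordings add reverberation, speech, coughs and device variation
  that the generator does not emulate.
* The amplitude→flow calibration is a single-gain line through the origin;
  real devices would be calibrated per hardware batch from measured pairs
  (`fit_calibration`).
* Cross-recording double-dose detection uses timestamps only.
* The group-trend model treats subject-weeks as independent observations.
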