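# Methods

This note records how each component is modeled, which parameters matter,
and where genuinely open design choices were resolved.

## Spectral engine

All filtering is short-time Fourier processing: Hann windows of 4096
samples at the 44.1 kHz reference rate (~93 ms; the window length scales
with the sample rate and is kept even), 75 % overlap, and overlap-add
reconstruction. At 44.1 kHz the bin spacing is ~10.8 Hz, which resolves a
½-octave notch at the 1 kHz bottom of the admissible tinnitus range with
ample margin. Both channels of stereo input pass through the identical code
path with identical masks, so identical channels stay bit-identical.

### Notch + edge mask

The mask is defined on the log-frequency axis. With tinnitus frequency
*f*ₜ and defaults (notch ½ oct, edges 3/8 oct, +20 dB):

- stop band [*f*ₜ·2^(−1/4), *f*ₜ·2^(+1/4)]: linear gain 0 — total removal.
  "Removed" is interpreted as full bin cancellation; the measured floor on a
  probe is then limited only by window leakage (≈ −90 dB).
- edge bands 3/8 oct on each side: gain 10 (+20 dB).
- elsewhere: gain 1.

Transitions between these levels are raised cosines of 1/48 octave,
centered on each band boundary, interpolating the *linear* gain (dB
interpolation is undefined through the zero-gain stop band). The narrow
transition keeps ringing low while shifting the measured −6 dB width by
well under the 0.05-octave verification tolerance. A spec whose upper edge
band (plus transition) would exceed Nyquist is rejected outright rather
than truncated.

### Equalization

Only the intent of equalization is fixed — equal spectral power below and
above the notch — so the algorithm is this package's choice: measure the
long-term average spectrum (LTAS) in 1/3-octave bands over 100 Hz–16 kHz
(Welch periodograms, channel-averaged, *band-integrated* energy per band —
under this convention white noise rises ~3 dB/octave and pink noise is
flat), pull every band toward the energy-weighted mean level with gains
clamped to ±24 dB, interpolate the gain curve linearly in log-frequency
(tapering to 0 dB one band outside the analysis range), and apply it as a
single static mask per track. With `preserve_energy` (default) the output
is rescaled to the input RMS, making the step a pure redistribution of
energy. A fixed point: input that is already flat per band passes through
within a fraction of a dB.

### Placebo walk

The placebo applies the same equalization and the same edge enhancement as
the treatment, moving with its notch; the two conditions differ only in
notch-center dynamics. This is the blinding-friendly reading of "same
bandwidth" and is the package's choice where the protocol is silent.
Borders for the walk are likewise unstated in the protocol; they default to
1–16 kHz, matching the pitch-matching range, with the constraint applied to
the notch band's edges. The initial center is uniform in log₂ over the
admissible range. The dwell clock advances per STFT hop (~23 ms), so jumps
are quantized to block boundaries; at each jump the outgoing and incoming
masks are blended 50/50 for one hop to avoid clicks. A step that would push
a band edge past a border is replaced by a step in the reversed direction
(reflect-before-move), which guarantees the band never leaves the borders.
The first step's direction is drawn uniformly; all randomness flows from a
single seeded generator, so (signal, parameters, seed) determines the
output and trace exactly.

## Pitch matching

"Equally large" subintervals are read on the logarithmic axis — bisection
at the geometric mean — consistent with the Cent-domain averaging of the
final estimates. Each round runs two 2-IFC comparisons (low subinterval,
high subinterval); the four response patterns map to the low subinterval,
the high subinterval, or the middle interval bounded by the two subinterval
midpoints. The contradictory pattern (closer to the extremes on both sides)
has no specified handling; the round is repeated once, then the middle
interval is taken. Termination is likewise unspecified: the session stops
when the interval is ≤ 1/12 octave wide or after 12 rounds (from the 4-octave
range, 6 rounds suffice), and the match is the final interval's geometric
midpoint. The octave-confusion check is run downward only (match vs
match/2), the dominant confusion direction, and only when the lower tone is
presentable (≥ the 1 kHz range bottom — this also keeps every reported
match inside the range). Cents use a fixed 1000 Hz reference; the reference
cancels in aggregation, whose retransformed mean is the geometric mean of
the session frequencies.

Simulated listeners judge by log-distance to their true pitch with Gaussian
noise (default 50 cents) on each comparison and a 2 % lapse rate — enough
structure for parameter-recovery and oracle tests; loudness matching is
reduced to a stored scalar per session.

## Trial design

Screening enforces: chronicity ≥ 3 months, tinnitus pitch 1–12 kHz,
hearing loss ≤ 70 dB in the ±½-octave band around the pitch, age 18–70,
and clear exclusion flags; every failed criterion is reported. Strata are
age × hearing loss with 51 years and 40 dB belonging to the upper classes.
Randomization runs an independent permuted-block stream per stratum
(block size 4, 1:1), with a dedicated child generator per stratum so
allocation in one stratum never perturbs another; any completed block is
exactly 2:2 and any prefix is within ±2 per stratum.

Power for the Session×Group interaction uses the noncentral F convention of
within-between repeated-measures designs: df₁ = (k−1)(m−1)ε,
df₂ = (N−k)(m−1)ε, λ = N·f²·m·ε/(1−ρ). The sample-size search returns the
smallest N that is a multiple of k with power ≥ target (88 at f = 0.25,
α = .05, power .90, k = m = 2, ρ = 0; the trial's inflation to 100 for
dropouts is an enrolment decision exposed in the CLI, not computed). With
m = 2 the interaction test is algebraically the squared two-sample t on
per-subject change scores, which is how the Monte-Carlo cross-check in the
test suite simulates it (3000–5000 replicates; agreement within ±0.02).

## Outcomes

The VAS total is the plain mean of the four subscales and is never imputed:
a missing subscale raises. Change scores are to−from per participant;
participants missing either session are excluded from the per-protocol set
and counted. Morris's effect size divides the difference in mean changes by
the pooled *pretest* SD; because the exact variant behind published d
values of this design family varies, the Hedges-style small-sample factor
1 − 3/(4(n₁+n₂−2)−1) is reported alongside rather than silently applied.
MCID comparisons are strict (>) for VAS — a change must exceed 10 points —
and inclusive (≥) for TQ/THQ/THI, whose sources state point thresholds
without strictness. Harms percentages use the harms-questionnaire
respondents as denominator, at one decimal from full-precision values. The
interim check is a Welch two-sample test on post−pre changes, gated on the
treatment arm's mean change pointing in the harmful direction — a
change-score proxy for the protocol's interaction criterion, chosen because
full mixed-model machinery is out of scope here.

## Synthetic fixtures

The music surrogate is spectrally tilted Gaussian noise (default −3 dB per
octave per Hz) plus amplitude-modulated harmonic tones — it reproduces the
one property the processing chain cares about, unequal energy across
octaves, and none of music's temporal or perceptual structure. Passing
audio tests therefore demonstrate filter geometry and energy bookkeeping,
not perceptual quality on real recordings. Cohorts draw age from a
truncated normal (47.5 ± 10.8 y on 18–70), hearing loss uniform on
0–70 dB, tinnitus pitch log-normal around 5.4 kHz (500-cent SD, truncated
to 1–12 kHz), and chronicity ≥ 3 months, so every generated participant is
eligible by construction. Outcome scores start from per-measure baseline
distributions typical of a moderately distressed cohort; injected arm
effects are added to change scores directly (not to latent trajectories),
which makes parameter recovery exactly checkable; dropouts (default 17 %)
go missing after the pre session. Everything is reproducible from
(model, seed).

## Problem sizes and numerics

Verification probes are 8–30 s of seeded flat noise (30 s for geometry
measurements, 60 s for the placebo walk — a dozen jumps); recovery studies
use 200 simulated listeners × 10 sessions; Monte-Carlo power uses 5000
replicates at N = 88. Welch averaging over these durations holds gain
measurements within ±0.1 dB. Degenerate inputs are explicit errors, never
silent: silent audio flags floor levels, zero pooled SDs and empty session
lists raise, and WAV parsing failures surface as parse errors.

## Known limitations

Real-time mobile processing, perceptual loudness handling, and music
ingestion are out of scope. The equalizer is static per track; strongly
nonstationary audio would need time-varying gains. Mixed-effects models,
repeated-measures ANOVA with sphericity corrections, and latent-change SEM
are deliberately not implemented — they are routine statistics on
participant data that does not exist here. WAV output covers float32 and
PCM16 (PCM24 is read but written as float32).
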