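# notchkit

Tools for **tailor-made notched music training (TMNMT)**, a sound therapy
for tonal tinnitus, and for the clinical-trial machinery around it.

TMNMT rests on lateral inhibition: removing a frequency band around a
listener's tinnitus frequency from music deprives the neurons coding that
band of input while their neighbors — further excited by amplified notch
edges — inhibit them. `notchkit` implements the full apparatus a trial of
this therapy needs, runnable end to end on synthetic audio and simulated
listeners:

- **Treatment audio chain** — equalize the music's long-term spectrum, remove
  a ½-octave band centered at the tinnitus frequency *f*ₜ (stop band
  [*f*ₜ·2^(−1/4), *f*ₜ·2^(+1/4)]), and amplify the flanking 3/8-octave edge
  bands by +20 dB. STFT processing: ~93 ms Hann windows, 75 % overlap,
  overlap-add.
- **Placebo chain** — a notch of identical bandwidth whose center jumps
  ±1/18 octave every 5 s, reversing direction at predefined borders
  (1–16 kHz), with a per-block trace of the walk.
- **Pitch matching** — the recursive two-interval forced-choice (2-IFC)
  procedure on the 1–16 kHz range with log-axis bisection, an octave-confusion
  check, and Cent-domain aggregation over repeated sessions
  (mean_Hz = ref·2^(mean_cents/1200), i.e. the geometric mean).
- **Trial design** — eligibility screening, the four age (< 51 / ≥ 51 y) ×
  hearing-loss (< 40 / ≥ 40 dB) strata, 1:1 permuted-block randomization
  (block size 4), and the repeated-measures within-between interaction power
  analysis: power = P(F′(df₁, df₂, λ) > F_crit) with df₁ = (k−1)(m−1)ε,
  df₂ = (N−k)(m−1)ε, λ = N·f²·m·ε/(1−ρ).
- **Outcomes** — VAS composite (mean of loudness, annoyance, awareness,
  handicap), post−pre change scores, Morris's pretest-pooled effect size
  d = (Δ̄ₜ − Δ̄c)/SD_pre,pooled, MCID flags (TQ 5, THQ 21, THI 7, VAS > 10
  points), planned dose, harms tabulation, and a harm-gated interim check.
- **Synthetic fixtures** — music-like audio (tilted noise + AM harmonic
  tones), verification probes, and two-arm cohorts with injectable effects.

## Worked example

```bash
python examples/notch_a_track.py
```

```
music surrogate: 10 s at 44100 Hz, RMS 0.250 -> treated RMS 0.610
measured -6 dB stop band: 3391-4716 Hz (0.476 octaves; design: 0.5)
lower edge band 2594-3364 Hz: mean gain +20.00 dB (design: +20 dB)
upper edge band 4757-6169 Hz: mean gain +20.00 dB (design: +20 dB)
stop-band floor: -90 dB (energy at the tinnitus frequency is effectively removed)
```

The filter realized by the STFT chain matches its design: the −6 dB stop
band spans half an octave around 4 kHz, both edge bands sit at +20 dB, and
energy inside the notch is ~90 dB down — effectively removed. Other
examples cover the placebo walk (`placebo_walk.py`), a simulated
pitch-matching week (`pitch_match_listener.py`), sample size and
randomization (`design_the_trial.py`), and outcome arithmetic on a
simulated cohort (`trial_outcomes.py`).

A thin CLI wraps the same library:

```bash
notchkit power --f 0.25 --alpha 0.05 --power 0.90 --groups 2 --measurements 2 --corr 0
# {"total_n": 88, "achieved_power": 0.9065}
notchkit target --in music.wav --out notched.wav --tinnitus-hz 5406
notchkit placebo --in music.wav --out placebo.wav --seed 7 --trace trace.csv
notchkit pitchmatch simulate --true-hz 5406 --noise-cents 50 --sessions 10 --seed 7
```

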