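"""Synthetic fixtures: music-like audio, probe signals, and trial cohorts.

No participant-level data from the trial exists, so every input the other
modules need is generated here: a music surrogate (spectrally tilted noise
plus amplitude-modulated harmonic tones — real music carries unequal energy
across octaves, which is what the equalizer must correct), flat probes for
filter verification, and two-arm cohorts with controllable injected
treatment effects for the outcome arithmetic.

Everything is reproducible from (model, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio_engine import AudioBuffer
from .outcomes import SESSIONS, VAS_SUBSCALES, OutcomeRecord
from .trial_design import Participant

__all__ = [
    "MusicModel",
    "CohortModel",
    "make_music",
    "make_probe",
    "make_listener_pool",
    "make_cohort",
]


@dataclass(frozen=True)
class MusicModel:
    """Parameters of the music surrogate."""

    spectral_tilt_db_per_octave: float = -3.0
    n_harmonic_tones: int = 8
    tone_freq_range: tuple[float, float] = (200.0, 4000.0)
    amplitude_modulation_rate: float = 4.0  # Hz, tremolo-like
    duration_s: float = 10.0
    rate: int = 44100
    tone_level: float = 0.3  # tone RMS relative to the noise bed

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        lo, hi = self.tone_freq_range
        if not (0 < lo < hi < self.rate / 2):
            raise ValueError("tone_freq_range must lie in (0, Nyquist)")


#: Per-measure baseline distributions (mean, SD) shared by both arms,
#: patterned on the typical symptom levels of a moderately distressed
#: tinnitus cohort. VAS values are clipped to [0, 100].
DEFAULT_BASELINES = {
    "vas_loudness": (50.0, 22.0),
    "vas_annoyance": (40.0, 24.0),
    "vas_awareness": (55.0, 23.0),
    "vas_handicap": (30.0, 22.0),
    "thq_total": (27.0, 17.0),
    "tq_total": (22.0, 12.0),
    "thi_total": (25.0, 16.0),
}


@dataclass(frozen=True)
class CohortModel:
    """Generative model of a two-arm cohort.

    Ages are normal (47.5 ± 10.8 y) truncated to the trial's 18–70 window;
    hearing loss is uniform on 0–70 dB; tinnitus pitch is normal on the
    log-frequency axis around 5.4 kHz, truncated to 1–12 kHz. A fraction
    ``dropout_rate`` of participants goes missing after the pre session.
    ``arm_effects`` maps (arm, measure) to the mean change added between
    pre and post (and carried into follow-up); ``change_sd`` is the
    session-to-session noise on every measure.
    """

    n: int = 100
    age_mean: float = 47.5
    age_sd: float = 10.8
    age_range: tuple[float, float] = (18.0, 70.0)
    hl_range_db: tuple[float, float] = (0.0, 70.0)
    pitch_mean_hz: float = 5400.0
    pitch_sd_cents: float = 500.0
    pitch_range_hz: tuple[float, float] = (1000.0, 12000.0)
    chronicity_mean_months: float = 84.0
    dropout_rate: float = 0.17
    arm_effects: dict = field(default_factory=dict)
    change_sd: float = 10.0
    harm_rates: dict = field(default_factory=lambda: {
        "consistently_louder": 0.10,
        "additional_sound": 0.08,
        "more_aware": 0.06,
    })

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not (0 <= self.dropout_rate <= 1):
            raise ValueError("dropout_rate must be a probability")
        for p in self.harm_rates.values():
            if not (0 <= p <= 1):
                raise ValueError("harm rates must be probabilities")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):  # resample; windows are wide so this terminates fast
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def make_music(model: MusicModel | None = None,
               seed: int | np.random.Generator = 0) -> AudioBuffer:
    """Tilted colored noise plus amplitude-modulated harmonic tones."""
    model = model or MusicModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(model.duration_s * model.rate))
    # shape white noise in the frequency domain: tilt in dB per octave
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / model.rate)
    ref = 1000.0
    with np.errstate(divide="ignore"):
        octaves = np.log2(np.maximum(freqs, freqs[1] if n > 1 else 1.0) / ref)
    amp = 10.0 ** (model.spectral_tilt_db_per_octave * octaves / 20.0)
    amp[0] = 0.0  # no DC
    noise = np.fft.irfft(spec * amp, n=n)
    noise /= max(np.sqrt(np.mean(noise ** 2)), 1e-12)

    t = np.arange(n) / model.rate
    tones = np.zeros(n)
    if model.n_harmonic_tones > 0:
        lo, hi = model.tone_freq_range
        fundamentals = 2.0 ** rng.uniform(math.log2(lo), math.log2(hi),
                                          size=model.n_harmonic_tones)
        for f0 in fundamentals:
            phase = rng.uniform(0, 2 * np.pi)
            am_phase = rng.uniform(0, 2 * np.pi)
            am = 0.5 * (1.0 + np.sin(2 * np.pi * model.amplitude_modulation_rate * t
                                     + am_phase))
            tones += am * np.sin(2 * np.pi * f0 * t + phase)
        tones_rms = np.sqrt(np.mean(tones ** 2))
        if tones_rms > 0:
            tones *= model.tone_level / tones_rms
    x = noise + tones
    x *= 0.25 / max(np.sqrt(np.mean(x ** 2)), 1e-12)  # comfortable headroom
    return AudioBuffer(samples=x, rate=model.rate)


def make_probe(kind: str = "flat_noise", duration_s: float = 30.0,
               rate: int = 44100,
               seed: int | np.random.Generator = 0) -> AudioBuffer:
    """Verification probes with known spectra.

    ``flat_noise``: white Gaussian noise (flat power per Hz).
    ``impulse_train``: 10 Hz click train (line spectrum at multiples of 10 Hz).
    ``chirp``: logarithmic sweep 100 Hz → 16 kHz.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    if kind == "flat_noise":
        x = rng.standard_normal(n)
    elif kind == "impulse_train":
        x = np.zeros(n)
        period = int(rate / 10.0)
        x[::period] = 1.0
    elif kind == "chirp":
        x = sps.chirp(t, f0=100.0, t1=duration_s, f1=16000.0, method="logarithmic")
    else:
        raise ValueError(f"unknown probe kind {kind!r}")
    x = x * (0.25 / max(np.sqrt(np.mean(x ** 2)), 1e-12))
    return AudioBuffer(samples=x, rate=rate)


def make_listener_pool(n: int, noise_cents: float = 50.0,
                       lapse_rate: float = 0.02,
                       pitch_range_hz: tuple[float, float] = (1000.0, 12000.0),
                       seed: int | np.random.Generator = 0):
    """Simulated listeners with true pitch uniform on the log axis."""
    from .pitch_matching import SimListener, hz_to_cents

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = pitch_range_hz
    pitches = 2.0 ** rng.uniform(math.log2(lo), math.log2(hi), size=n)
    return [SimListener(true_pitch_cents=hz_to_cents(f),
                        judgment_noise_cents=noise_cents,
                        lapse_rate=lapse_rate) for f in pitches]


def make_cohort(model: CohortModel | None = None,
                seed: int | np.random.Generator = 0):
    """Roster, outcome records, and harm reports for a simulated trial.

    Participants are eligible by construction. Arms alternate
    deterministically here (treatment/placebo) so injected effects are
    balanced; use :func:`notchkit.trial_design.randomize` when the
    allocation process itself is under study. Baseline and pre scores are
    drawn per measure from :data:`DEFAULT_BASELINES`; post adds the arm's
    injected mean change plus noise; follow-up carries the change forward.
    Dropouts are missing after the pre session (they keep baseline/pre
    records only).

    Returns ``(roster, records, harm_rows)``.
    """
    model = model or CohortModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ages = _truncated_normal(rng, model.age_mean, model.age_sd,
                             *model.age_range, size=model.n)
    hls = rng.uniform(*model.hl_range_db, size=model.n)
    lo, hi = model.pitch_range_hz
    pitch_log2 = _truncated_normal(
        rng, math.log2(model.pitch_mean_hz), model.pitch_sd_cents / 1200.0,
        math.log2(lo), math.log2(hi), size=model.n)
    pitches = 2.0 ** pitch_log2
    chronicity = 3.0 + rng.exponential(model.chronicity_mean_months, size=model.n)

    roster, records, harm_rows = [], [], []
    dropouts = rng.random(model.n) < model.dropout_rate
    for i in range(model.n):
        pid = f"P{i + 1:03d}"
        arm = "treatment" if i % 2 == 0 else "placebo"
        roster.append(Participant(
            id=pid, age=float(ages[i]), hearing_loss_db=float(hls[i]),
            tinnitus_hz=float(pitches[i]),
            chronicity_months=float(chronicity[i]),
        ))
        base = {m: rng.normal(mu, sd) for m, (mu, sd) in DEFAULT_BASELINES.items()}
        sessions = SESSIONS[:2] if dropouts[i] else SESSIONS
        for session in sessions:
            vals = {}
            for m, b in base.items():
                v = b + rng.normal(0.0, model.change_sd)
                if session in ("post", "followup"):
                    v += model.arm_effects.get((arm, m), 0.0)
                if m in VAS_SUBSCALES:
                    v = float(np.clip(v, 0.0, 100.0))
                vals[m] = float(v)
            records.append(OutcomeRecord(
                participant_id=pid, arm=arm, session=session, **vals))
        if not dropouts[i]:
            for cat, p in model.harm_rates.items():
                if rng.random() < p:
                    harm_rows.append((pid, arm, cat))
    return roster, records, harm_rows
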