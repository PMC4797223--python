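"""Recursive two-interval forced-choice (2-IFC) tinnitus pitch matching.

The matching procedure bisects the presentable range (1–16 kHz) on the
logarithmic axis. Each round asks two 2-IFC questions — for the low and for
the high subinterval, is the tinnitus more similar to the lower or the upper
end? — and recurses into the low subinterval, the high subinterval, or the
middle interval bounded by the two subinterval midpoints. The session ends
when the interval is narrower than a twelfth of an octave (or a round cap is
hit); a final forced-choice octave-confusion check compares the match
against the tone one octave below. Across repeated sessions, frequencies are
averaged in the Cent domain and retransformed to Hz (a geometric mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FreqInterval",
    "MatchConfig",
    "PitchSession",
    "PitchEstimate",
    "SimListener",
    "CENTS_REF_HZ",
    "hz_to_cents",
    "cents_to_hz",
    "bisect",
    "next_interval",
    "run_session",
    "octave_confusion",
    "aggregate_sessions",
]

#: Reference frequency for Cent values. Any positive reference cancels out
#: of the aggregate (the retransformed mean is the geometric mean).
CENTS_REF_HZ = 1000.0

LOW_END = "low_end"
HIGH_END = "high_end"


def hz_to_cents(f: float, ref: float = CENTS_REF_HZ) -> float:
    """Cents of ``f`` relative to ``ref``: 1200·log2(f/ref)."""
    if f <= 0 or ref <= 0:
        raise ValueError("frequencies must be positive")
    return 1200.0 * math.log2(f / ref)


def cents_to_hz(c: float, ref: float = CENTS_REF_HZ) -> float:
    """Inverse of :func:`hz_to_cents`."""
    if ref <= 0:
        raise ValueError("reference must be positive")
    return ref * 2.0 ** (c / 1200.0)


@dataclass(frozen=True)
class FreqInterval:
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("interval must satisfy 0 < low < high")

    @property
    def width_oct(self) -> float:
        return math.log2(self.high_hz / self.low_hz)

    @property
    def midpoint_hz(self) -> float:
        """Geometric (log-axis) midpoint."""
        return math.sqrt(self.low_hz * self.high_hz)

    def contains(self, other: "FreqInterval", tol: float = 1e-9) -> bool:
        return (self.low_hz <= other.low_hz * (1 + tol)
                and other.high_hz <= self.high_hz * (1 + tol))


@dataclass(frozen=True)
class MatchConfig:
    range_hz: tuple[float, float] = (1000.0, 16000.0)
    stop_width_oct: float = 1.0 / 12.0
    max_rounds: int = 12
    octave_test: bool = True

    def __post_init__(self):
        lo, hi = self.range_hz
        if not (0 < lo < hi):
            raise ValueError("range_hz must satisfy 0 < low < high")
        if self.stop_width_oct <= 0:
            raise ValueError("stop_width_oct must be positive")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be at least 1")


@dataclass(frozen=True)
class SimListener:
    """Simulated participant for driving the matching procedure.

    Judgments compare log-distances to the true pitch with additive Gaussian
    noise of ``judgment_noise_cents`` on each comparison; with probability
    ``lapse_rate`` the listener answers at random.
    """

    true_pitch_cents: float
    judgment_noise_cents: float = 50.0
    lapse_rate: float = 0.02

    def __post_init__(self):
        if self.judgment_noise_cents < 0:
            raise ValueError("judgment noise must be non-negative")
        if not (0 <= self.lapse_rate < 0.5):
            raise ValueError("lapse_rate must lie in [0, 0.5)")

    @property
    def true_pitch_hz(self) -> float:
        return cents_to_hz(self.true_pitch_cents)

    def choose(self, f_a: float, f_b: float, rng: np.random.Generator) -> int:
        """Return 0 if ``f_a`` judged closer to the tinnitus, else 1."""
        if rng.random() < self.lapse_rate:
            return int(rng.integers(2))
        d_a = abs(hz_to_cents(f_a) - self.true_pitch_cents)
        d_b = abs(hz_to_cents(f_b) - self.true_pitch_cents)
        noise = rng.normal(0.0, self.judgment_noise_cents) if self.judgment_noise_cents else 0.0
        return 0 if d_a <= d_b + noise else 1


@dataclass(frozen=True)
class PitchSession:
    """One completed matching run with its full per-round choice log."""

    matched_hz: float
    matched_cents: float
    loudness_setting: float
    rounds_used: int
    responses: tuple  # ((low_hz, high_hz, choice_low, choice_high), ...)

    def __post_init__(self):
        if abs(cents_to_hz(self.matched_cents) / self.matched_hz - 1.0) > 1e-6:
            raise ValueError("matched_cents and matched_hz are inconsistent")


@dataclass(frozen=True)
class PitchEstimate:
    """Cent-domain aggregate over repeated sessions."""

    mean_cents: float
    sd_cents: float
    mean_hz: float
    n_sessions: int


def bisect(interval: FreqInterval) -> tuple[FreqInterval, FreqInterval]:
    """Split at the log-frequency midpoint into two equal-octave halves."""
    mid = interval.midpoint_hz
    return (FreqInterval(interval.low_hz, mid), FreqInterval(mid, interval.high_hz))


def next_interval(choice_low: str, choice_high: str,
                  interval: FreqInterval) -> FreqInterval | None:
    """Map the round's two 2-IFC choices to the next search interval.

    ``choice_low``/``choice_high`` are the answers for the low and high
    subintervals. Consistent patterns select the low subinterval, the high
    subinterval, or the middle interval bounded by the two subinterval
    midpoints. The inconsistent pattern (low end of the low subinterval AND
    high end of the high subinterval) returns ``None`` so the caller can
    repeat the round.
    """
    for ch in (choice_low, choice_high):
        if ch not in (LOW_END, HIGH_END):
            raise ValueError(f"choice must be '{LOW_END}' or '{HIGH_END}'")
    low_sub, high_sub = bisect(interval)
    if choice_low == LOW_END and choice_high == LOW_END:
        return low_sub
    if choice_low == HIGH_END and choice_high == HIGH_END:
        return high_sub
    if choice_low == HIGH_END and choice_high == LOW_END:
        return FreqInterval(low_sub.midpoint_hz, high_sub.midpoint_hz)
    return None  # (low_end, high_end): contradictory


def octave_confusion(listener: SimListener, matched_hz: float,
                     rng: np.random.Generator,
                     lowest_hz: float = 1000.0) -> float:
    """Forced choice between the match and the tone one octave below.

    Octave errors in pitch matching are overwhelmingly downward confusions,
    so only ``matched_hz/2`` is offered. Requires ``matched_hz/2`` to be
    presentable (≥ ``lowest_hz``).
    """
    half = matched_hz / 2.0
    if half < lowest_hz:
        raise ValueError("octave-below tone falls under the presentable range")
    return matched_hz if listener.choose(matched_hz, half, rng) == 0 else half


def _one_round(listener: SimListener, interval: FreqInterval,
               rng: np.random.Generator) -> tuple[str, str]:
    low_sub, high_sub = bisect(interval)
    ch_low = LOW_END if listener.choose(low_sub.low_hz, low_sub.high_hz, rng) == 0 else HIGH_END
    ch_high = LOW_END if listener.choose(high_sub.low_hz, high_sub.high_hz, rng) == 0 else HIGH_END
    return ch_low, ch_high


def run_session(listener: SimListener, cfg: MatchConfig | None = None,
                seed: int | np.random.Generator = 0,
                loudness_setting: float = 50.0) -> PitchSession:
    """Run one recursive 2-IFC matching session with a simulated listener.

    Bisection recurses until the interval is at most ``stop_width_oct``
    wide or ``max_rounds`` rounds have been used; the match is the geometric
    midpoint of the final interval. A contradictory choice pattern repeats
    the round once, then falls back to the middle interval. If enabled and
    presentable, the octave-confusion test may replace the match by the
    octave below.
    """
    cfg = cfg or MatchConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    interval = FreqInterval(*cfg.range_hz)
    responses = []
    rounds = 0
    while interval.width_oct > cfg.stop_width_oct and rounds < cfg.max_rounds:
        ch_low, ch_high = _one_round(listener, interval, rng)
        nxt = next_interval(ch_low, ch_high, interval)
        if nxt is None:  # repeat once, then fall back to the middle interval
            ch_low, ch_high = _one_round(listener, interval, rng)
            nxt = next_interval(ch_low, ch_high, interval)
            if nxt is None:
                low_sub, high_sub = bisect(interval)
                nxt = FreqInterval(low_sub.midpoint_hz, high_sub.midpoint_hz)
        responses.append((interval.low_hz, interval.high_hz, ch_low, ch_high))
        interval = nxt
        rounds += 1
    matched = interval.midpoint_hz
    if cfg.octave_test and matched / 2.0 >= cfg.range_hz[0]:
        matched = octave_confusion(listener, matched, rng, lowest_hz=cfg.range_hz[0])
    return PitchSession(
        matched_hz=matched,
        matched_cents=hz_to_cents(matched),
        loudness_setting=loudness_setting,
        rounds_used=rounds,
        responses=tuple(responses),
    )


def aggregate_sessions(sessions: list[PitchSession]) -> PitchEstimate:
    """Cent-domain mean and sample SD over sessions, retransformed to Hz.

    The retransformed mean is the geometric mean of the session frequencies
    and does not depend on the Cent reference.
    """
    if not sessions:
        raise ValueError("at least one session is required")
    cents = np.array([s.matched_cents for s in sessions], dtype=np.float64)
    mean_c = float(np.mean(cents))
    sd_c = float(np.std(cents, ddof=1)) if len(cents) > 1 else 0.0
    return PitchEstimate(
        mean_cents=mean_c,
        sd_cents=sd_c,
        mean_hz=cents_to_hz(mean_c),
        n_sessions=len(sessions),
    )
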