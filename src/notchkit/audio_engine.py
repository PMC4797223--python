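"""Notched-music audio processing: equalization, notch filtering, edge enhancement.

The treatment condition removes a ½-octave band of spectral energy centered
at the listener's tinnitus frequency and amplifies the flanking 3/8-octave
edge bands by 20 dB, after first equalizing the music's long-term spectrum.
The placebo condition applies a notch of the same bandwidth whose center
frequency performs a bounded random walk (1/18-octave jumps every 5 s,
reflecting at predefined borders).

All spectral processing is short-time Fourier based: ~93 ms Hann windows
(4096 samples at 44.1 kHz, scaled with the sample rate), 75 % overlap, and
overlap-add reconstruction. Masks are defined on the log-frequency axis with
raised-cosine transitions to limit ringing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "AudioBuffer",
    "NotchSpec",
    "EqualizerSpec",
    "MovingNotchState",
    "MagnitudeResponse",
    "BandLevels",
    "design_notch_mask",
    "estimate_ltas",
    "equalize",
    "process_target",
    "moving_notch_step",
    "process_placebo",
    "measure_response",
]

#: Reference rate at which the analysis window is 4096 samples (~93 ms).
REFERENCE_RATE = 44100
REFERENCE_NPERSEG = 4096

#: dB value reported where a band/bin has been fully removed or is silent.
DB_FLOOR = -120.0

TINNITUS_RANGE_HZ = (1000.0, 12000.0)


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class AudioBuffer:
    """A mono or stereo waveform held as float64 samples.

    ``samples`` has shape ``(n,)`` for mono or ``(n, channels)`` for
    multichannel audio; ``rate`` is in samples per second.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (mono) or 2-D (frames, channels)")
        if arr.ndim == 2 and arr.shape[1] not in (1, 2):
            raise ValueError("only mono or stereo audio is supported")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def nyquist(self) -> float:
        return self.rate / 2.0

    def channel(self, i: int) -> np.ndarray:
        return self.samples if self.samples.ndim == 1 else self.samples[:, i]

    def with_samples(self, samples: np.ndarray) -> "AudioBuffer":
        return AudioBuffer(samples=samples, rate=self.rate)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


@dataclass(frozen=True)
class NotchSpec:
    """Parameters of the fixed notch + edge-enhancement filter.

    The stop band spans ``notch_width_oct`` octaves centered (geometrically)
    at ``center_hz``; each flanking edge band spans ``edge_width_oct``
    octaves and is amplified by ``edge_gain_db``. Transitions between the
    constant-gain regions are raised cosines of width ``transition_oct``
    on the log-frequency axis, centered on each band boundary.
    """

    center_hz: float
    notch_width_oct: float = 0.5
    edge_width_oct: float = 0.375
    edge_gain_db: float = 20.0
    transition_oct: float = 1.0 / 48.0

    def __post_init__(self):
        if self.center_hz <= 0:
            raise ValueError("center_hz must be positive")
        if self.notch_width_oct <= 0:
            raise ValueError("notch_width_oct must be positive")
        if self.edge_width_oct < 0:
            raise ValueError("edge_width_oct must be non-negative")
        if self.transition_oct <= 0:
            raise ValueError("transition_oct must be positive")

    @property
    def notch_band_hz(self) -> tuple[float, float]:
        half = self.notch_width_oct / 2.0
        return (self.center_hz * 2.0 ** -half, self.center_hz * 2.0 ** half)

    @property
    def lower_edge_band_hz(self) -> tuple[float, float]:
        lo, _ = self.notch_band_hz
        return (lo * 2.0 ** -self.edge_width_oct, lo)

    @property
    def upper_edge_band_hz(self) -> tuple[float, float]:
        _, hi = self.notch_band_hz
        return (hi, hi * 2.0 ** self.edge_width_oct)

    def recentered(self, center_hz: float) -> "NotchSpec":
        return replace(self, center_hz=center_hz)


@dataclass(frozen=True)
class EqualizerSpec:
    """Fractional-octave spectrum equalization parameters.

    The long-term average spectrum is measured in ``band_resolution``-octave
    bands over ``range_hz`` and each band is pulled toward the
    energy-weighted mean level, clamped to ``±max_gain_db``. With
    ``preserve_energy`` the output is rescaled to the input RMS.
    """

    band_resolution: float = 1.0 / 3.0
    range_hz: tuple[float, float] = (100.0, 16000.0)
    max_gain_db: float = 24.0
    preserve_energy: bool = True

    def __post_init__(self):
        lo, hi = self.range_hz
        if not (0 < lo < hi):
            raise ValueError("range_hz must satisfy 0 < low < high")
        if self.max_gain_db <= 0:
            raise ValueError("max_gain_db must be positive")
        if self.band_resolution <= 0:
            raise ValueError("band_resolution must be positive")


@dataclass(frozen=True)
class MovingNotchState:
    """Random-walk state of the placebo filter's notch center.

    The center jumps ``step_oct`` octaves every ``dwell_s`` seconds, always
    in the current direction; when a jump would push a notch-band edge past
    a border the direction is reversed and the step is taken the other way.
    ``direction`` is ``None`` until the first jump, whose direction is drawn
    uniformly at random.
    """

    center_hz: float
    direction: str | None = None  # "up" | "down" | None before first jump
    dwell_s: float = 5.0
    step_oct: float = 1.0 / 18.0
    border_hz: tuple[float, float] = (1000.0, 16000.0)
    elapsed_s: float = 0.0
    notch_width_oct: float = 0.5

    def __post_init__(self):
        lo, hi = self.border_hz
        if not (0 < lo < hi):
            raise ValueError("border_hz must satisfy 0 < low < high")
        # the borders must admit the notch band plus at least one step
        # in each direction, otherwise the walk cannot move at all
        needed = self.notch_width_oct + 2 * self.step_oct
        if math.log2(hi / lo) < needed:
            raise ValueError(
                "borders narrower than notch band plus two steps: "
                f"{math.log2(hi / lo):.3f} oct available, {needed:.3f} needed"
            )
        half = self.notch_width_oct / 2.0
        if not (lo <= self.center_hz * 2.0 ** -half and self.center_hz * 2.0 ** half <= hi):
            raise ValueError("notch band must start inside the borders")
        if self.direction not in (None, "up", "down"):
            raise ValueError("direction must be 'up', 'down' or None")


@dataclass(frozen=True)
class MagnitudeResponse:
    """Measured output-vs-input gain on a frequency grid."""

    freqs_hz: np.ndarray
    gain_db: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs_hz, dtype=np.float64)
        g = np.asarray(self.gain_db, dtype=np.float64)
        if f.shape != g.shape:
            raise ValueError("freqs_hz and gain_db must have equal shapes")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs_hz must be strictly increasing")
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "gain_db", g)

    def band_mean_db(self, low_hz: float, high_hz: float) -> float:
        """Mean gain over [low_hz, high_hz]; NaN if no grid point falls inside."""
        sel = (self.freqs_hz >= low_hz) & (self.freqs_hz <= high_hz)
        if not np.any(sel):
            return float("nan")
        return float(np.mean(self.gain_db[sel]))


@dataclass(frozen=True)
class BandLevels:
    """Fractional-octave band levels (band-integrated energy, dB)."""

    centers_hz: np.ndarray
    edges_hz: np.ndarray  # shape (n_bands, 2)
    levels_db: np.ndarray
    silent: bool = False


# ---------------------------------------------------------------------------
# STFT plumbing


def stft_params(rate: int) -> tuple[int, int]:
    """Window and hop length for this rate (~93 ms window, 75 % overlap)."""
    nperseg = int(round(REFERENCE_NPERSEG * rate / REFERENCE_RATE))
    nperseg += nperseg % 2  # keep even so hop = nperseg // 4 tiles exactly
    return nperseg, nperseg // 4


def _stft(x: np.ndarray, rate: int):
    nperseg, hop = stft_params(rate)
    f, t, Z = sps.stft(
        x, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg - hop,
        boundary="zeros", padded=True,
    )
    return f, t, Z, nperseg, hop


def _istft(Z: np.ndarray, rate: int, n_out: int) -> np.ndarray:
    nperseg, hop = stft_params(rate)
    _, y = sps.istft(
        Z, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg - hop,
    )
    if len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)))
    return y[:n_out]


def _apply_static_mask(buf: AudioBuffer, mask: np.ndarray) -> AudioBuffer:
    """Multiply every STFT frame of every channel by one spectral mask."""
    outs = []
    for c in range(buf.channels):
        _, _, Z, _, _ = _stft(buf.channel(c), buf.rate)
        Z *= mask[:, None]
        outs.append(_istft(Z, buf.rate, buf.n_samples))
    return buf.with_samples(outs[0] if buf.channels == 1 else np.stack(outs, axis=1))


# ---------------------------------------------------------------------------
# notch mask


def _smooth_profile(x: np.ndarray, boundaries: np.ndarray, levels: np.ndarray,
                    width: float) -> np.ndarray:
    """Piecewise-constant profile over x with raised-cosine blends.

    ``levels`` has one more entry than ``boundaries``; each transition is
    centered on its boundary and spans ``width`` along x.
    """
    g = np.full_like(x, levels[0], dtype=np.float64)
    half = width / 2.0
    for b, l_right in zip(boundaries, levels[1:]):
        g = np.where(x >= b + half, l_right, g)
        in_t = (x > b - half) & (x < b + half)
        if np.any(in_t):
            w = 0.5 * (1.0 - np.cos(np.pi * (x[in_t] - (b - half)) / width))
            l_left = g[in_t]  # value approaching from the left
            # left value inside the window is the previous level
            g[in_t] = l_left + w * (l_right - l_left)
    return g


def design_notch_mask(spec: NotchSpec, freq_grid: np.ndarray) -> np.ndarray:
    """Per-frequency linear gain implementing notch removal + edge boost.

    Gain is 0 inside the notch band, ``10^(edge_gain_db/20)`` inside each
    edge band, 1 elsewhere, with raised-cosine transitions of width
    ``transition_oct`` centered on the four band boundaries (log-frequency
    axis). Rejects a spec whose upper edge band (plus transition) exceeds
    the top of the grid, i.e. would fall outside (0, Nyquist).
    """
    freqs = np.asarray(freq_grid, dtype=np.float64)
    pos = freqs[freqs > 0]
    if pos.size and np.any(np.diff(freqs) <= 0):
        raise ValueError("freq_grid must be strictly increasing")
    e_lo = spec.lower_edge_band_hz
    e_hi = spec.upper_edge_band_hz
    top_needed = e_hi[1] * 2.0 ** (spec.transition_oct / 2.0)
    if freqs.size and top_needed > freqs.max():
        raise ValueError(
            f"upper edge band reaches {top_needed:.0f} Hz, beyond the grid "
            f"maximum {freqs.max():.0f} Hz (Nyquist); lower the center or "
            "raise the sample rate"
        )
    edge_gain = 10.0 ** (spec.edge_gain_db / 20.0)
    boundaries = np.log2([e_lo[0], e_lo[1], e_hi[0], e_hi[1]])
    levels = np.array([1.0, edge_gain, 0.0, edge_gain, 1.0])
    x = np.log2(np.where(freqs > 0, freqs, np.min(pos) if pos.size else 1.0))
    gain = _smooth_profile(x, boundaries, levels, spec.transition_oct)
    if freqs.size and freqs[0] == 0:
        gain[0] = 1.0  # DC is far below any admissible band
    return gain


# ---------------------------------------------------------------------------
# equalization


def _band_edges(spec: EqualizerSpec) -> np.ndarray:
    lo, hi = spec.range_hz
    r = spec.band_resolution
    n = int(math.ceil(math.log2(hi / lo) / r - 1e-9))
    edges = lo * 2.0 ** (r * np.arange(n + 1))
    edges[-1] = min(edges[-1], hi)
    return np.column_stack([edges[:-1], edges[1:]])


def _welch_psd(buf: AudioBuffer) -> tuple[np.ndarray, np.ndarray]:
    """Channel-averaged Welch power spectral density."""
    nperseg, hop = stft_params(buf.rate)
    psds = []
    for c in range(buf.channels):
        f, p = sps.welch(buf.channel(c), fs=buf.rate, window="hann",
                         nperseg=nperseg, noverlap=nperseg - hop)
        psds.append(p)
    return f, np.mean(psds, axis=0)


def estimate_ltas(buf: AudioBuffer, spec: EqualizerSpec | None = None) -> BandLevels:
    """Long-term average spectrum as fractional-octave band levels.

    Levels are band-integrated energies in dB (a white-noise input therefore
    rises ~3 dB per octave because bands widen with frequency); a silent
    input returns all-floor levels with ``silent=True``.
    """
    spec = spec or EqualizerSpec()
    nperseg, _ = stft_params(buf.rate)
    if buf.n_samples < nperseg:
        raise ValueError("signal shorter than one analysis window")
    f, psd = _welch_psd(buf)
    edges = _band_edges(spec)
    centers = np.sqrt(edges[:, 0] * edges[:, 1])
    df = f[1] - f[0]
    powers = np.array([
        psd[(f >= lo) & (f < hi)].sum() * df for lo, hi in edges
    ])
    silent = bool(np.all(powers <= 0))
    with np.errstate(divide="ignore"):
        levels = np.where(powers > 0, 10.0 * np.log10(np.maximum(powers, 1e-300)),
                          DB_FLOOR)
    levels = np.maximum(levels, DB_FLOOR)
    return BandLevels(centers_hz=centers, edges_hz=edges, levels_db=levels,
                      silent=silent)


def _equalizer_gain(buf: AudioBuffer, spec: EqualizerSpec,
                    freqs: np.ndarray) -> np.ndarray:
    """Linear gain per frequency that flattens the band-integrated LTAS."""
    ltas = estimate_ltas(buf, spec)
    if ltas.silent:
        return np.ones_like(freqs)
    powers = 10.0 ** (ltas.levels_db / 10.0)
    target_db = 10.0 * math.log10(np.mean(powers))  # energy-weighted mean level
    gains_db = np.clip(target_db - ltas.levels_db, -spec.max_gain_db,
                       spec.max_gain_db)
    # interpolate linearly in log2-frequency; taper to 0 dB one band
    # outside the analysis range
    r = spec.band_resolution
    lo, hi = spec.range_hz
    xs = np.concatenate([
        [math.log2(lo) - r], np.log2(ltas.centers_hz), [math.log2(hi) + r]
    ])
    ys = np.concatenate([[0.0], gains_db, [0.0]])
    x = np.log2(np.maximum(freqs, 1e-6))
    gain_db = np.interp(x, xs, ys, left=0.0, right=0.0)
    return 10.0 ** (gain_db / 20.0)


def equalize(buf: AudioBuffer, spec: EqualizerSpec | None = None) -> AudioBuffer:
    """Flatten the long-term spectrum across ``spec.range_hz``.

    One static gain curve is estimated per track and applied to all
    channels identically; with ``preserve_energy`` the output is rescaled
    so total RMS matches the input within numerical precision.
    """
    spec = spec or EqualizerSpec()
    nperseg, _ = stft_params(buf.rate)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / buf.rate)
    gain = _equalizer_gain(buf, spec, freqs)
    out = _apply_static_mask(buf, gain)
    if spec.preserve_energy:
        rms_in, rms_out = buf.rms(), out.rms()
        if rms_out > 0:
            out = out.with_samples(out.samples * (rms_in / rms_out))
    return out


# ---------------------------------------------------------------------------
# treatment / placebo processing chains


def process_target(buf: AudioBuffer, tinnitus_hz: float,
                   eq: EqualizerSpec | None = None,
                   notch: NotchSpec | None = None,
                   force: bool = False) -> AudioBuffer:
    """Full treatment chain: equalize, notch out, edge-enhance.

    ``tinnitus_hz`` must lie in the trial's admissible 1–12 kHz range
    unless ``force`` is set. Both channels receive identical processing.
    """
    lo, hi = TINNITUS_RANGE_HZ
    if not force and not (lo <= tinnitus_hz <= hi):
        raise ValueError(
            f"tinnitus frequency {tinnitus_hz:g} Hz outside [{lo:g}, {hi:g}] Hz; "
            "pass force=True to override"
        )
    eq = eq or EqualizerSpec()
    notch = (notch or NotchSpec(center_hz=tinnitus_hz)).recentered(tinnitus_hz)
    nperseg, _ = stft_params(buf.rate)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / buf.rate)
    mask = design_notch_mask(notch, freqs)
    return _apply_static_mask(equalize(buf, eq), mask)


def moving_notch_step(state: MovingNotchState, rng: np.random.Generator,
                      dt: float) -> MovingNotchState:
    """Advance the placebo walk by ``dt`` seconds.

    While the dwell clock has not expired only ``elapsed_s`` advances. On
    expiry the center jumps ``step_oct`` octaves in the current direction
    (the first direction ever is drawn uniformly at random); if the jump
    would push a notch-band edge past a border, the direction is reversed
    and the step taken the other way.
    """
    elapsed = state.elapsed_s + dt
    if elapsed < state.dwell_s:
        return replace(state, elapsed_s=elapsed)
    elapsed -= state.dwell_s
    direction = state.direction
    if direction is None:
        direction = "up" if rng.random() < 0.5 else "down"
    half = state.notch_width_oct / 2.0
    lo, hi = state.border_hz

    def _admissible(center: float) -> bool:
        return lo <= center * 2.0 ** -half and center * 2.0 ** half <= hi

    sign = 1.0 if direction == "up" else -1.0
    candidate = state.center_hz * 2.0 ** (sign * state.step_oct)
    if not _admissible(candidate):
        direction = "down" if direction == "up" else "up"
        sign = -sign
        candidate = state.center_hz * 2.0 ** (sign * state.step_oct)
    return replace(state, center_hz=candidate, direction=direction,
                   elapsed_s=elapsed)


def _initial_state(notch: NotchSpec, borders: tuple[float, float],
                   dwell_s: float, step_oct: float,
                   rng: np.random.Generator) -> MovingNotchState:
    half = notch.notch_width_oct / 2.0
    lo = borders[0] * 2.0 ** half
    hi = borders[1] * 2.0 ** -half
    center = 2.0 ** rng.uniform(math.log2(lo), math.log2(hi))
    return MovingNotchState(
        center_hz=center, direction=None, dwell_s=dwell_s, step_oct=step_oct,
        border_hz=borders, elapsed_s=0.0, notch_width_oct=notch.notch_width_oct,
    )


def process_placebo(buf: AudioBuffer,
                    eq: EqualizerSpec | None = None,
                    notch: NotchSpec | None = None,
                    borders: tuple[float, float] = (1000.0, 16000.0),
                    seed: int | np.random.Generator = 0,
                    dwell_s: float = 5.0,
                    step_oct: float = 1.0 / 18.0):
    """Placebo chain: equalize, then apply the moving notch (same bandwidth).

    The placebo receives the same equalization and the same edge
    enhancement as the treatment; only the notch-center dynamics differ.
    Jump instants are quantized to STFT block boundaries with a one-hop
    linear crossfade between the outgoing and incoming masks.

    Returns ``(processed AudioBuffer, trace)`` where ``trace`` is a list of
    ``(time_s, center_hz, direction)`` per STFT block.
    """
    eq = eq or EqualizerSpec()
    notch = notch or NotchSpec(center_hz=4000.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nperseg, hop = stft_params(buf.rate)
    dt = hop / buf.rate
    if buf.duration_s < dwell_s:
        raise ValueError("signal must be at least one dwell period long")

    eq_buf = equalize(buf, eq)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / buf.rate)

    # drive the walk once, shared by all channels
    _, _, Z0, _, _ = _stft(eq_buf.channel(0), buf.rate)
    n_frames = Z0.shape[1]
    state = _initial_state(notch, borders, dwell_s, step_oct, rng)
    centers = np.empty(n_frames)
    trace = []
    for j in range(n_frames):
        centers[j] = state.center_hz
        trace.append((j * dt, state.center_hz, state.direction or "none"))
        state = moving_notch_step(state, rng, dt)

    mask_cache: dict[float, np.ndarray] = {}

    def mask_for(center: float) -> np.ndarray:
        if center not in mask_cache:
            mask_cache[center] = design_notch_mask(notch.recentered(center), freqs)
        return mask_cache[center]

    outs = []
    for c in range(buf.channels):
        _, _, Z, _, _ = _stft(eq_buf.channel(c), buf.rate)
        for j in range(n_frames):
            m = mask_for(centers[j])
            if j > 0 and centers[j] != centers[j - 1]:
                m = 0.5 * (m + mask_for(centers[j - 1]))  # one-hop crossfade
            Z[:, j] *= m
        outs.append(_istft(Z, buf.rate, buf.n_samples))
    out = eq_buf.with_samples(outs[0] if buf.channels == 1 else np.stack(outs, axis=1))
    return out, trace


# ---------------------------------------------------------------------------
# verification


def measure_response(inp: AudioBuffer, out: AudioBuffer) -> MagnitudeResponse:
    """Output-minus-input gain per frequency from averaged power spectra.

    Bins where the input has (numerically) no power are reported at the
    −120 dB floor rather than as infinities.
    """
    if inp.rate != out.rate or inp.n_samples != out.n_samples:
        raise ValueError("input and output must share rate and length")
    f, p_in = _welch_psd(inp)
    _, p_out = _welch_psd(out)
    floor_lin = 10.0 ** (DB_FLOOR / 10.0)
    valid = p_in > 0
    ratio = np.full_like(p_in, floor_lin)
    np.divide(p_out, p_in, out=ratio, where=valid)
    gain_db = 10.0 * np.log10(np.maximum(ratio, floor_lin))
    return MagnitudeResponse(freqs_hz=f, gain_db=gain_db)
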