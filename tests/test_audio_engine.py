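"""Spectral engine: notch mask geometry, equalization, placebo walk."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import notchkit as nk
from notchkit.audio_engine import (
    DB_FLOOR,
    MovingNotchState,
    stft_params,
)


class TestNotchMask:
    def test_band_geometry_closed_form(self):
        spec = nk.NotchSpec(center_hz=4000.0)
        lo, hi = spec.notch_band_hz
        assert lo == pytest.approx(4000 * 2 ** -0.25)  # 3363.6
        assert hi == pytest.approx(4000 * 2 ** 0.25)   # 4756.8
        elo = spec.lower_edge_band_hz
        ehi = spec.upper_edge_band_hz
        assert elo[0] == pytest.approx(lo * 2 ** -0.375)  # 2593.7
        assert ehi[1] == pytest.approx(hi * 2 ** 0.375)   # 6168.4

    def test_mask_levels_by_region(self):
        spec = nk.NotchSpec(center_hz=4000.0)
        freqs = np.linspace(1.0, 22050.0, 8192)
        gain = nk.design_notch_mask(spec, freqs)
        t = spec.transition_oct
        nb, elo, ehi = spec.notch_band_hz, spec.lower_edge_band_hz, spec.upper_edge_band_hz

        def region(lo, hi):
            return (freqs > lo * 2 ** t) & (freqs < hi * 2 ** -t)

        assert np.allclose(gain[region(*nb)], 0.0)
        assert np.allclose(gain[region(*elo)], 10.0)
        assert np.allclose(gain[region(*ehi)], 10.0)
        far = (freqs < elo[0] * 2 ** -t) | (freqs > ehi[1] * 2 ** t)
        assert np.allclose(gain[far], 1.0)
        # a frequency far outside all bands passes exactly unity
        assert nk.design_notch_mask(spec, np.array([100.0, 20000.0]))[0] == 1.0

    def test_rejects_edge_band_beyond_nyquist(self):
        spec = nk.NotchSpec(center_hz=12000.0)
        freqs = np.fft.rfftfreq(4096, 1 / 32000)  # Nyquist 16 kHz < 18.5 kHz needed
        with pytest.raises(ValueError, match="edge band"):
            nk.design_notch_mask(spec, freqs)

    @given(center=st.floats(min_value=1500.0, max_value=8000.0))
    @settings(max_examples=25, deadline=None)
    def test_mask_gain_bounded(self, center):
        spec = nk.NotchSpec(center_hz=center)
        freqs = np.linspace(10.0, 22050.0, 2048)
        gain = nk.design_notch_mask(spec, freqs)
        assert np.all(gain >= 0.0)
        assert np.all(gain <= 10.0 + 1e-12)


class TestLtasAndEqualizer:
    def test_white_noise_band_levels_rise_per_octave(self, short_probe):
        """Band-integrated white-noise energy rises ~3 dB per octave."""
        ltas = nk.estimate_ltas(short_probe)
        oct_pos = np.log2(ltas.centers_hz / ltas.centers_hz[0])
        slope = np.polyfit(oct_pos[:-1], ltas.levels_db[:-1], 1)[0]
        assert slope == pytest.approx(10 * math.log10(2), abs=0.3)

    def test_pure_tone_energy_in_its_band(self):
        rate = 44100
        t = np.arange(rate * 4) / rate
        buf = nk.AudioBuffer(np.sin(2 * np.pi * 1000.0 * t), rate)
        ltas = nk.estimate_ltas(buf)
        k = int(np.argmax(ltas.levels_db))
        lo, hi = ltas.edges_hz[k]
        assert lo <= 1000.0 < hi

    def test_ltas_time_invariance(self, short_probe):
        doubled = short_probe.with_samples(
            np.concatenate([short_probe.samples, short_probe.samples]))
        a = nk.estimate_ltas(short_probe).levels_db
        b = nk.estimate_ltas(doubled).levels_db
        assert np.allclose(a, b, atol=0.2)

    def test_silent_input_flagged_at_floor(self):
        buf = nk.AudioBuffer(np.zeros(44100), 44100)
        ltas = nk.estimate_ltas(buf)
        assert ltas.silent
        assert np.all(ltas.levels_db == DB_FLOOR)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            nk.estimate_ltas(nk.AudioBuffer(np.zeros(100), 44100))

    def test_equalized_output_flat_within_3db(self):
        """Pink-ish tilted noise comes out flat across the analysis range."""
        buf = nk.make_music(nk.MusicModel(duration_s=8.0, n_harmonic_tones=0,
                                          spectral_tilt_db_per_octave=-6.0), seed=3)
        out = nk.equalize(buf)
        ltas = nk.estimate_ltas(out)
        inside = (ltas.centers_hz > 150) & (ltas.centers_hz < 12000)
        levels = ltas.levels_db[inside]
        assert np.ptp(levels) / 2 < 3.0

    def test_energy_conserved_within_one_percent(self, short_probe):
        out = nk.equalize(short_probe)
        assert abs(out.rms() - short_probe.rms()) / short_probe.rms() < 0.01

    def test_flat_input_near_fixed_point(self):
        """An already-flat (per band) spectrum gets ≈0 dB band gains."""
        buf = nk.make_music(nk.MusicModel(duration_s=8.0, n_harmonic_tones=0,
                                          spectral_tilt_db_per_octave=-3.0), seed=4)
        # −3 dB/oct per Hz is flat per fractional-octave band
        out = nk.equalize(buf)
        resp = nk.measure_response(buf, out)
        sel = (resp.freqs_hz > 200) & (resp.freqs_hz < 12000)
        assert np.abs(resp.gain_db[sel]).mean() < 1.5


class TestTargetChain:
    def test_tinnitus_range_enforced_unless_forced(self, short_probe):
        with pytest.raises(ValueError, match="force"):
            nk.process_target(short_probe, 500.0)
        out = nk.process_target(short_probe, 900.0, force=True)
        assert out.n_samples == short_probe.n_samples

    def test_measured_geometry_on_flat_probe(self, short_probe):
        """Notch width, edge gain and passband contracts, measured."""
        spec = nk.NotchSpec(center_hz=4000.0)
        eq_probe = nk.equalize(short_probe)
        out = nk.process_target(short_probe, 4000.0)
        resp = nk.measure_response(eq_probe, out)
        t = spec.transition_oct
        # stop band: deep floor inside
        nb = spec.notch_band_hz
        inner = (resp.freqs_hz > nb[0] * 2 ** t) & (resp.freqs_hz < nb[1] * 2 ** -t)
        assert resp.gain_db[inner].min() <= -40.0
        # −6 dB width
        sel = (resp.freqs_hz > 2000) & (resp.freqs_hz < 8000)
        f, g = resp.freqs_hz[sel], resp.gain_db[sel]
        below = f[g < -6.0]
        assert math.log2(below.max() / below.min()) == pytest.approx(0.5, abs=0.05)
        # edge gain ±1 dB over the band interiors
        for band in (spec.lower_edge_band_hz, spec.upper_edge_band_hz):
            mean = resp.band_mean_db(band[0] * 2 ** t, band[1] * 2 ** -t)
            assert mean == pytest.approx(20.0, abs=1.0)
        # passband flat relative to the equalized signal
        passband = resp.band_mean_db(300.0, 2000.0)
        assert passband == pytest.approx(0.0, abs=1.0)

    def test_stereo_channels_processed_identically(self):
        mono = nk.make_probe("flat_noise", duration_s=4.0, seed=5)
        stereo = mono.with_samples(np.stack([mono.samples, mono.samples], axis=1))
        out = nk.process_target(stereo, 4000.0)
        assert np.array_equal(out.samples[:, 0], out.samples[:, 1])


class TestMovingNotch:
    def _state(self, **kw):
        defaults = dict(center_hz=4000.0, direction="up", dwell_s=5.0,
                        border_hz=(1000.0, 16000.0))
        defaults.update(kw)
        return MovingNotchState(**defaults)

    def test_step_up_closed_form(self, rng):
        state = self._state(elapsed_s=5.0)
        new = nk.moving_notch_step(state, rng, dt=0.0)
        assert new.center_hz == pytest.approx(4000 * 2 ** (1 / 18))  # 4156.1

    def test_dwell_not_expired_keeps_center(self, rng):
        state = self._state(elapsed_s=2.0)
        new = nk.moving_notch_step(state, rng, dt=0.5)
        assert new.center_hz == state.center_hz
        assert new.elapsed_s == pytest.approx(2.5)

    def test_reflects_at_border(self, rng):
        # center near the top: notch upper edge at the 16 kHz border
        center = 16000.0 * 2 ** -0.25
        state = self._state(center_hz=center, elapsed_s=5.0)
        new = nk.moving_notch_step(state, rng, dt=0.0)
        assert new.direction == "down"
        assert new.center_hz < center

    def test_rejects_borders_narrower_than_band_plus_steps(self):
        with pytest.raises(ValueError, match="borders"):
            self._state(center_hz=4000.0, border_hz=(3400.0, 4700.0))

    def test_elapsed_invariant_after_commit(self, rng):
        state = self._state(elapsed_s=4.9)
        new = nk.moving_notch_step(state, rng, dt=0.3)
        assert 0.0 <= new.elapsed_s < new.dwell_s

    def test_first_direction_random_but_seeded(self):
        state = self._state(direction=None, elapsed_s=5.0)
        a = nk.moving_notch_step(state, np.random.default_rng(0), dt=0.0)
        b = nk.moving_notch_step(state, np.random.default_rng(0), dt=0.0)
        assert a.direction == b.direction
        assert a.direction in ("up", "down")


@pytest.fixture(scope="module")
def placebo_run():
    probe = nk.make_probe("flat_noise", duration_s=20.0, seed=2)
    return probe, nk.process_placebo(probe, seed=7)


class TestPlaceboChain:

    def test_jumps_every_dwell_within_one_hop(self, placebo_run):
        probe, (out, trace) = placebo_run
        times = np.array([t for t, _, _ in trace])
        centers = np.array([c for _, c, _ in trace])
        jumps = np.nonzero(np.diff(centers) != 0)[0] + 1
        hop = stft_params(probe.rate)[1] / probe.rate
        assert len(jumps) >= 2
        assert np.all(np.abs(np.diff(times[jumps]) - 5.0) <= hop)

    def test_all_steps_one_eighteenth_octave(self, placebo_run):
        _, (out, trace) = placebo_run
        centers = np.array([c for _, c, _ in trace])
        jumps = np.nonzero(np.diff(centers) != 0)[0] + 1
        steps = np.abs(np.log2(centers[jumps] / centers[jumps - 1]))
        assert np.all(np.abs(steps - 1 / 18) < 1e-6)

    def test_direction_changes_only_at_borders(self, placebo_run):
        _, (out, trace) = placebo_run
        centers = np.array([c for _, c, _ in trace])
        jumps = np.nonzero(np.diff(centers) != 0)[0] + 1
        signs = np.sign(np.log2(centers[jumps] / centers[jumps - 1]))
        for i in np.nonzero(np.diff(signs) != 0)[0]:
            # a reversal means the straight-line step would have crossed
            c_before = centers[jumps[i]]
            step = signs[i] * (1 / 18)
            edge = c_before * 2 ** (step + signs[i] * 0.25)
            assert edge < 1000.0 * 2 ** (1 / 18) or edge > 16000.0 * 2 ** (-1 / 18)

    def test_seeded_determinism(self, placebo_run):
        probe, (out, trace) = placebo_run
        out2, trace2 = nk.process_placebo(probe, seed=7)
        assert np.array_equal(out.samples, out2.samples)
        assert trace == trace2

    def test_requires_one_dwell_period(self):
        probe = nk.make_probe("flat_noise", duration_s=2.0, seed=0)
        with pytest.raises(ValueError, match="dwell"):
            nk.process_placebo(probe, seed=0)


class TestMeasureResponse:
    def test_identity_and_scaling(self, short_probe):
        resp = nk.measure_response(short_probe, short_probe)
        assert np.allclose(resp.gain_db, 0.0, atol=1e-9)
        doubled = short_probe.with_samples(short_probe.samples * 2.0)
        resp2 = nk.measure_response(short_probe, doubled)
        assert np.allclose(resp2.gain_db, 20 * math.log10(2), atol=1e-9)

    def test_zero_power_input_reported_at_floor(self):
        rate = 44100
        t = np.arange(rate * 2) / rate
        tone = nk.AudioBuffer(np.sin(2 * np.pi * 1000 * t), rate)
        noise = nk.make_probe("flat_noise", duration_s=2.0, seed=0)
        resp = nk.measure_response(tone, noise)
        assert np.isfinite(resp.gain_db).all()

    def test_mismatched_buffers_rejected(self, short_probe):
        other = nk.AudioBuffer(short_probe.samples[:-10], short_probe.rate)
        with pytest.raises(ValueError):
            nk.measure_response(short_probe, other)
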