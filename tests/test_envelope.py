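"""Filtering, envelope extraction, window arithmetic, and PLV oracles."""

import numpy as np
import pandas as pd
import pytest

from duetibs import (
    band_envelope, bpm_to_hz, envelope_phase, preprocess, roi_average,
    sliding_plv,
)
from duetibs.envelope import PLVSeries, WindowGrid, band_power, condition_means
from duetibs.io import DyadEpochs
from duetibs.montage import CHANNELS

SF = 500.0


def _tone(freq, dur=18.0, amp=1.0, phase=0.0, sf=SF):
    t = np.arange(0, dur, 1 / sf)
    return t, amp * np.cos(2 * np.pi * freq * t + phase)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocess:
    def _run(self, signal, events=(9000,)):
        raw = np.tile(signal, (len(CHANNELS), 1))
        ep = preprocess(raw, raw, SF, np.array(events), list(CHANNELS),
                        conditions=pd.DataFrame(index=range(len(events))))
        return ep

    def test_notch_removes_line_noise(self):
        """A pure 50 Hz sinusoid is suppressed below 1% of its amplitude."""
        _, x = _tone(50.0, dur=40.0)
        ep = self._run(x)
        interior = ep.data1[0, 0, 1000:-1000]
        assert np.abs(interior).max() < 0.01

    def test_highpass_removes_dc(self):
        _, x = _tone(10.0, dur=40.0)
        ep = self._run(x + 5.0)
        interior = ep.data1[0, 0, 1000:-1000]
        assert abs(interior.mean()) < 1e-3

    def test_epoch_sample_arithmetic(self):
        """Epoch sample 0 corresponds to event sample minus sfreq."""
        x = np.zeros(int(40 * SF))
        marker = 9000 - int(SF)
        x[marker] = 100.0
        ep = self._run(x)
        assert ep.times[0] == pytest.approx(-1.0)
        assert np.argmax(np.abs(ep.data1[0, 0])) == 0
        assert ep.data1.shape[-1] == int(17 * SF)

    def test_mastoid_rereference(self):
        names = list(CHANNELS) + ["M1", "M2"]
        rng = np.random.default_rng(0)
        raw = rng.normal(0, 1, (len(names), int(40 * SF)))
        ep = preprocess(raw, raw, SF, np.array([9000]), names)
        assert ep.ch_names == list(CHANNELS)

    def test_missing_events_error(self):
        with pytest.raises(ValueError, match="event"):
            self._run(np.zeros(int(40 * SF)), events=())


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

class TestBandEnvelope:
    def test_tone_envelope_recovers_amplitude(self):
        _, x = _tone(35.0, amp=2.5)
        env = band_envelope(x, "gamma", SF)
        interior = env[2000:-2000]
        assert interior == pytest.approx(2.5, rel=0.02)

    def test_out_of_band_rejected(self):
        _, x = _tone(10.0)
        env = band_envelope(x, "gamma", SF)
        assert env[2000:-2000].max() < 0.02

    def test_am_demodulation(self):
        """Envelope of A(1 + 0.5 cos 2pi 2t) cos 2pi 35t recovers the 2 Hz
        modulation within 5% in the interior."""
        t, carrier = _tone(35.0)
        x = (1 + 0.5 * np.cos(2 * np.pi * 2 * t)) * carrier
        env = band_envelope(x, "gamma", SF)
        expected = 1 + 0.5 * np.cos(2 * np.pi * 2 * t)
        sl = slice(2000, -2000)
        assert np.max(np.abs(env[sl] - expected[sl])) < 0.05

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_envelope(np.zeros(1000), "gamma", 60.0)


class TestEnvelopePhase:
    def test_phase_ramp_of_2hz_envelope(self):
        """A 2 Hz envelope oscillation advances 4*pi of phase per second."""
        t = np.arange(0, 18, 1 / SF)
        env = 1 + np.cos(2 * np.pi * 2 * t)
        phase = np.unwrap(envelope_phase(env, SF))
        sl = slice(2000, -2000)
        rate = np.polyfit(t[sl], phase[sl], 1)[0]
        assert rate == pytest.approx(4 * np.pi, rel=0.01)

    def test_identical_envelopes_zero_difference(self):
        rng = np.random.default_rng(1)
        env = np.abs(rng.normal(1, 0.3, 5000))
        p = envelope_phase(env, SF)
        assert np.allclose(p - p, 0.0)
        assert (p > -np.pi).all() and (p <= np.pi).all()

    def test_known_phase_offset_recovered(self):
        t = np.arange(0, 18, 1 / SF)
        offset = 0.8
        e1 = 1 + np.cos(2 * np.pi * 2 * t)
        e2 = 1 + np.cos(2 * np.pi * 2 * t - offset)
        d = envelope_phase(e1, SF) - envelope_phase(e2, SF)
        d = np.angle(np.exp(1j * d))[2000:-2000]
        assert np.median(d) == pytest.approx(offset, abs=0.02)


def test_bpm_to_hz_conversions():
    assert bpm_to_hz(96) == pytest.approx(1.6)
    assert bpm_to_hz(150) == pytest.approx(2.5)
    assert bpm_to_hz(120) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        bpm_to_hz(0)


# ---------------------------------------------------------------------------
# window grid
# ---------------------------------------------------------------------------

class TestWindowGrid:
    def test_default_grid_has_113_windows(self):
        grid = WindowGrid()
        assert grid.n_windows == 113
        assert grid.centers[0] == pytest.approx(2.0)
        assert grid.centers[-1] == pytest.approx(13.2)
        assert grid.onsets()[-1] + grid.width == pytest.approx(14.2)

    def test_window_samples_at_500hz(self):
        assert WindowGrid().n_samples(500.0) == 1000

    def test_cluster_coverage_arithmetic(self):
        """Significant centers 7.7-8.3 s reflect data from 6.7 to 9.3 s."""
        lo, hi = WindowGrid().coverage(7.7, 8.3)
        assert lo == pytest.approx(6.7)
        assert hi == pytest.approx(9.3)

    def test_grid_outside_epoch_rejected(self):
        times = np.arange(0.0, 10.0, 1 / 100.0)
        with pytest.raises(ValueError, match="exceeds"):
            WindowGrid().start_indices(times, 100.0)


# ---------------------------------------------------------------------------
# sliding PLV
# ---------------------------------------------------------------------------

def _phase_setup(n=None, sf=100.0):
    times = np.arange(-1.0, 16.0, 1 / sf)
    return times, sf


class TestSlidingPLV:
    def test_identical_phases_give_one(self):
        times, sf = _phase_setup()
        rng = np.random.default_rng(0)
        p1 = rng.uniform(-np.pi, np.pi, (3, times.size))
        plv = sliding_plv(p1, p1, sf, times)
        assert np.allclose(plv.values, 1.0)

    def test_constant_offset_gives_one(self):
        times, sf = _phase_setup()
        rng = np.random.default_rng(1)
        p1 = rng.uniform(-np.pi, np.pi, (2, times.size))
        plv = sliding_plv(p1, p1 + 1.234, sf, times)
        assert np.allclose(plv.values, 1.0)

    def test_balanced_phasors_give_zero(self):
        """Phase differences equally spaced over 2pi cancel exactly."""
        times, sf = _phase_setup()
        T = WindowGrid().n_samples(sf)
        d = 2 * np.pi * np.arange(times.size) / T
        plv = sliding_plv(d[None, :], np.zeros((1, times.size)), sf, times)
        assert np.abs(plv.values).max() < 1e-10

    def test_matches_brute_force_resultant(self):
        """Cumulative-sum windowing equals the naive per-window mean phasor."""
        times, sf = _phase_setup()
        rng = np.random.default_rng(2)
        p1 = rng.uniform(-np.pi, np.pi, (4, times.size))
        p2 = rng.uniform(-np.pi, np.pi, (4, times.size))
        grid = WindowGrid()
        plv = sliding_plv(p1, p2, sf, times, grid)
        T = grid.n_samples(sf)
        starts = grid.start_indices(times, sf)
        z = np.exp(1j * (p1 - p2))
        brute = np.stack([np.abs(z[:, s:s + T].mean(axis=1)) for s in starts],
                         axis=-1)
        assert np.max(np.abs(plv.values - brute)) < 1e-12

    def test_player_swap_symmetry(self):
        times, sf = _phase_setup()
        rng = np.random.default_rng(3)
        p1 = rng.uniform(-np.pi, np.pi, (2, times.size))
        p2 = rng.uniform(-np.pi, np.pi, (2, times.size))
        a = sliding_plv(p1, p2, sf, times)
        b = sliding_plv(p2, p1, sf, times)
        assert np.allclose(a.values, b.values)

    def test_values_in_unit_interval(self):
        times, sf = _phase_setup()
        rng = np.random.default_rng(4)
        p1 = rng.uniform(-np.pi, np.pi, (5, times.size))
        p2 = p1 + rng.normal(0, 0.1, p1.shape)
        v = sliding_plv(p1, p2, sf, times).values
        assert (v >= 0).all() and (v <= 1).all()

    def test_uniform_phases_match_rayleigh_expectation(self):
        """E[PLV] for T iid uniform phase differences is ~sqrt(pi/(4T))."""
        rng = np.random.default_rng(5)
        T = 1000
        n_win = 4000
        d = rng.uniform(-np.pi, np.pi, (n_win, T))
        r = np.abs(np.exp(1j * d).mean(axis=1))
        expected = np.sqrt(np.pi / (4 * T))
        sem = r.std(ddof=1) / np.sqrt(n_win)
        assert r.mean() == pytest.approx(expected, abs=4 * sem)


# ---------------------------------------------------------------------------
# ROI averaging and power
# ---------------------------------------------------------------------------

class TestRoiAverage:
    @staticmethod
    def _series(values):
        return PLVSeries(values, WindowGrid().centers, "gamma", list(CHANNELS))

    def test_uniform_channels_pass_through(self):
        v = np.full((2, 29, 113), 0.4)
        assert np.allclose(roi_average(self._series(v), "RP"), 0.4)

    def test_rp_mean_matches_hand_average(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(0, 1, (1, 29, 1))
        idx = [CHANNELS.index(c) for c in ("C4", "CP2", "CP6", "P4", "P8")]
        hand = v[0, idx, 0].mean()
        assert roi_average(self._series(v), "RP")[0, 0] == pytest.approx(hand)

    def test_global_uses_all_29_pairs(self):
        from duetibs.montage import roi_channels
        assert len(roi_channels("GLOBAL")) == 29
        with pytest.raises(ValueError, match="unknown ROI"):
            roi_channels("occipital")


class TestBandPower:
    @staticmethod
    def _epochs(signal):
        times = np.arange(-1.0, 16.0, 1 / SF)
        # 4 trials, one per design cell
        conds = pd.DataFrame({
            "tempo_condition": ["congruent", "congruent", "incongruent",
                                "incongruent"],
            "familiarity": ["familiar", "unfamiliar", "familiar",
                            "unfamiliar"],
        })
        data = np.tile(signal, (4, 29, 1))
        return DyadEpochs(data, data, SF, list(CHANNELS), times, conds)

    def test_tone_power_matches_envelope_convention(self):
        """A tone of amplitude A has mean squared envelope ~ A^2."""
        t = np.arange(-1.0, 16.0, 1 / SF)
        x = 2.0 * np.cos(2 * np.pi * 35 * t)
        ep = self._epochs(x)
        p = band_power(ep, "gamma", (4.0, 6.0), "RP")
        assert p == pytest.approx(np.full(4, 4.0), rel=0.02)

    def test_amplitude_doubling_quadruples_power(self):
        t = np.arange(-1.0, 16.0, 1 / SF)
        x = np.cos(2 * np.pi * 35 * t)
        p1 = band_power(self._epochs(x), "gamma", (4.0, 6.0))
        p2 = band_power(self._epochs(2 * x), "gamma", (4.0, 6.0))
        assert p2 == pytest.approx(4 * p1, rel=1e-6)

    def test_out_of_band_power_negligible(self):
        t = np.arange(-1.0, 16.0, 1 / SF)
        x = np.cos(2 * np.pi * 10 * t)
        p = band_power(self._epochs(x), "gamma", (4.0, 6.0))
        assert p.max() < 1e-4


def test_condition_means_orders_cells_canonically():
    vals = np.arange(8, dtype=float).reshape(4, 2)
    cells = np.array([3, 2, 1, 0])
    out = condition_means(vals, cells)
    assert out[0].tolist() == [6.0, 7.0]
    assert out[3].tolist() == [0.0, 1.0]
    with pytest.raises(ValueError, match="no trials"):
        condition_means(vals, np.array([0, 0, 1, 2]))
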