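"""Alpha-power regressor construction: filtering, envelope, repair, HRF."""
import numpy as np
import pytest
from scipy import signal as sps

from laminalpha import eeg_alpha as ea
from laminalpha.core import Paradigm

FS = 500.0


def _sine(freq, dur_s=20.0, fs=FS, amp=1.0):
    t = np.arange(0, dur_s, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t), t


class TestBandpass:
    def test_passband_centre_preserved(self):
        x, _ = _sine(10.0)
        y = ea.bandpass_alpha(x, FS)
        core = slice(int(2 * FS), int(18 * FS))
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("freq", [2.0, 4.0, 20.0])
    def test_stopband_attenuation_40db(self, freq):
        x, _ = _sine(freq, dur_s=60.0)
        y = ea.bandpass_alpha(x, FS)
        core = slice(int(5 * FS), int(55 * FS))
        # forward-backward 4th-order Butterworth: >= 40 dB outside the band
        assert np.abs(y[core]).max() < 10 ** (-40 / 20)

    def test_band_edges_are_alpha(self):
        # half-power points of the designed filter sit at 8 and 13 Hz
        sos = sps.butter(4, (8.0, 13.0), btype="bandpass", fs=FS, output="sos")
        w, h = sps.sosfreqz(sos, worN=2**14, fs=FS)
        gain = np.abs(h)
        for edge in (8.0, 13.0):
            assert gain[np.argmin(np.abs(w - edge))] == pytest.approx(np.sqrt(0.5), abs=0.02)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            ea.bandpass_alpha(np.zeros(100), fs_hz=20.0)


class TestEnvelope:
    def test_sinusoid_amplitude_recovered(self):
        x, _ = _sine(10.0, amp=2.0)
        env = ea.power_envelope(x, FS)
        core = slice(int(2 * FS), int(18 * FS))
        assert np.allclose(env.values[core], 2.0, rtol=0.01)

    def test_zero_input_zero_envelope(self):
        env = ea.power_envelope(np.zeros(1000), FS)
        assert np.all(env.values == 0)

    def test_am_modulator_recovered(self):
        t = np.arange(0, 30, 1 / FS)
        modulator = 1.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        x = modulator * np.sin(2 * np.pi * 10.0 * t)
        env = ea.power_envelope(x, FS)
        core = slice(int(3 * FS), int(27 * FS))
        rms = np.sqrt(np.mean((env.values[core] - modulator[core]) ** 2))
        assert rms / np.sqrt(np.mean(modulator[core] ** 2)) < 0.02

    def test_envelope_nonnegative(self):
        rng = np.random.default_rng(0)
        env = ea.power_envelope(rng.normal(size=2000), FS)
        assert (env.values >= 0).all()


def _series(values, seg_len=4, flags=None):
    return ea.AlphaPowerSeries(
        np.asarray(values, float), fs_hz=1.0, segment_len=seg_len,
        segment_flags=flags if flags is None else np.asarray(flags, bool),
    )


class TestRepairSegments:
    def test_all_clean_is_identity(self):
        s = _series(np.arange(20.0), flags=[False] * 5)
        out = ea.repair_segments(s, np.array(["open"] * 5))
        assert np.array_equal(out.values, s.values)

    def test_noisy_segment_replaced_by_window_mean(self):
        # five segments of 4 samples; segment 2 noisy, flanked by 4 clean
        vals = np.concatenate([np.full(4, m) for m in (1.0, 2.0, 99.0, 3.0, 4.0)])
        s = _series(vals, flags=[False, False, True, False, False])
        out = ea.repair_segments(s, np.array(["open"] * 5))
        assert np.allclose(out.values[8:12], np.mean([1.0, 2.0, 3.0, 4.0]))

    def test_fallback_to_condition_mean(self):
        # segment 0 noisy with a single clean neighbour in its window:
        # falls back to the run-level mean of clean segments of its condition
        vals = np.concatenate([np.full(4, m) for m in (99.0, 88.0, 5.0, 7.0, 9.0)])
        flags = [True, True, False, False, False]
        cond = np.array(["closed", "open", "open", "closed", "closed"])
        s = _series(vals, flags=flags)
        out = ea.repair_segments(s, cond)
        # brute-force candidates: window of segment 0 = {1, 2}, only one clean
        closed_clean_mean = np.mean([7.0, 9.0])
        assert np.allclose(out.values[0:4], closed_clean_mean)
        # segment 1 has >= 2 clean in its window {0(noisy), 2, 3}
        assert np.allclose(out.values[4:8], np.mean([5.0, 7.0]))

    def test_all_noisy_is_an_error(self):
        s = _series(np.arange(8.0), flags=[True, True])
        with pytest.raises(ValueError, match="noisy"):
            ea.repair_segments(s, np.array(["open", "open"]))


class TestRegressor:
    def test_constant_input_gives_zero_regressor(self, paradigm):
        s = ea.AlphaPowerSeries(
            np.full(paradigm.n_eeg_samples, 5.0), FS, paradigm.segment_len_samples
        )
        reg = ea.make_regressor(s, paradigm)
        assert np.allclose(reg.values, 0.0, atol=1e-12)

    def test_impulse_traces_double_gamma(self, paradigm):
        x = np.zeros(paradigm.n_eeg_samples)
        x[0] = 1.0
        s = ea.AlphaPowerSeries(x, FS, paradigm.segment_len_samples)
        reg = ea.make_regressor(s, paradigm)
        t_mid = paradigm.volume_midpoints()
        # closed-form expectation: HRF at the midpoints minus the drift from
        # convolving the (tiny) subtracted mean, i.e. a scaled cumulative HRF
        n = paradigm.n_eeg_samples
        t_full = np.arange(0.0, 32.0, 1 / FS)
        drift = np.cumsum(ea.double_gamma_hrf(t_full)) / n
        keep = t_mid < 30.0
        idx = (t_mid[keep] * FS).astype(int)
        expected = ea.double_gamma_hrf(t_mid[keep]) - drift[idx]
        assert np.allclose(reg.values[keep], expected, atol=1e-3)

    def test_short_series_rejected(self, paradigm):
        s = ea.AlphaPowerSeries(np.ones(100), FS, paradigm.segment_len_samples)
        with pytest.raises(ValueError, match="shorter"):
            ea.make_regressor(s, paradigm)

    def test_linearity_after_demeaning(self, paradigm):
        rng = np.random.default_rng(1)
        a = rng.random(paradigm.n_eeg_samples)
        b = rng.random(paradigm.n_eeg_samples)
        mk = lambda v: ea.make_regressor(
            ea.AlphaPowerSeries(v, FS, paradigm.segment_len_samples), paradigm
        ).values
        assert np.allclose(mk(2 * a + 3 * b), 2 * mk(a) + 3 * mk(b), atol=1e-9)

    def test_volume_rate_matches_tr(self, paradigm):
        s = ea.AlphaPowerSeries(
            np.random.default_rng(0).random(paradigm.n_eeg_samples),
            FS, paradigm.segment_len_samples,
        )
        reg = ea.make_regressor(s, paradigm)
        assert len(reg.values) == paradigm.n_vols
        assert paradigm.tr_s == 3.8  # sampled at 1/3.8 s = 0.26 Hz


class TestBoxcar:
    def test_first_block_open(self, paradigm):
        box = ea.make_boxcar(paradigm)
        # brute force: midpoint (i+0.5)*3.8 < 30 for i = 0..7
        expect = np.array([(i + 0.5) * 3.8 % 60.0 >= 30.0 for i in range(68)], float)
        assert np.array_equal(box.values, expect)
        assert np.all(box.values[:8] == 0)

    def test_closed_first_paradigm_flips_blocks(self):
        p = Paradigm(order=("closed", "open"))
        box = ea.make_boxcar(p)
        assert np.all(box.values[:8] == 1)

    def test_open_blocks_are_zero(self, paradigm):
        box = ea.make_boxcar(paradigm)
        open_mid = ~paradigm.volume_closed()
        assert np.all(box.values[open_mid] == 0)

    def test_balanced_blocks_sum_half(self, paradigm):
        box = ea.make_boxcar(paradigm)
        assert abs(box.values.sum() - paradigm.n_vols / 2) <= 4


class TestOrthogonalize:
    def test_self_orthogonalization_is_zero(self, paradigm):
        box = ea.make_boxcar(paradigm)
        out = ea.orthogonalize(box, box)
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_already_orthogonal_unchanged(self):
        n = 64
        t = np.arange(n)
        a = ea.Regressor(np.sin(2 * np.pi * t / n), "a")
        b = ea.Regressor(np.cos(2 * np.pi * t / n), "b")
        out = ea.orthogonalize(a, b)
        assert np.allclose(out.values, a.values - a.values.mean(), atol=1e-10)

    def test_residual_orthogonal_to_demeaned_boxcar(self, paradigm):
        rng = np.random.default_rng(2)
        reg = ea.Regressor(rng.normal(size=paradigm.n_vols), "alpha")
        box = ea.make_boxcar(paradigm)
        out = ea.orthogonalize(reg, box)
        box_dm = box.values - box.values.mean()
        dot = abs(out.values @ box_dm)
        assert dot < 1e-10 * np.linalg.norm(reg.values) * np.linalg.norm(box.values)

    def test_idempotent(self, paradigm):
        rng = np.random.default_rng(3)
        reg = ea.Regressor(rng.normal(size=paradigm.n_vols), "alpha")
        box = ea.make_boxcar(paradigm)
        once = ea.orthogonalize(reg, box)
        twice = ea.orthogonalize(once, box)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_constant_target_rejected(self, paradigm):
        reg = ea.Regressor(np.arange(paradigm.n_vols, dtype=float), "alpha")
        const = ea.Regressor(np.ones(paradigm.n_vols), "c")
        with pytest.raises(ValueError):
            ea.orthogonalize(reg, const)


class TestCompareConditions:
    def test_identical_conditions_give_t0_p1(self, paradigm):
        s = ea.AlphaPowerSeries(
            np.ones(paradigm.n_eeg_samples), FS, paradigm.segment_len_samples
        )
        res = ea.compare_conditions(s, paradigm)
        assert res.t == 0.0 and res.p == 1.0

    def test_modulated_alpha_detected(self, paradigm):
        from laminalpha import synthdata as sd

        hits = 0
        for seed in range(20):
            s = sd.make_alpha_timecourse(
                paradigm, modulation_depth=0.5, noise_sd=0.05, seed=seed
            )
            res = ea.compare_conditions(s, paradigm)
            hits += (res.p < 0.05) and (res.mean_closed > res.mean_open)
        assert hits >= 18  # eyes-closed power reliably exceeds eyes-open

    def test_too_few_pairs_rejected(self):
        p = Paradigm(block_len_s=30.0, n_cycles=1, n_vols=17)
        s = ea.AlphaPowerSeries(np.ones(p.n_eeg_samples), FS, p.segment_len_samples)
        with pytest.raises(ValueError):
            ea.compare_conditions(s, p)
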