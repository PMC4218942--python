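"""Epoching, deviance responses, back-projection, pvaf and peak scoring."""

import numpy as np
import pytest
from scipy.special import erf

from devsource.data_io import DEVIANT, STANDARD, EventSequence, ValidationError
from devsource.deviance import (
    PEAK_POLARITY,
    PEAK_WINDOWS,
    backproject,
    condition_erps,
    deviance_response,
    epoch_average,
    fz_reference_measures,
    pvaf,
    score_peaks,
    signed_rms_trace,
)

FS = 500.0


def events_alternating(n, step=500):
    onsets = 200 + np.arange(n) * step
    codes = [DEVIANT if i % 5 == 0 else STANDARD for i in range(n)]
    return EventSequence(onsets, codes)


def gaussian_wave(times_ms, amp, lat, width):
    return amp * np.exp(-0.5 * ((times_ms - lat) / width) ** 2)


class TestEpochAverage:
    def test_identical_epochs_recovered_minus_baseline(self):
        template = np.sin(np.linspace(0, 6 * np.pi, 300))
        data = np.zeros(20_000)
        ev = np.arange(5) * 2000 + 500
        for o in ev:
            data[o - 50 : o + 250] = template  # epoch is -100..500 ms = 300 samples
        times, erp, n = epoch_average(data, FS, ev)
        assert n == 5
        expected = template - template[:50].mean()
        assert np.allclose(erp[0], expected, atol=1e-12)

    def test_baseline_mean_zero_after_correction(self, rng):
        data = rng.standard_normal((3, 30_000)) + 5.0
        ev = 300 + np.arange(20) * 1000
        times, erp, _ = epoch_average(data, FS, ev)
        assert np.allclose(erp[:, times < 0].mean(axis=1), 0.0, atol=1e-12)

    def test_averaging_reduces_noise_as_sqrt_n(self, rng):
        data = rng.standard_normal((1, 500_000))
        ev = 200 + np.arange(400) * 1200
        times, erp, n = epoch_average(data, FS, ev)
        assert n == 400
        ratio = erp.std() / data.std()
        assert abs(ratio - 1.0 / np.sqrt(400)) < 0.2 / np.sqrt(400) * 5

    def test_zero_retained_trials_errors_with_condition_name(self):
        data = np.zeros((1, 1000))
        with pytest.raises(ValidationError, match="deviant"):
            epoch_average(data, FS, np.array([], dtype=int), label="deviant")

    def test_epochs_overlapping_rejected_samples_skipped(self, rng):
        data = rng.standard_normal((1, 20_000))
        mask = np.ones(20_000, bool)
        mask[3000:3500] = False
        ev = np.array([1000, 3100, 5000])
        _, _, n = epoch_average(data, FS, ev, retained_mask=mask)
        assert n == 2


class TestDevianceResponse:
    def test_identical_conditions_give_zero(self, rng):
        data = rng.standard_normal((2, 30_000))
        ev = events_alternating(25)
        erps = condition_erps(data, FS, ev)
        erps.waves[DEVIANT] = erps.waves[STANDARD].copy()
        assert np.allclose(deviance_response(erps), 0.0)

    def test_planted_bump_appears_in_difference(self, rng):
        n = 60_000
        data = 0.1 * rng.standard_normal((1, n))
        ev = events_alternating(100, step=500)
        kernel_t = np.arange(0, 250) / FS * 1000.0
        bump = gaussian_wave(kernel_t, -2.0, 180.0, 25.0)
        for o, c in zip(ev.onsets, ev.codes):
            if c == DEVIANT and o + 250 <= n:
                data[0, o : o + 250] += bump
        erps = condition_erps(data, FS, ev)
        diff = deviance_response(erps)[0]
        times = erps.times_ms
        sel = times >= 0
        recovered = diff[sel][: bump.size]
        assert np.abs(recovered - bump).max() < 0.25

    def test_linearity_sum_of_differences(self, rng):
        data = rng.standard_normal((3, 30_000))
        ev = events_alternating(25)
        erps = condition_erps(data, FS, ev)
        diff = deviance_response(erps)
        assert np.allclose(diff.sum(axis=0), deviance_response(erps).sum(axis=0))


class TestBackprojection:
    def test_unit_map_routes_erp_to_single_channel(self):
        maps = np.zeros((5, 1))
        maps[2, 0] = 1.0
        erp = np.sin(np.linspace(0, np.pi, 100))[None, :]
        bp = backproject(maps, erp)
        assert np.allclose(bp[2], erp[0])
        assert np.allclose(np.delete(bp, 2, axis=0), 0.0)

    def test_sign_flip_of_member_pair_invariant(self, rng):
        maps = rng.standard_normal((6, 3))
        erps = rng.standard_normal((3, 80))
        bp1 = backproject(maps, erps)
        maps2 = maps.copy()
        erps2 = erps.copy()
        maps2[:, 1] *= -1
        erps2[1] *= -1
        assert np.allclose(bp1, backproject(maps2, erps2))

    def test_all_ic_backprojection_completeness(self, rng):
        """Back-projecting every IC reproduces the mixed data exactly."""
        A = rng.standard_normal((6, 6))
        S = rng.standard_normal((6, 500))
        X = A @ S
        bp = backproject(A, S)
        assert np.linalg.norm(bp - X) / np.linalg.norm(X) < 1e-12

    def test_signed_rms_trace_sign_convention(self):
        maps = np.array([[1.0], [0.2]])
        erp = -np.ones((1, 10))
        bp = backproject(maps, erp)
        trace = signed_rms_trace(bp, maps[:, 0])
        assert np.all(trace < 0)  # dominant channel is negative


class TestPvaf:
    def test_component_equal_total_gives_100(self, rng):
        x = rng.standard_normal((4, 100))
        assert pvaf(x, x) == pytest.approx(100.0)

    def test_zero_component_gives_0(self, rng):
        x = rng.standard_normal((4, 100))
        assert pvaf(np.zeros_like(x), x) == pytest.approx(0.0)

    def test_anti_correlated_component_direct_formula(self, rng):
        # component -x doubles the residual: pvaf = 100·(1 − var(2x)/var(x)) = −300
        x = rng.standard_normal((1, 200))
        x -= x.mean()
        expected = 100.0 * (1.0 - np.var(2 * x) / np.var(x))
        assert pvaf(-x, x) == pytest.approx(expected)
        assert expected == pytest.approx(-300.0)

    def test_orthogonal_equal_variance_component(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        total = np.sin(t)[None, :]
        comp = np.cos(t)[None, :]
        assert pvaf(comp, total) == pytest.approx(-100.0, abs=1e-9)

    def test_zero_total_variance_errors(self):
        with pytest.raises(ValidationError):
            pvaf(np.zeros((1, 10)), np.zeros((1, 10)))

    def test_disjoint_components_close_to_total(self, rng):
        """Union of all components plus remainder accounts for 100 %."""
        parts = rng.standard_normal((5, 3, 120))
        total = parts.sum(axis=0)
        assert pvaf(parts.sum(axis=0), total) == pytest.approx(100.0)


class TestPeakScoring:
    def _times(self):
        return np.arange(-50, 251) * 2.0  # -100..500 ms at 500 Hz

    def test_gaussian_bump_latency_exact_amplitude_analytic(self):
        times = self._times()
        wave = gaussian_wave(times, -2.0, 190.0, 20.0)
        ps = score_peaks(times, wave)
        mmn = ps["MMN"]
        assert mmn.latency_ms == 190.0
        assert not mmn.edge
        # closed-form mean over ±10 ms of a Gaussian bump
        s = 20.0
        analytic = -2.0 * s * np.sqrt(2 * np.pi) / 20.0 * (
            0.5 * (erf(10.0 / (s * np.sqrt(2))) - erf(-10.0 / (s * np.sqrt(2))))
        )
        assert mmn.amplitude == pytest.approx(analytic, rel=0.01)

    def test_zero_waveform_edge_flagged_latencies_at_window_start(self):
        times = self._times()
        ps = score_peaks(times, np.zeros_like(times))
        for label, (lo, _) in PEAK_WINDOWS.items():
            p = ps[label]
            assert p.amplitude == 0.0
            assert p.edge
            assert p.latency_ms == pytest.approx(lo, abs=2.0)

    def test_default_windows(self):
        assert PEAK_WINDOWS == {
            "MMN": (140.0, 240.0),
            "P3a": (220.0, 340.0),
            "RON": (310.0, 460.0),
        }
        assert PEAK_POLARITY == {"MMN": -1, "P3a": +1, "RON": -1}

    def test_shift_equivariance(self):
        times = self._times()
        w1 = gaussian_wave(times, -1.5, 180.0, 15.0)
        w2 = gaussian_wave(times, -1.5, 190.0, 15.0)
        l1 = score_peaks(times, w1)["MMN"].latency_ms
        l2 = score_peaks(times, w2)["MMN"].latency_ms
        assert l2 - l1 == pytest.approx(10.0)

    def test_free_polarity_mode(self):
        times = self._times()
        wave = gaussian_wave(times, +3.0, 190.0, 15.0)  # inverted MMN
        nominal = score_peaks(times, wave)["MMN"]
        free = score_peaks(times, wave, polarity="free")["MMN"]
        assert free.latency_ms == 190.0
        assert free.amplitude > 0
        assert nominal.amplitude <= free.amplitude

    def test_waveform_must_cover_windows(self):
        times = np.arange(0, 100) * 2.0
        with pytest.raises(ValidationError):
            score_peaks(times, np.zeros(100))


class TestFzMeasures:
    def test_scoring_is_source_agnostic(self, montage68, rng):
        times = np.arange(-50, 251) * 2.0
        wave = gaussian_wave(times, -2.0, 200.0, 25.0) + gaussian_wave(times, 1.5, 280.0, 25.0)
        n_ch = 68
        waves_std = np.zeros((n_ch, times.size))
        waves_dev = np.zeros((n_ch, times.size))
        waves_dev[montage68.index("Fz")] = wave
        from devsource.deviance import ERPSet

        erps = ERPSet(
            times_ms=times,
            waves={STANDARD: waves_std, DEVIANT: waves_dev},
            trial_counts={STANDARD: 10, DEVIANT: 10},
        )
        fz = fz_reference_measures(erps, montage68)
        direct = score_peaks(times, wave)
        for label in PEAK_WINDOWS:
            assert fz[label].latency_ms == direct[label].latency_ms
            assert fz[label].amplitude == pytest.approx(direct[label].amplitude)

    def test_missing_fz_channel_rejected(self, montage68, rng):
        from devsource.data_io import Montage
        from devsource.deviance import ERPSet

        small = montage68.subset(["Cz", "Pz"])
        times = np.arange(-50, 251) * 2.0
        erps = ERPSet(
            times_ms=times,
            waves={STANDARD: np.zeros((2, times.size)), DEVIANT: np.zeros((2, times.size))},
            trial_counts={STANDARD: 1, DEVIANT: 1},
        )
        with pytest.raises(ValidationError):
            fz_reference_measures(erps, small)

    def test_group_polarity_on_synthetic_cohort(self):
        """NCS Fz-region MMN is negative; SZ amplitudes shrink toward zero
        in the direction of the planted group scaling."""
        from devsource.synth import CohortConfig, generate_subject

        cfg = CohortConfig(
            n_subjects={"NCS": 1, "SZ": 1},
            session_min=4.0,
            montage="standard-32",
            amplitude_jitter_frac=0.0,
            latency_jitter_ms=0.0,
            seed=11,
        )
        amps = {}
        for group in ("NCS", "SZ"):
            rec, _ = generate_subject(cfg, group, group, 11)
            erps = condition_erps(rec.data, rec.fs, rec.events)
            diff = deviance_response(erps)
            fz = rec.channel_names.index("Fz")
            ps = score_peaks(erps.times_ms, diff[fz])
            amps[group] = ps["MMN"].amplitude
        assert amps["NCS"] < 0
        assert amps["NCS"] < amps["SZ"] + 0.2  # SZ deficit direction
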