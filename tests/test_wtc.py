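"""Morlet wavelet coherence: transform localization, coherence/phase
conventions, red-noise significance calibration, and the time-averaged
coherence statistic against counting oracles."""

import numpy as np
import pytest

from bercvr import wtc
from bercvr.wtc import (FOURIER_FACTOR, WTCResult, ar1_series, band_mean_tac,
                        cwt_morlet, fit_ar1, montecarlo_threshold,
                        time_averaged_coherence, wavelet_coherence)

DT = 0.5


@pytest.fixture(scope="module")
def sin_pair():
    """64 s sinusoid and its quarter-period-delayed copy."""
    t = np.arange(1024) * DT
    x = np.sin(2 * np.pi * t / 64.0)
    y = np.sin(2 * np.pi * (t - 16.0) / 64.0)  # y lags x by P/4
    return t, x, y


class TestCWT:
    def test_sinusoid_peak_at_driving_period(self, sin_pair):
        t, x, _ = sin_pair
        W, scales, periods = cwt_morlet(x, DT)
        amp = np.abs(W[:, len(t) // 2])
        peak = periods[np.argmax(amp)]
        step = periods[1] / periods[0]
        assert peak / 64.0 < step and 64.0 / peak < step

    def test_agrees_with_pywavelets_peak(self, sin_pair):
        """Independent implementation check: pywavelets' complex Morlet
        localizes the same 64 s component."""
        import pywt
        _, x, _ = sin_pair
        wavelet = "cmor2.0-0.9549"  # bandwidth 2, center freq 6/(2*pi)
        scales = np.arange(8, 300)
        coefs, freqs = pywt.cwt(x, scales, wavelet, sampling_period=DT)
        amp = np.abs(coefs[:, 512])
        assert 1.0 / freqs[np.argmax(amp)] == pytest.approx(64.0, rel=0.05)

    def test_zero_series_zero_coefficients(self):
        W, _, _ = cwt_morlet(np.zeros(512), DT)
        assert np.allclose(np.abs(W), 0.0)

    def test_impulse_energy_localized_in_time(self):
        x = np.zeros(1024)
        x[600] = 1.0
        W, scales, periods = cwt_morlet(x, DT)
        for j in (10, 30, 50):
            amp = np.abs(W[j])
            # energy concentrated within the e-folding time of the scale
            half_width = np.sqrt(2) * scales[j] / DT
            lo, hi = int(600 - 3 * half_width), int(600 + 3 * half_width)
            inside = amp[max(lo, 0):hi].sum()
            assert inside / amp.sum() > 0.99

    def test_long_periods_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            _, _, periods = cwt_morlet(np.random.default_rng(0).standard_normal(256),
                                       DT, period_range_s=(4.0, 1024.0))
        assert periods.max() <= 256 * DT


class TestCoherence:
    def test_self_coherence_is_one(self, rng):
        x = np.cumsum(rng.standard_normal(1024))
        w = wavelet_coherence(x, x, DT)
        assert w.coherence[w.off_coi].min() >= 0.99

    def test_bounded_unit_interval(self, rng):
        w = wavelet_coherence(rng.standard_normal(512),
                              rng.standard_normal(512), DT)
        assert w.coherence.min() >= 0.0 and w.coherence.max() <= 1.0

    def test_quarter_period_shift_phase(self, sin_pair):
        _, x, y = sin_pair
        w = wavelet_coherence(x, y, DT)
        j = int(np.argmin(np.abs(w.periods - 64.0)))
        ph = w.phase[j, w.off_coi[j]]
        # x leads y by a quarter period -> phase +pi/2 by convention
        assert np.abs(np.median(ph)) == pytest.approx(np.pi / 2, abs=0.1)
        assert np.median(ph) > 0

    def test_phase_antisymmetric_under_swap(self, rng):
        # broadband inputs so the cross-spectrum has power at every scale
        x = np.cumsum(rng.standard_normal(512))
        y = np.cumsum(rng.standard_normal(512))
        a = wavelet_coherence(x, y, DT)
        b = wavelet_coherence(y, x, DT)
        sel = a.off_coi
        # compare on the circle: +pi and -pi are the same angle
        wrapped = np.angle(np.exp(1j * (a.phase[sel] + b.phase[sel])))
        assert np.allclose(wrapped, 0.0, atol=1e-9)

    def test_independent_noise_low_median_coherence(self):
        rng = np.random.default_rng(5)
        w = wavelet_coherence(rng.standard_normal(1024),
                              rng.standard_normal(1024), DT)
        assert np.median(w.coherence[w.off_coi]) < 0.5

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            wavelet_coherence(np.ones(100), np.ones(101), DT)

    def test_coi_shrinks_toward_edges(self, rng):
        w = wavelet_coherence(rng.standard_normal(512),
                              rng.standard_normal(512), DT)
        mid = len(w.times) // 2
        assert w.coi[0] < w.coi[mid] and w.coi[-1] < w.coi[mid]


class TestMonteCarlo:
    def test_ar1_fit_recovers_coefficient(self, rng):
        x = ar1_series(0.6, 20000, rng)
        assert fit_ar1(x) == pytest.approx(0.6, abs=0.05)

    def test_thresholds_within_unit_interval(self, rng):
        x = ar1_series(0.3, 256, rng)
        y = ar1_series(0.3, 256, rng)
        thr = montecarlo_threshold(x, y, n_surrogates=100, dt=DT, seed=1)
        ok = np.isfinite(thr)
        assert ok.any()
        assert (thr[ok] > 0).all() and (thr[ok] < 1).all()

    def test_redder_noise_raises_long_period_thresholds(self, rng):
        n = 512
        thr_white = montecarlo_threshold(ar1_series(0.0, n, rng),
                                         ar1_series(0.0, n, rng),
                                         n_surrogates=100, dt=DT, seed=3)
        thr_red = montecarlo_threshold(ar1_series(0.9, n, rng),
                                       ar1_series(0.9, n, rng),
                                       n_surrogates=100, dt=DT, seed=3)
        ok = np.isfinite(thr_white) & np.isfinite(thr_red)
        long_p = ok & (np.arange(len(thr_white)) > 36)  # periods > ~32 s
        assert np.mean(thr_red[long_p] >= thr_white[long_p]) > 0.5

    def test_too_few_surrogates_rejected(self, rng):
        with pytest.raises(ValueError):
            montecarlo_threshold(np.ones(64), np.ones(64), n_surrogates=10,
                                 dt=DT, seed=0)


def constructed_wtc(coherence, phase, threshold=0.5, n_scales=4, n_times=200):
    """A WTCResult with hand-set fields and a COI that keeps the middle half
    of the record valid at every scale."""
    periods = np.array([8.0, 16.0, 32.0, 64.0])[:n_scales]
    times = np.arange(n_times) * 1.0
    coi = np.full(n_times, 0.0)
    coi[n_times // 4: 3 * n_times // 4] = 1000.0
    return WTCResult(scales=periods / FOURIER_FACTOR, periods=periods,
                     freqs=1 / periods, times=times,
                     coherence=np.broadcast_to(coherence,
                                               (n_scales, n_times)).copy(),
                     phase=np.broadcast_to(phase, (n_scales, n_times)).copy(),
                     coi=coi, sig_threshold=np.full(n_scales, threshold))


class TestTAC:
    def test_full_coherence_gives_unit_tac(self):
        w = constructed_wtc(1.0, 0.2)  # all significant, phase in 0+ quadrant
        tac = time_averaged_coherence(w, quadrant="0+")
        assert np.allclose(tac.tac[tac.valid], 1.0)

    def test_nothing_significant_gives_zero(self):
        w = constructed_wtc(0.3, 0.2, threshold=0.5)
        tac = time_averaged_coherence(w, quadrant="0")
        assert np.allclose(tac.tac[tac.valid], 0.0)

    def test_half_valid_points_at_unit_coherence(self):
        """Counting oracle: half the off-COI points at significant coherence
        1, half at 0 -> TAC exactly 0.5."""
        w = constructed_wtc(0.0, 0.1)
        w.coherence[:, ::2] = 1.0
        tac = time_averaged_coherence(w, quadrant="0")
        assert np.allclose(tac.tac[tac.valid], 0.5)

    def test_fully_in_coi_scale_flagged(self):
        w = constructed_wtc(1.0, 0.1)
        w.coi[:] = 10.0  # only the two shortest periods survive
        tac = time_averaged_coherence(w, quadrant="0")
        assert tac.valid[0] and not tac.valid[3]
        assert np.isnan(tac.tac[3])

    def test_quadrant_partition_with_shared_denominator(self, rng):
        x = np.cumsum(rng.standard_normal(512))
        y = np.cumsum(rng.standard_normal(512))
        w = wavelet_coherence(x, y, DT)
        w.sig_threshold = np.full(len(w.scales), 0.4)
        parts = [time_averaged_coherence(w, q, shared_denominator=True).tac
                 for q in ("0+", "0-", "pi+", "pi-")]
        total = time_averaged_coherence(w, "0", shared_denominator=True).tac + \
            time_averaged_coherence(w, "pi", shared_denominator=True).tac
        s = np.nansum(parts, axis=0)
        ok = ~np.isnan(total)
        assert np.allclose(s[ok], total[ok], atol=1e-12)

    def test_requires_threshold(self, rng):
        w = wavelet_coherence(rng.standard_normal(256),
                              rng.standard_normal(256), DT)
        with pytest.raises(ValueError, match="threshold"):
            time_averaged_coherence(w)


class TestBandMean:
    def test_constant_tac_band_mean(self):
        w = constructed_wtc(1.0, 0.2)
        w.coherence[:] = 0.6
        w.sig_threshold = np.full(4, 0.5)
        tac = time_averaged_coherence(w, quadrant="0")
        got = band_mean_tac(tac, band_hz=(1 / 70.0, 1 / 7.0))
        assert got == pytest.approx(0.6)

    def test_band_uses_expected_period_range(self):
        """On the default dyadic grid the 0.008-0.03 Hz band touches only
        scales with periods between ~33 s and 125 s."""
        _, _, periods = cwt_morlet(np.random.default_rng(0).standard_normal(2048),
                                   DT)
        sel = (1.0 / periods >= 0.008) & (1.0 / periods <= 0.03)
        assert periods[sel].min() >= 33.0
        assert periods[sel].max() <= 125.0
        assert sel.sum() >= 10  # 12 scales/octave over ~2 octaves

    def test_band_limited_coupling_detected(self):
        """A pair coupled only at 64 s shows band-mean TAC far larger in the
        0.008-0.03 Hz band than at 0.06-0.25 Hz."""
        rng = np.random.default_rng(2)
        t = np.arange(1024) * DT
        common = np.sin(2 * np.pi * t / 64.0)
        x = common + 0.3 * rng.standard_normal(1024)
        y = common + 0.3 * rng.standard_normal(1024)
        w = wavelet_coherence(x, y, DT)
        w.sig_threshold = montecarlo_threshold(x, y, n_surrogates=100, dt=DT,
                                               seed=4)
        tac = time_averaged_coherence(w, quadrant="0")
        low = band_mean_tac(tac, (0.008, 0.03))
        high = band_mean_tac(tac, (0.06, 0.25))
        assert low > 5 * high

    def test_empty_band_rejected(self):
        w = constructed_wtc(1.0, 0.2)
        tac = time_averaged_coherence(w, quadrant="0")
        with pytest.raises(ValueError, match="band"):
            band_mean_tac(tac, band_hz=(10.0, 20.0))
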