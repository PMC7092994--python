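"""Wavelet transform coherence (WTC) with red-noise Monte Carlo significance.

Continuous Morlet transform (omega0 = 6) on a dyadic scale grid, squared
coherence with the standard scale-dependent smoothing (Gaussian in time with
width proportional to scale, 0.6-octave boxcar across scale), cone of
influence from the wavelet's e-folding time, per-scale 95% significance
thresholds estimated from AR(1) surrogate pairs, and the time-averaged
coherence (TAC) statistic: per scale, the total significant off-COI coherence
within a phase-lag quadrant normalized by the maximum possible coherence
(all valid points at 1).

Phase convention: positive phase means the first series leads the second;
swapping the inputs negates the phase matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

OMEGA0 = 6.0
#: equivalent Fourier period per unit scale for the omega0=6 Morlet
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0 ** 2))

#: half-open phase-lag quadrants, (lo, hi] on (-pi, pi]
QUADRANTS = {
    "0+": (0.0, np.pi / 2),
    "0-": (-np.pi / 2, 0.0),
    "pi-": (np.pi / 2, np.pi),
    "pi+": (-np.pi, -np.pi / 2),
    "0": (-np.pi / 2, np.pi / 2),    # in-phase pair 0 +/- pi/2
    "pi": (np.pi / 2, 3 * np.pi / 2),  # anti-phase pair pi +/- pi/2 (wraps)
}


@dataclass
class WTCResult:
    scales: np.ndarray          # wavelet scales, seconds
    periods: np.ndarray         # equivalent Fourier periods, seconds
    freqs: np.ndarray           # Hz, 1/period
    times: np.ndarray           # seconds
    coherence: np.ndarray       # (n_scales, n_times) in [0, 1]
    phase: np.ndarray           # (n_scales, n_times) in (-pi, pi]
    coi: np.ndarray             # per-time maximum reliable period, seconds
    sig_threshold: np.ndarray | None = None  # per-scale 95% coherence level
    meta: dict = field(default_factory=dict)

    @property
    def off_coi(self) -> np.ndarray:
        """Boolean (n_scales, n_times): True where outside the cone."""
        return self.periods[:, None] <= self.coi[None, :]

    @property
    def significant(self) -> np.ndarray:
        if self.sig_threshold is None:
            raise ValueError("no significance threshold attached")
        return self.coherence > self.sig_threshold[:, None]


@dataclass
class TACProfile:
    freqs: np.ndarray
    periods: np.ndarray
    tac: np.ndarray       # NaN where the scale is fully inside the COI
    quadrant: str
    valid: np.ndarray     # bool per scale


def _scale_grid(dt: float, n: int, scales_per_octave: int,
                period_range_s: tuple[float, float]) -> np.ndarray:
    lo, hi = period_range_s
    if lo <= 0 or hi <= lo:
        raise ValueError("invalid period range")
    record = n * dt
    if hi > record:
        warnings.warn("period range exceeds record length; scales truncated")
        hi = record
    s0 = lo / FOURIER_FACTOR
    n_scales = int(np.floor(scales_per_octave * np.log2(hi / lo))) + 1
    return s0 * 2.0 ** (np.arange(n_scales) / scales_per_octave)


def cwt_morlet(
    x: np.ndarray,
    dt: float,
    scales_per_octave: int = 12,
    period_range_s: tuple[float, float] = (4.0, 256.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FFT-based Morlet CWT on a dyadic scale grid.

    Returns (W, scales, periods) with W of shape (n_scales, n).  The input is
    zero-meaned; the record is zero-padded to the next power of two to limit
    wrap-around.  Fourier period = scale * 4*pi / (omega0 + sqrt(2+omega0^2)).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    scales = _scale_grid(dt, n, scales_per_octave, period_range_s)
    if n < 2 * period_range_s[0] / dt:
        raise ValueError("record shorter than two cycles of the smallest period")
    npad = int(2 ** np.ceil(np.log2(n)))
    xa = np.zeros(npad)
    xa[:n] = x - x.mean()
    xh = np.fft.fft(xa)
    k = np.fft.fftfreq(npad, d=dt) * 2.0 * np.pi  # angular frequency
    W = np.empty((len(scales), n), dtype=complex)
    norm_const = np.pi ** -0.25
    for j, s in enumerate(scales):
        psi_hat = np.zeros(npad)
        pos = k > 0
        psi_hat[pos] = (norm_const * np.sqrt(2.0 * np.pi * s / dt)
                        * np.exp(-0.5 * (s * k[pos] - OMEGA0) ** 2))
        W[j] = np.fft.ifft(xh * psi_hat)[:n]
    periods = scales * FOURIER_FACTOR
    return W, scales, periods


def _smooth(field: np.ndarray, scales: np.ndarray, dt: float,
            scales_per_octave: int, boxcar_octaves: float = 0.6) -> np.ndarray:
    """Grinsted-style smoothing: per-scale Gaussian in time (sd = scale),
    then a 0.6-octave boxcar across scale."""
    out = np.empty_like(field)
    for j, s in enumerate(scales):
        sigma = s / dt
        if np.iscomplexobj(field):
            out[j] = (gaussian_filter1d(field[j].real, sigma, mode="reflect")
                      + 1j * gaussian_filter1d(field[j].imag, sigma, mode="reflect"))
        else:
            out[j] = gaussian_filter1d(field[j], sigma, mode="reflect")
    win = max(1, int(round(boxcar_octaves * scales_per_octave)))
    if np.iscomplexobj(field):
        out = (uniform_filter1d(out.real, win, axis=0, mode="nearest")
               + 1j * uniform_filter1d(out.imag, win, axis=0, mode="nearest"))
    else:
        out = uniform_filter1d(out, win, axis=0, mode="nearest")
    return out


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    dt: float,
    scales_per_octave: int = 12,
    period_range_s: tuple[float, float] = (4.0, 256.0),
    boxcar_octaves: float = 0.6,
) -> WTCResult:
    """Squared wavelet coherence and phase between two equal-length series.

    R^2 = |S(Wxy/s)|^2 / (S(|Wx|^2/s) * S(|Wy|^2/s)); a localized squared
    correlation coefficient in time-frequency space, in [0, 1].
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("mismatched series lengths")
    n = len(x)
    Wx, scales, periods = cwt_morlet(x, dt, scales_per_octave, period_range_s)
    Wy, _, _ = cwt_morlet(y, dt, scales_per_octave, period_range_s)
    inv_s = 1.0 / scales[:, None]
    sx = _smooth(np.abs(Wx) ** 2 * inv_s, scales, dt, scales_per_octave, boxcar_octaves)
    sy = _smooth(np.abs(Wy) ** 2 * inv_s, scales, dt, scales_per_octave, boxcar_octaves)
    sxy = _smooth(Wx * np.conj(Wy) * inv_s, scales, dt, scales_per_octave, boxcar_octaves)
    coh = np.abs(sxy) ** 2 / (sx * sy + 1e-300)
    coh = np.clip(coh, 0.0, 1.0)
    phase = np.angle(sxy)
    times = np.arange(n) * dt
    dist = np.minimum(times - times[0], times[-1] - times)
    coi = FOURIER_FACTOR / np.sqrt(2.0) * np.maximum(dist, dt / 2)
    return WTCResult(scales=scales, periods=periods, freqs=1.0 / periods,
                     times=times, coherence=coh, phase=phase, coi=coi,
                     meta={"dt": dt, "scales_per_octave": scales_per_octave,
                           "period_range_s": tuple(period_range_s),
                           "boxcar_octaves": boxcar_octaves})


def fit_ar1(x: np.ndarray) -> float:
    """Lag-1 autocorrelation, clipped to |phi| <= 0.99 with a warning."""
    x = np.asarray(x, float)
    x = x - x.mean()
    denom = np.dot(x, x)
    if denom == 0:
        return 0.0
    phi = float(np.dot(x[1:], x[:-1]) / denom)
    if abs(phi) >= 1.0:
        warnings.warn("AR(1) fit |phi| >= 1; clipped to 0.99")
        phi = np.sign(phi) * 0.99
    return phi


def ar1_series(phi: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1) series (stationary start)."""
    innov = rng.standard_normal(n) * np.sqrt(1.0 - phi ** 2)
    out = np.empty(n)
    out[0] = rng.standard_normal()
    for i in range(1, n):
        out[i] = phi * out[i - 1] + innov[i]
    return out


def montecarlo_threshold(
    x: np.ndarray,
    y: np.ndarray,
    n_surrogates: int = 300,
    dt: float = 0.5,
    seed: int = 0,
    scales_per_octave: int = 12,
    period_range_s: tuple[float, float] = (4.0, 256.0),
    boxcar_octaves: float = 0.6,
) -> np.ndarray:
    """Per-scale 95% coherence level against red noise.

    AR(1) coefficients are fitted to both inputs (lag-1 autocorrelation);
    surrogate pairs with those coefficients are generated independently
    (both series randomized), their coherence computed with identical
    smoothing, and the 95th percentile of off-COI coherence values pooled
    over time and surrogates is taken per scale.
    """
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogates")
    phi_x, phi_y = fit_ar1(x), fit_ar1(y)
    n = len(x)
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] | None = None
    for _ in range(n_surrogates):
        sx = ar1_series(phi_x, n, rng)
        sy = ar1_series(phi_y, n, rng)
        w = wavelet_coherence(sx, sy, dt, scales_per_octave, period_range_s,
                              boxcar_octaves)
        off = w.off_coi
        if pooled is None:
            pooled = [[] for _ in range(len(w.scales))]
        for j in range(len(w.scales)):
            pooled[j].append(w.coherence[j, off[j]].astype(np.float32))
    thresholds = np.array([
        np.percentile(np.concatenate(vals), 95.0) if any(len(v) for v in vals)
        else np.nan
        for vals in pooled
    ])
    return thresholds


def attach_significance(wtc: WTCResult, x: np.ndarray, y: np.ndarray,
                        n_surrogates: int = 300, seed: int = 0) -> WTCResult:
    """Compute and attach the Monte Carlo threshold matching wtc's grid."""
    wtc.sig_threshold = montecarlo_threshold(
        x, y, n_surrogates=n_surrogates, dt=wtc.meta["dt"], seed=seed,
        scales_per_octave=wtc.meta["scales_per_octave"],
        period_range_s=wtc.meta["period_range_s"],
        boxcar_octaves=wtc.meta["boxcar_octaves"])
    return wtc


def _in_quadrant(phase: np.ndarray, quadrant: str) -> np.ndarray:
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}; one of {sorted(QUADRANTS)}")
    lo, hi = QUADRANTS[quadrant]
    if quadrant == "pi":  # wraps through +/-pi
        return (phase > lo) | (phase <= hi - 2 * np.pi)
    return (phase > lo) & (phase <= hi)


def time_averaged_coherence(
    wtc: WTCResult,
    quadrant: str = "0",
    shared_denominator: bool = False,
    normalization: str = "count",
) -> TACProfile:
    """TAC per scale within a phase-lag quadrant.

    tac(s) = sum of significant off-COI coherence with phase in the quadrant,
    divided by the maximum possible coherence at that scale: the number of
    off-COI points in the quadrant (count normalization; every point at
    coherence 1), or the sum of the per-scale threshold over those points
    (``normalization='threshold_sum'``).  ``shared_denominator=True`` uses
    all off-COI points regardless of phase, making the four quadrants an
    exact partition of the unrestricted TAC.  Scales entirely inside the COI
    are flagged invalid (NaN).
    """
    if wtc.sig_threshold is None:
        raise ValueError("attach a significance threshold first")
    if normalization not in ("count", "threshold_sum"):
        raise ValueError("normalization must be 'count' or 'threshold_sum'")
    off = wtc.off_coi
    sig = wtc.significant
    inq = _in_quadrant(wtc.phase, quadrant)
    n_scales = len(wtc.scales)
    tac = np.full(n_scales, np.nan)
    valid = np.zeros(n_scales, dtype=bool)
    for j in range(n_scales):
        denom_pts = off[j] if shared_denominator else (off[j] & inq[j])
        if not off[j].any() or not denom_pts.any():
            continue
        num = float(np.sum(wtc.coherence[j] * (sig[j] & off[j] & inq[j])))
        if normalization == "count":
            den = float(np.count_nonzero(denom_pts))
        else:
            den = float(np.count_nonzero(denom_pts) * wtc.sig_threshold[j])
        tac[j] = num / den
        valid[j] = True
    return TACProfile(freqs=wtc.freqs, periods=wtc.periods, tac=tac,
                      quadrant=quadrant, valid=valid)


def band_mean_tac(tac: TACProfile, band_hz: tuple[float, float] = (0.008, 0.03)) -> float:
    """Mean TAC over valid scales with frequency inside [lo, hi] Hz."""
    lo, hi = band_hz
    sel = (tac.freqs >= lo) & (tac.freqs <= hi) & tac.valid
    if not sel.any():
        raise ValueError("no valid scales in the requested band")
    return float(np.mean(tac.tac[sel]))
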