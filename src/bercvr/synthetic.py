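"""Synthetic breath-hold study data with known ground truth.

Emulates the measurement chain of a breath-hold CVR study: a visual-cue
protocol (six ~30 s holds interleaved with 60-90 s free breathing over about
ten minutes, or an exogenous-CO2 arm with alternating +4/+8 mmHg hypercapnic
steps), nasal-line PO2/PCO2 traces with per-breath end-tidal plateaus,
pulsatile middle-cerebral-artery velocity whose mean follows a delayed
low-passed respiratory drive, and small 4-D BOLD volumes with AR(1) noise and
a stored ground-truth slope map.

Design notes
------------
* Each breath is a piecewise-linear trapezoid with a slightly sloped alveolar
  plateau, so end-tidal markers are unique local extrema (capnogram
  morphology), not flat-top ambiguities.
* During apnea the nasal sample is static: the trace holds the last expired
  value and the accumulated gas exchange appears in the first post-hold
  expirate, then washes out over per-gas recovery time constants (end-tidal
  CO2 renormalizes within a few breaths; the O2 stores refill more slowly)
  while the first recovery breaths are deep, slow gasps.
* A common per-breath ventilatory depth factor scales both gas swings; the
  exchange ratio bER cancels it by construction, which is exactly the
  property the ratio is meant to have.
* The hemodynamic impulse response is a delayed single-exponential (delay
  ~2 s, time constant ~6 s).  Reported flow changes reach their ~40 percent
  plateau by the end of a 30 s hold, so the response must be mostly realized
  within the hold; the response nevertheless outlasts the hold because the
  gas excess washes out over tens of seconds after breathing resumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .gas import GasTraces
from .hemo import BoldDataset, CBFvTrace, ROI_LABELS

CHALLENGE_LABELS = {"breath_hold", "hypercapnia_4", "hypercapnia_8"}
FREE_LABELS = {"free_breathing", "normocapnia"}


@dataclass(frozen=True)
class Epoch:
    onset_s: float
    duration_s: float
    label: str


@dataclass
class ProtocolSchedule:
    """Contiguous, non-overlapping epochs covering [0, total_duration_s]."""

    epochs: list[Epoch]
    total_duration_s: float

    def __post_init__(self) -> None:
        eps = sorted(self.epochs, key=lambda e: e.onset_s)
        for e in eps:
            if e.duration_s < 0 or e.onset_s < 0:
                raise ValueError("negative epoch onset/duration")
            if e.label not in CHALLENGE_LABELS | FREE_LABELS:
                raise ValueError(f"unknown epoch label: {e.label}")
        for a, b in zip(eps[:-1], eps[1:]):
            if a.onset_s + a.duration_s > b.onset_s + 1e-9:
                raise ValueError("overlapping epochs")
        if eps and eps[-1].onset_s + eps[-1].duration_s > self.total_duration_s + 1e-9:
            raise ValueError("epochs exceed total duration")
        holds = [e for e in eps if e.label == "breath_hold"]
        for a, b in zip(holds[:-1], holds[1:]):
            between = [e for e in eps if e.label in FREE_LABELS
                       and e.onset_s >= a.onset_s + a.duration_s - 1e-9
                       and e.onset_s + e.duration_s <= b.onset_s + 1e-9]
            if not between:
                raise ValueError("breath-hold epochs not separated by free breathing")
        self.epochs = eps

    def challenge_epochs(self) -> list[Epoch]:
        return [e for e in self.epochs if e.label in CHALLENGE_LABELS]

    def to_dict(self) -> dict:
        return {
            "total_duration_s": self.total_duration_s,
            "epochs": [vars(e) for e in self.epochs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSchedule":
        return cls(epochs=[Epoch(**e) for e in d["epochs"]],
                   total_duration_s=d["total_duration_s"])


def generate_protocol(
    kind: str = "breath_hold",
    n_epochs: int = 6,
    bh_duration_s: float = 30.0,
    free_range_s: tuple[float, float] = (60.0, 90.0),
    seed: int = 0,
    lead_in_s: float = 60.0,
) -> ProtocolSchedule:
    """Challenge schedule: lead-in baseline, then n challenge/free pairs.

    ``kind='breath_hold'`` labels every challenge epoch as a hold;
    ``kind='co2'`` alternates hypercapnia_4/hypercapnia_8 steps (3 of each for
    the standard 6-epoch paradigm) with normocapnic gaps.  Gap durations are
    drawn uniformly from ``free_range_s`` with a seeded RNG.
    """
    lo, hi = free_range_s
    if n_epochs < 0 or bh_duration_s < 0 or lead_in_s < 0 or lo < 0:
        raise ValueError("negative durations are invalid")
    if lo > hi:
        raise ValueError("free_range_s must satisfy lo <= hi")
    if kind not in ("breath_hold", "co2"):
        raise ValueError(f"unknown protocol kind: {kind}")
    rng = np.random.default_rng(seed)
    free_label = "free_breathing" if kind == "breath_hold" else "normocapnia"
    epochs: list[Epoch] = []
    t = 0.0
    if lead_in_s > 0:
        epochs.append(Epoch(0.0, lead_in_s, free_label))
        t = lead_in_s
    for i in range(n_epochs):
        if kind == "breath_hold":
            lab = "breath_hold"
        else:
            lab = "hypercapnia_4" if i % 2 == 0 else "hypercapnia_8"
        epochs.append(Epoch(t, bh_duration_s, lab))
        t += bh_duration_s
        gap = float(rng.uniform(lo, hi))
        epochs.append(Epoch(t, gap, free_label))
        t += gap
    return ProtocolSchedule(epochs=epochs, total_duration_s=t)


@dataclass
class GasSimParams:
    """Gas-trace generator settings (defaults follow reported MRI-session
    baselines: PETCO2 38.7, PETO2 113.8 mmHg, per-breath swings 36.6 and
    32.7 mmHg, hold-induced swing growth ~0.30 and ~1.28 mmHg per second of
    apnea)."""

    fs: float = 50.0
    baseline_petco2: float = 38.7
    baseline_peto2: float = 113.8
    inspired_pco2: float = 2.1
    inspired_po2: float = 146.5
    breath_period_mean: float = 5.0
    breath_period_sd: float = 0.4
    bh_dpco2_drift: float = 0.30
    bh_dpo2_drift: float = 1.28
    noise_sd: float = 0.3
    seed: int = 0
    # secondary realism knobs
    vent_noise_frac: float = 0.015  # per-breath ventilatory depth SD
    gas_noise_mmHg: float = 0.3     # independent per-gas end-tidal jitter
    # epoch-to-epoch variability of the hold-induced swing growth; reported
    # per-subject hold responses scatter with SD comparable to the mean for
    # CO2 and roughly a third to a half of the mean for O2
    bh_drift_cv_co2: float = 0.6
    bh_drift_cv_o2: float = 0.35
    # achieved hold duration varies around the 30 s cue ("hold for as long
    # as you can"); reported per-subject duration SDs run up to ~6 s
    bh_duration_sd_s: float = 3.0
    # post-hold washout of the accumulated excess: ventilatory recovery
    # clears end-tidal CO2 within a few breaths; the O2 stores refill slower
    recovery_tau_co2_s: float = 8.0
    recovery_tau_o2_s: float = 18.0
    # post-apnea recovery breathing: the first breaths after a hold are deep
    # slow gasps, transiently lengthening the respiratory cycle
    tob_recovery_gain: float = 0.3
    hyper_tau_s: float = 10.0       # approach to exogenous-CO2 targets
    plateau_slope_mmHg: float = 0.8  # alveolar-plateau rise to the end-tidal point

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (self.baseline_peto2 > self.baseline_petco2 > 0):
            raise ValueError("require baseline_peto2 > baseline_petco2 > 0")
        if self.bh_dpco2_drift < 0 or self.bh_dpo2_drift < 0:
            raise ValueError("drifts must be nonnegative")


def simulate_gas_traces(protocol: ProtocolSchedule, params: GasSimParams) -> GasTraces:
    """Generate nasal-line PO2/PCO2 traces plus respiration phase.

    Deterministic for a fixed seed.  The returned traces carry a ground-truth
    breath table in ``meta['truth_breaths']`` (marker times and pre-noise
    inspired/expired readings) for detector validation.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    total = protocol.total_duration_s
    holds = [(e.onset_s, e.duration_s) for e in protocol.epochs
             if e.label == "breath_hold"]
    hypers = [(e.onset_s, e.onset_s + e.duration_s,
               4.0 if e.label == "hypercapnia_4" else 8.0)
              for e in protocol.epochs if e.label.startswith("hypercapnia")]

    bp_t: list[float] = [0.0]
    bp_c: list[float] = [p.baseline_petco2]
    bp_o: list[float] = [p.baseline_peto2]
    resp_spans: list[tuple[float, float, float]] = []  # (start, end, value)
    actual_holds: list[tuple[float, float]] = []  # realized apnea intervals
    rows = []

    t = 0.0
    last_c, last_o = p.baseline_petco2, p.baseline_peto2
    excess_c = excess_o = 0.0
    decay_origin: float | None = None  # first post-hold end-expiration time
    hyper_shift = 0.0
    hold_i = 0

    while t < total:
        if hold_i < len(holds) and t >= holds[hold_i][0]:
            dur = holds[hold_i][1]
            if p.bh_duration_sd_s > 0:
                dur = float(np.clip(rng.normal(dur, p.bh_duration_sd_s),
                                    5.0, dur + 10.0))
            # static nasal sample during apnea; a small sampling-line
            # relaxation keeps the pre-hold end-tidal point a unique extremum
            bp_t += [t + 0.5, t + dur]
            bp_c += [last_c - 0.5, last_c - 0.5]
            bp_o += [last_o + 0.5, last_o + 0.5]
            resp_spans.append((t, t + dur, 0.0))
            actual_holds.append((t, t + dur))
            # decay any leftover excess to the hold start, then accumulate
            if decay_origin is not None:
                excess_c *= np.exp(-(t - decay_origin) / p.recovery_tau_co2_s)
                excess_o *= np.exp(-(t - decay_origin) / p.recovery_tau_o2_s)
            fac_c = max(0.0, 1.0 + (rng.normal(0.0, p.bh_drift_cv_co2)
                                    if p.bh_drift_cv_co2 else 0.0))
            fac_o = max(0.0, 1.0 + (rng.normal(0.0, p.bh_drift_cv_o2)
                                    if p.bh_drift_cv_o2 else 0.0))
            excess_c += p.bh_dpco2_drift * dur * fac_c
            excess_o += p.bh_dpo2_drift * dur * fac_o
            decay_origin = None
            t += dur
            hold_i += 1
            continue

        T = float(max(1.5, rng.normal(p.breath_period_mean, p.breath_period_sd)))
        if decay_origin is not None and p.tob_recovery_gain:
            # deep slow recovery breaths while the hold excess washes out
            T *= 1.0 + p.tob_recovery_gain * float(
                np.exp(-(t - decay_origin) / p.recovery_tau_o2_s))
        elif decay_origin is None and (excess_c or excess_o) and p.tob_recovery_gain:
            T *= 1.0 + p.tob_recovery_gain
        t_exp = t + T
        if decay_origin is None and (excess_c or excess_o):
            decay_origin = t_exp  # first post-hold breath carries full excess
        if decay_origin is not None:
            decay_c = np.exp(-(t_exp - decay_origin) / p.recovery_tau_co2_s)
            decay_o = np.exp(-(t_exp - decay_origin) / p.recovery_tau_o2_s)
        else:
            decay_c = decay_o = 0.0

        target = next((d for s, e, d in hypers if s <= t_exp < e), 0.0)
        hyper_shift += (target - hyper_shift) * (1.0 - np.exp(-T / p.hyper_tau_s))

        eps_c = rng.normal(0.0, p.gas_noise_mmHg) if p.gas_noise_mmHg else 0.0
        eps_o = rng.normal(0.0, p.gas_noise_mmHg) if p.gas_noise_mmHg else 0.0
        exp_c = p.baseline_petco2 + excess_c * decay_c + hyper_shift + eps_c
        exp_o = p.baseline_peto2 - excess_o * decay_o - 0.5 * hyper_shift + eps_o

        vent = float(np.clip(1.0 + (rng.normal(0.0, p.vent_noise_frac)
                                    if p.vent_noise_frac else 0.0), 0.3, 1.7))
        ins_c = exp_c - vent * (exp_c - p.inspired_pco2)
        ins_o = exp_o + vent * (p.inspired_po2 - exp_o)

        t_ei = t + 0.35 * T
        sl = p.plateau_slope_mmHg
        bp_t += [t + 0.15 * T, t_ei, t + 0.5 * T, t_exp]
        bp_c += [ins_c + 0.5 * sl, ins_c, exp_c - sl, exp_c]
        bp_o += [ins_o - 0.5 * sl, ins_o, exp_o + sl, exp_o]
        resp_spans.append((t, t_ei, 1.0))
        resp_spans.append((t_ei, t_exp, -1.0))
        rows.append({"t_end_insp_s": t_ei, "t_end_exp_s": t_exp,
                     "inspired_po2": ins_o, "expired_po2": exp_o,
                     "inspired_pco2": ins_c, "expired_pco2": exp_c})
        last_c, last_o = exp_c, exp_o
        t = t_exp

    time = np.arange(0.0, total, 1.0 / p.fs)
    pco2 = np.interp(time, bp_t, bp_c)
    po2 = np.interp(time, bp_t, bp_o)
    resp = np.zeros_like(time)
    for s, e, v in resp_spans:
        resp[(time >= s) & (time < e)] = v
    if p.noise_sd > 0:
        pco2 = pco2 + rng.normal(0.0, p.noise_sd, size=time.shape)
        po2 = po2 + rng.normal(0.0, p.noise_sd, size=time.shape)

    truth = pd.DataFrame(rows)
    truth = truth[truth["t_end_exp_s"] <= total - 1.0 / p.fs].reset_index(drop=True)
    return GasTraces(time_s=time, po2=po2, pco2=pco2, fs=p.fs, resp=resp,
                     meta={"truth_breaths": truth, "actual_holds": actual_holds,
                           "params": vars(p).copy()})


# Reported per-subject MRI-session conditions: baseline end-tidal pressures
# and per-breath swings (mmHg), mean achieved hold duration (s), and the mean
# (SD) change of each swing from hold onset to hold end.  These rows drive
# cohort-level simulations so the synthetic group carries the real spread of
# CO2/O2 responsiveness (including near-non-responders).
MRI_SESSION_SUBJECTS = [
    # petco2, peto2, dpco2, dpo2, dur_s, d_dpco2(sd), d_dpo2(sd)
    (42.9, 99.3, 42.5, 54.0, 33.4, 3.9, 2.4, 29.7, 7.6),
    (38.7, 113.8, 36.6, 32.7, 31.7, 9.5, 2.7, 40.5, 2.5),
    (36.1, 112.7, 35.9, 38.1, 32.6, 5.3, 1.9, 46.8, 5.3),
    (39.4, 104.1, 39.2, 44.2, 35.5, 1.7, 1.3, 17.3, 6.8),
    (32.4, 117.1, 32.1, 32.4, 35.3, 7.6, 5.4, 30.9, 6.0),
    (39.0, 109.8, 37.5, 38.3, 32.2, 9.4, 3.9, 39.9, 7.7),
    (40.3, 109.0, 38.6, 41.3, 32.9, 3.5, 3.5, 34.3, 6.4),
    (37.7, 103.1, 37.1, 47.9, 35.4, 3.0, 3.7, 22.4, 14.9),
    (41.3, 106.6, 40.0, 44.6, 33.9, 6.8, 4.0, 35.9, 21.3),
    (36.6, 117.6, 34.3, 35.9, 31.5, 8.3, 0.9, 50.9, 4.1),
    (34.2, 114.7, 33.1, 35.7, 36.4, 0.0, 0.6, 4.5, 5.5),
    (37.6, 113.6, 36.0, 40.0, 32.0, 1.6, 1.6, 26.0, 4.9),
    (36.3, 109.1, 34.1, 44.4, 31.8, 3.7, 6.3, 15.8, 16.0),
    (36.1, 114.6, 31.7, 38.1, 35.7, 3.6, 1.6, 17.2, 4.4),
    (35.8, 115.9, 32.8, 37.7, 34.1, 7.9, 5.3, 30.7, 8.4),
    (34.8, 119.9, 31.4, 23.9, 27.7, 1.6, 2.1, 11.8, 4.0),
]


def subject_gas_params(row: tuple, seed: int = 0, **overrides) -> "GasSimParams":
    """GasSimParams for one reported subject row of ``MRI_SESSION_SUBJECTS``.

    Baselines map directly; the hold drifts are the subject's mean hold
    response divided by the mean achieved hold duration, and the
    epoch-to-epoch drift CVs are the reported SD/mean ratios (floored at 0.1,
    capped at 1.5)."""
    petco2, peto2, dpco2, dpo2, dur, dc, dc_sd, do, do_sd = row
    def cv(mean, sd):
        if mean <= 0:
            return 1.0
        return float(np.clip(sd / mean, 0.1, 1.5))
    kw = dict(
        baseline_petco2=petco2, baseline_peto2=peto2,
        inspired_pco2=petco2 - dpco2, inspired_po2=peto2 + dpo2,
        bh_dpco2_drift=dc / dur, bh_dpo2_drift=do / dur,
        bh_drift_cv_co2=cv(dc, dc_sd), bh_drift_cv_o2=cv(do, do_sd),
        seed=seed,
    )
    kw.update(overrides)
    return GasSimParams(**kw)


@dataclass
class HemoSimParams:
    """Hemodynamic generator settings.

    ``coupling_gain`` is the percent response per unit of the (convolved)
    drive; the delayed single-exponential kernel has onset ``response_delay_s``
    and time constant ``dispersion_tau_s`` and is normalized to unit gain, so
    a sustained unit drive produces a ``coupling_gain`` percent plateau.
    """

    coupling_gain: float = 15.0
    response_delay_s: float = 2.0
    dispersion_tau_s: float = 6.0
    ar1_coef: float = 0.3
    noise_sd: float = 2.0
    seed: int = 0
    baseline_velocity: float = 60.0  # cm/s, mid-MCA resting mean
    heart_rate_hz: float = 1.0
    pulse_amp: float = 0.35

    def __post_init__(self) -> None:
        if self.response_delay_s < 0:
            raise ValueError("delay must be nonnegative")
        if self.dispersion_tau_s <= 0:
            raise ValueError("tau must be positive")
        if not abs(self.ar1_coef) < 1:
            raise ValueError("|ar1_coef| must be < 1")


def hemodynamic_kernel(delay_s: float, tau_s: float, dt: float,
                       length_s: float | None = None) -> np.ndarray:
    """Delayed single-exponential impulse response, unit gain (sum*dt == 1)."""
    if length_s is None:
        length_s = delay_s + 8.0 * tau_s
    tt = np.arange(0.0, length_s, dt)
    h = np.where(tt >= delay_s, np.exp(-(tt - delay_s) / tau_s), 0.0)
    s = h.sum() * dt
    if s == 0:
        h = np.zeros_like(tt)
        h[0] = 1.0 / dt
        return h
    return h / s


def _convolve_drive(vals: np.ndarray, dt: float, params: HemoSimParams,
                    kernel: np.ndarray | str | None) -> np.ndarray:
    if isinstance(kernel, str) and kernel == "identity":
        return vals.copy()
    if kernel is None:
        kernel = hemodynamic_kernel(params.response_delay_s,
                                    params.dispersion_tau_s, dt)
    return np.convolve(vals, kernel)[: len(vals)] * dt


def standardize(vals: np.ndarray) -> np.ndarray:
    """Z-score a drive series (zero mean, unit SD)."""
    v = np.asarray(vals, dtype=float)
    sd = np.std(v)
    if sd == 0:
        raise ValueError("cannot standardize a constant drive")
    return (v - np.mean(v)) / sd


def simulate_cbfv(
    protocol: ProtocolSchedule,
    drive: tuple[np.ndarray, np.ndarray],
    params: HemoSimParams,
    fs: float = 100.0,
    kernel: np.ndarray | str | None = None,
) -> CBFvTrace:
    """Pulsatile MCA velocity whose beat mean follows the convolved drive.

    ``drive`` is (time_s, values) on a uniform grid, typically the
    interpolated z-scored bER series (pass values as-is; no internal
    standardization so that rectangular test drives keep their units).
    velocity = baseline * (1 + gain * (h * drive)/100) * pulse + noise.
    """
    t_d, v_d = np.asarray(drive[0], float), np.asarray(drive[1], float)
    if len(t_d) == 0:
        raise ValueError("empty drive")
    # breath-stamped drives start at the first end-expiration; allow up to a
    # couple of breath periods of edge-hold extrapolation at either end
    if t_d[0] > 12.0 or t_d[-1] < protocol.total_duration_s - 12.0:
        raise ValueError("drive does not cover the protocol duration")
    p = params
    rng = np.random.default_rng(p.seed)
    dt = 1.0 / fs
    time = np.arange(0.0, protocol.total_duration_s, dt)
    dr = np.interp(time, t_d, v_d)
    conv = _convolve_drive(dr, dt, p, kernel)
    mean_v = p.baseline_velocity * (1.0 + p.coupling_gain * conv / 100.0)

    phase = (time * p.heart_rate_hz) % 1.0
    raw = (np.exp(-(((phase - 0.15) / 0.08) ** 2))
           + 0.4 * np.exp(-(((phase - 0.45) / 0.15) ** 2)))
    fine = np.linspace(0, 1, 2048, endpoint=False)
    raw_mean = float(np.mean(np.exp(-(((fine - 0.15) / 0.08) ** 2))
                             + 0.4 * np.exp(-(((fine - 0.45) / 0.15) ** 2))))
    pulse = 1.0 + p.pulse_amp * (raw - raw_mean)
    vel = mean_v * pulse
    if p.noise_sd > 0:
        vel = vel + p.baseline_velocity * p.noise_sd / 100.0 * rng.standard_normal(len(time))
    return CBFvTrace(time_s=time, velocity=vel, fs=fs,
                     meta={"truth_mean": mean_v, "truth_conv": conv,
                           "params": vars(p).copy()})


def quadrant_parcellation(grid: tuple[int, int, int]) -> np.ndarray:
    """Four-quadrant label volume standing in for a cortical parcellation
    (1=LGM, 2=RGM, 3=LWM, 4=RWM by x/y quadrant, all slices)."""
    nx, ny, nz = grid
    parc = np.zeros(grid, dtype=int)
    parc[: nx // 2, : ny // 2, :] = ROI_LABELS["LGM"]
    parc[nx // 2:, : ny // 2, :] = ROI_LABELS["RGM"]
    parc[: nx // 2, ny // 2:, :] = ROI_LABELS["LWM"]
    parc[nx // 2:, ny // 2:, :] = ROI_LABELS["RWM"]
    return parc


def default_truth_map(grid: tuple[int, int, int],
                      gm_slope: float = 2.0, wm_slope: float = 1.0) -> np.ndarray:
    """Ground-truth CVR slopes: gray-matter quadrants respond ~2x white."""
    parc = quadrant_parcellation(grid)
    truth = np.where(np.isin(parc, [ROI_LABELS["LGM"], ROI_LABELS["RGM"]]),
                     gm_slope, wm_slope).astype(float)
    return truth


def simulate_bold(
    protocol: ProtocolSchedule,
    regressor: tuple[np.ndarray, np.ndarray],
    truth_cvr_map: np.ndarray,
    params: HemoSimParams,
    grid: tuple[int, int, int] = (8, 8, 4),
    tr_s: float = 1.45,
    mask: np.ndarray | None = None,
    kernel: np.ndarray | str | None = None,
    voxel_dims_mm: tuple[float, float, float] = (3.4, 3.4, 6.0),
) -> BoldDataset:
    """4-D BOLD volumes driven voxelwise by the convolved regressor.

    voxel(t) = 100 * (1 + truth_cvr * (h * regressor)(t) / 100) + AR(1) noise
    with innovation variance set so the marginal noise SD equals
    ``params.noise_sd`` (percent units).  Mask, quadrant parcellation, and the
    truth map travel with the dataset.
    """
    truth = np.asarray(truth_cvr_map, dtype=float)
    if truth.shape != tuple(grid):
        raise ValueError("truth map does not match grid")
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    if mask.shape != tuple(grid):
        raise ValueError("mask does not match grid")
    t_r, v_r = np.asarray(regressor[0], float), np.asarray(regressor[1], float)
    n_vols = int(np.floor(protocol.total_duration_s / tr_s))
    frame_t = np.arange(n_vols) * tr_s
    # breath-stamped regressors start at the first end-expiration; allow a
    # couple of breath periods of edge-hold extrapolation at either end
    if t_r[0] > frame_t[0] + 12.0 or t_r[-1] < frame_t[-1] - 12.0:
        raise ValueError("regressor does not cover the acquisition")
    reg = np.interp(frame_t, t_r, v_r)
    conv = _convolve_drive(reg, tr_s, params, kernel)

    p = params
    rng = np.random.default_rng(p.seed)
    clean = 100.0 * (1.0 + truth[..., None] * conv[None, None, None, :] / 100.0)
    data = clean
    if p.noise_sd > 0:
        innov = rng.standard_normal((*grid, n_vols)) * p.noise_sd * np.sqrt(1 - p.ar1_coef ** 2)
        noise = lfilter([1.0], [1.0, -p.ar1_coef], innov, axis=-1)
        data = clean + noise
    return BoldDataset(data=data, tr_s=tr_s, mask=mask,
                       parcellation=quadrant_parcellation(grid),
                       voxel_dims_mm=voxel_dims_mm, truth_cvr=truth,
                       meta={"regressor_conv": conv, "params": vars(p).copy(),
                             "seed": p.seed})
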