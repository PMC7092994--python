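"""Breath-by-breath respiratory gas-exchange (RGE) metrics from PO2/PCO2 traces.

The central quantity is the breath-by-breath O2-CO2 exchange ratio

    bER = dPO2 / dPCO2,

where dPO2 = inspired PO2 - expired PO2 and dPCO2 = expired PCO2 - inspired
PCO2, both read between the end-inspiration and end-expiration markers of a
single respiratory cycle.  End-tidal pressures (PETCO2, PETO2) are read at end
expiration, the time of breath (ToB) is the interval between consecutive
end-expiration markers, and the stimulus index SI = PETCO2/PETO2.

Breath-hold epochs carry no breaths; metric series are bridged across them by
linear interpolation between the last pre-hold and first post-hold breath.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

#: breaths with dPCO2 below this (mmHg) are treated as shallow artifacts
MIN_DPCO2_MMHG = 1.0

#: metric columns of an RGE table that can be resampled to a uniform grid
RGE_METRICS = ("ber", "dpo2", "dpco2", "petco2", "peto2", "tob_s", "si")


@dataclass
class GasTraces:
    """Uniformly sampled PO2/PCO2 (mmHg) traces with optional respiration phase."""

    time_s: np.ndarray
    po2: np.ndarray
    pco2: np.ndarray
    fs: float
    resp: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.po2 = np.asarray(self.po2, dtype=float)
        self.pco2 = np.asarray(self.pco2, dtype=float)
        if self.resp is not None:
            self.resp = np.asarray(self.resp, dtype=float)
        if self.time_s.ndim != 1 or len(self.time_s) < 2:
            raise ValueError("time_s must be 1-D with at least two samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time not monotone")
        for name in ("po2", "pco2"):
            arr = getattr(self, name)
            if arr.shape != self.time_s.shape:
                raise ValueError(f"{name} shape mismatch with time_s")
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


def correct_technical_delay(
    gas: GasTraces,
    reference: np.ndarray,
    max_lag_s: float,
    ref_fs: float | None = None,
) -> tuple[GasTraces, float]:
    """Align gas traces to a respiration-phase reference by cross-correlation.

    The gas analyzer samples through a nasal line, so PO2/PCO2 arrive with a
    transport delay relative to the respiration reference (bellows, flow, or
    chest-excursion artifact).  The lag is the argmax of the normalized
    cross-correlation of the gas respiration-phase signal against the
    reference within +/-max_lag_s; the traces are shifted by -lag and the
    non-overlapping ends are trimmed (never wrapped).

    A positive returned lag means the gas traces lagged the reference.  If the
    argmax sits on the search boundary the result is flagged in
    ``gas.meta['delay_clipped']``.
    """
    if max_lag_s <= 0:
        raise ValueError("max_lag_s must be positive")
    reference = np.asarray(reference, dtype=float)
    if ref_fs is not None and abs(ref_fs - gas.fs) > 1e-9:
        t_ref = np.arange(len(reference)) / ref_fs
        t_gas = np.arange(int(np.floor(t_ref[-1] * gas.fs)) + 1) / gas.fs
        reference = np.interp(t_gas, t_ref, reference)
    if np.std(reference) == 0:
        raise ValueError("no respiratory phase information: reference is flat")

    # respiration-phase proxy of the gas signal: its own resp channel when
    # present, otherwise -d(PCO2)/dt (PCO2 falls during inspiration)
    if gas.resp is not None and np.std(gas.resp) > 0:
        sig = gas.resp
    else:
        sig = -np.gradient(gas.pco2, 1.0 / gas.fs)

    n = min(len(sig), len(reference))
    a = (sig[:n] - np.mean(sig[:n])) / (np.std(sig[:n]) + 1e-30)
    b = (reference[:n] - np.mean(reference[:n])) / (np.std(reference[:n]) + 1e-30)
    max_lag = int(round(max_lag_s * gas.fs))
    lags = np.arange(-max_lag, max_lag + 1)
    # xc(k) = sum_i sig[i + k] * ref[i]; positive k means the gas runs late
    xc = np.array([np.sum(a[max(0, k): n - max(0, -k)] * b[max(0, -k): n - max(0, k)])
                   for k in lags])
    counts = n - np.abs(lags)
    xc = xc / counts
    best = int(np.argmax(xc))
    lag_samples = int(lags[best])
    clipped = best in (0, len(lags) - 1)
    lag_s = lag_samples / gas.fs

    # shift the gas record earlier by lag (trim, don't wrap)
    if lag_samples > 0:
        sl = slice(lag_samples, None)
    elif lag_samples < 0:
        sl = slice(None, lag_samples)
    else:
        sl = slice(None)
    t = gas.time_s[: len(gas.po2[sl])]
    out = GasTraces(
        time_s=t,
        po2=gas.po2[sl],
        pco2=gas.pco2[sl],
        fs=gas.fs,
        resp=gas.resp[sl] if gas.resp is not None else None,
        meta={**gas.meta, "delay_s": lag_s, "delay_clipped": clipped},
    )
    if clipped:
        warnings.warn("delay estimate hit the max_lag_s search boundary")
    return out, lag_s


def detect_breath_markers(
    gas: GasTraces,
    resp: np.ndarray | None = None,
    prominence_frac: float = 0.25,
    min_separation_s: float = 1.5,
) -> pd.DataFrame:
    """Mark end inspiration/expiration on the PCO2 trace and read both gases.

    End expiration is the local maximum of PCO2 terminating the alveolar
    plateau of each cycle; end inspiration is the local minimum of PCO2
    preceding it.  PO2 is read at the PCO2-derived timestamps so both gases
    share one time base.  Peak prominence defaults to 25% of the trace IQR
    with a 1.5 s minimum inter-breath separation.  Apneic (breath-hold)
    epochs contain no PCO2 oscillation and therefore yield no breaths.

    When a respiration-phase signal is supplied (positive deflection =
    inspiration), markers landing in the wrong phase are rejected.

    Returns a breath table with columns t_end_insp_s, t_end_exp_s,
    inspired_po2, expired_po2, inspired_pco2, expired_pco2.
    """
    pco2 = gas.pco2
    iqr = float(np.subtract(*np.percentile(pco2, [75, 25])))
    cols = ["t_end_insp_s", "t_end_exp_s", "inspired_po2", "expired_po2",
            "inspired_pco2", "expired_pco2"]
    if iqr <= 0 or np.ptp(pco2) == 0:
        warnings.warn("PCO2 trace has no oscillation; no breaths detected")
        return pd.DataFrame(columns=cols)

    distance = max(1, int(round(min_separation_s * gas.fs)))
    prominence = prominence_frac * iqr
    peaks, _ = find_peaks(pco2, prominence=prominence, distance=distance)
    if len(peaks) < 2:
        warnings.warn("fewer than two end-expiration markers found")
        return pd.DataFrame(columns=cols)

    rows = []
    prev = 0
    for pk in peaks:
        seg = pco2[prev:pk]
        if len(seg) == 0:
            prev = pk
            continue
        tr = prev + int(np.argmin(seg))
        if resp is not None:
            # end inspiration must terminate an inspiratory (resp > 0) phase,
            # end expiration an expiratory (resp < 0) phase
            w = max(1, int(round(0.5 * gas.fs)))
            insp_ok = np.max(resp[max(0, tr - w): tr + 1]) > 0
            exp_ok = np.min(resp[max(0, pk - w): pk + 1]) < 0
            if not (insp_ok and exp_ok):
                prev = pk
                continue
        rows.append({
            "t_end_insp_s": gas.time_s[tr],
            "t_end_exp_s": gas.time_s[pk],
            "inspired_po2": gas.po2[tr],
            "expired_po2": gas.po2[pk],
            "inspired_pco2": gas.pco2[tr],
            "expired_pco2": gas.pco2[pk],
        })
        prev = pk
    return pd.DataFrame(rows, columns=cols)


def compute_rge_metrics(
    breaths: pd.DataFrame,
    min_dpco2: float = MIN_DPCO2_MMHG,
) -> pd.DataFrame:
    """Per-breath RGE metrics from a breath-marker table.

    Computes dpo2 = inspired - expired PO2, dpco2 = expired - inspired PCO2,
    ber = dpo2/dpco2, end-tidal pressures at end expiration, si =
    petco2/peto2, and tob_s from consecutive end-expiration timestamps (the
    first breath has no predecessor, so its tob_s is NaN).  Breaths with
    dpco2 below ``min_dpco2`` (shallow artifacts) or nonpositive dpco2 are
    excluded and logged.

    Rows are stamped at end expiration (column t_s).
    """
    if len(breaths) < 2:
        raise ValueError("need at least two breaths to compute ToB")
    b = breaths.reset_index(drop=True)
    dpo2 = b["inspired_po2"] - b["expired_po2"]
    dpco2 = b["expired_pco2"] - b["inspired_pco2"]
    tob = b["t_end_exp_s"].diff()
    out = pd.DataFrame({
        "t_s": b["t_end_exp_s"],
        "dpo2": dpo2,
        "dpco2": dpco2,
        "ber": dpo2 / dpco2,
        "petco2": b["expired_pco2"],
        "peto2": b["expired_po2"],
        "tob_s": tob,
        "si": b["expired_pco2"] / b["expired_po2"],
    })
    bad = dpco2 < min_dpco2
    if bad.any():
        logger.info("excluding %d breath(s) with dPCO2 < %.2f mmHg",
                    int(bad.sum()), min_dpco2)
    return out[~bad].reset_index(drop=True)


def interpolate_over_breath_holds(
    rge: pd.DataFrame,
    protocol=None,
    grid: np.ndarray | float = 0.5,
    metrics: tuple[str, ...] = RGE_METRICS,
) -> pd.DataFrame:
    """Resample breath-stamped metrics to a uniform grid, bridging holds.

    Metrics are linearly interpolated between breath timestamps, so inside a
    breath-hold epoch every value lies on the chord between the last pre-hold
    and first post-hold breath.  ``grid`` is either a step in seconds (the
    grid then spans the breath record) or an explicit time vector.  When a
    protocol is given, every hold epoch inside the record must have a breath
    on both sides, otherwise an error names the epoch.
    """
    if len(rge) < 2:
        raise ValueError("need at least two breaths to interpolate")
    t = rge["t_s"].to_numpy(dtype=float)
    if protocol is not None:
        for i, ep in enumerate(protocol.epochs):
            if ep.label != "breath_hold":
                continue
            if ep.onset_s > t[-1] or ep.onset_s + ep.duration_s < t[0]:
                continue
            if not np.any(t <= ep.onset_s) or not np.any(t >= ep.onset_s + ep.duration_s):
                raise ValueError(
                    f"breath-hold epoch {i} (onset {ep.onset_s:.1f} s) has no "
                    "flanking breath on both sides"
                )
    if np.isscalar(grid):
        tg = np.arange(t[0], t[-1] + 1e-9, float(grid))
    else:
        tg = np.asarray(grid, dtype=float)
    out = {"time_s": tg}
    for m in metrics:
        if m not in rge.columns:
            continue
        vals = rge[m].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            continue
        out[m] = np.interp(tg, t[ok], vals[ok])
    return pd.DataFrame(out)
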