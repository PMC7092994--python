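"""Preprocessing of cerebral hemodynamic signals.

Covers transcranial-Doppler blood flow velocity (CBFv) in the middle cerebral
arteries -- median-filter despiking, cardiac beat detection, beat-averaged
mean velocity -- and BOLD-fMRI series -- mean normalization, polynomial
detrending, ROI extraction.  Both end up as percent-change series relative to
a resting baseline window (default: the first 30 s of the record).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

#: FreeSurfer-style hemisphere/tissue ROI labels used throughout
ROI_LABELS = {"LGM": 1, "RGM": 2, "LWM": 3, "RWM": 4}


@dataclass
class CBFvTrace:
    """Cerebral blood flow velocity (cm/s) sampled at fs, with optional beats."""

    time_s: np.ndarray
    velocity: np.ndarray
    fs: float
    beats: list | None = None  # list of (t_systolic_s, t_diastolic_s)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.shape != self.time_s.shape:
            raise ValueError("velocity/time shape mismatch")


@dataclass
class HemoSeries:
    """Percent-change hemodynamic series (dCBFv or dBOLD) on a uniform grid."""

    time_s: np.ndarray
    value: np.ndarray
    baseline_window_s: tuple[float, float] = (0.0, 30.0)
    source_label: str = "custom"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)


@dataclass
class BoldDataset:
    """A 4-D BOLD acquisition with mask, integer parcellation, and truth slot.

    ``truth_cvr`` stores the generating slope map for synthetic data so that
    recovery can be checked; it is None for real acquisitions.
    """

    data: np.ndarray  # (x, y, z, t) signal intensity
    tr_s: float
    mask: np.ndarray  # 3-D boolean
    parcellation: np.ndarray  # 3-D integer labels, 0 = background
    voxel_dims_mm: tuple[float, float, float] = (3.4, 3.4, 6.0)
    truth_cvr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.parcellation = np.asarray(self.parcellation)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask does not match data grid")
        if self.parcellation.shape != self.data.shape[:3]:
            raise ValueError("parcellation does not match data grid")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


def despike_median(v: CBFvTrace, window_s: float = 0.1) -> CBFvTrace:
    """Running-median despiking; edges handled by reflection.

    The window must span an odd number (>= 3) of samples and fit in the trace.
    """
    w = int(round(window_s * v.fs))
    if w % 2 == 0:
        w += 1
    w = max(w, 3)
    if w > len(v.velocity):
        raise ValueError("median window longer than trace")
    out = median_filter(v.velocity, size=w, mode="reflect")
    return CBFvTrace(v.time_s, out, v.fs, beats=v.beats, meta=dict(v.meta))


def detect_cardiac_cycles(
    v: CBFvTrace,
    hr_range_bpm: tuple[float, float] = (40.0, 140.0),
    prominence_frac: float = 0.25,
) -> list[tuple[float, float]]:
    """Detect systolic peaks and end-diastolic troughs on a CBFv waveform.

    Peak search is prominence-based with the minimum inter-beat interval set
    by the upper heart-rate bound; each systolic peak is paired with the
    diastolic trough that follows it.  Inter-beat intervals longer than the
    lower bound allows are flagged as artifact gaps in ``v.meta['gaps_s']``
    rather than interpolated.  Returns [(t_systolic_s, t_diastolic_s), ...].
    """
    lo, hi = hr_range_bpm
    x = v.velocity
    if np.ptp(x) == 0:
        warnings.warn("flat CBFv trace; no beats detected")
        return []
    min_dist = max(1, int(round(60.0 / hi * v.fs)))
    prom = prominence_frac * float(np.subtract(*np.percentile(x, [75, 25])) + 1e-30)
    peaks, _ = find_peaks(x, distance=min_dist, prominence=prom)
    if len(peaks) < 3:
        warnings.warn("fewer than three systolic peaks detected")
        return []
    max_ibi = 60.0 / lo
    beats: list[tuple[float, float]] = []
    gaps: list[tuple[float, float]] = []
    for i in range(len(peaks) - 1):
        p0, p1 = peaks[i], peaks[i + 1]
        ibi = (p1 - p0) / v.fs
        if ibi > max_ibi:
            gaps.append((v.time_s[p0], v.time_s[p1]))
            continue
        tr = p0 + int(np.argmin(x[p0:p1]))
        beats.append((float(v.time_s[p0]), float(v.time_s[tr])))
    v.meta["gaps_s"] = gaps
    v.beats = beats
    return beats


def beat_average(
    v: CBFvTrace,
    beats: list[tuple[float, float]] | None = None,
    artifact_spans_s: list[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean CBFv over each cardiac cycle, stamped at the cycle midpoint.

    Cycles run from one end-diastolic trough to the next.  Cycles overlapping
    a configured artifact span (and spans flagged by beat detection) are
    excluded from further analysis.  Returns (times, means).
    """
    beats = beats if beats is not None else v.beats
    if not beats:
        raise ValueError("no beats available; run detect_cardiac_cycles first")
    spans = list(artifact_spans_s or []) + list(v.meta.get("gaps_s", []))
    troughs = [b[1] for b in beats]
    times, means = [], []
    for t0, t1 in zip(troughs[:-1], troughs[1:]):
        if any(t0 < e and t1 > s for s, e in spans):
            continue
        i0 = int(np.searchsorted(v.time_s, t0))
        i1 = int(np.searchsorted(v.time_s, t1))
        if i1 <= i0:
            continue
        times.append(0.5 * (t0 + t1))
        means.append(float(np.mean(v.velocity[i0:i1])))
    return np.asarray(times), np.asarray(means)


def percent_change(
    time_s: np.ndarray,
    values: np.ndarray,
    baseline_window_s: tuple[float, float] = (0.0, 30.0),
    source_label: str = "custom",
) -> HemoSeries:
    """Percent change relative to the mean over a resting baseline window.

    value_t = 100 * (x_t - mean_baseline) / mean_baseline.  The 30 s window at
    the start of the record is the conventional resting baseline.  Invariant
    under positive rescaling of the raw signal.
    """
    time_s = np.asarray(time_s, dtype=float)
    values = np.asarray(values, dtype=float)
    s, e = baseline_window_s
    sel = (time_s >= s) & (time_s <= e)
    if not sel.any():
        raise ValueError("baseline window outside record")
    base = float(np.mean(values[sel]))
    if base <= 0:
        raise ValueError("nonpositive baseline mean")
    return HemoSeries(time_s, 100.0 * (values - base) / base,
                      baseline_window_s=baseline_window_s,
                      source_label=source_label)


def detrend_bold(series: np.ndarray, order: int = 5) -> np.ndarray:
    """Mean-normalize a voxel series to percent and remove a polynomial drift.

    The series is divided by its mean (x100), a least-squares polynomial of
    the given order is removed, and the residual is re-centered at 0%.  A 5th
    order polynomial over a ~10 min record removes drift below roughly
    0.008 Hz while leaving task-band oscillations nearly untouched.
    Constant series return zeros.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= order + 1:
        raise ValueError("series shorter than polynomial order + 2")
    mu = np.mean(x)
    if np.ptp(x) == 0 or mu == 0:
        return np.zeros(n)
    pct = 100.0 * x / mu
    t = np.linspace(-1.0, 1.0, n)
    coefs = np.polynomial.polynomial.polyfit(t, pct, deg=order)
    resid = pct - np.polynomial.polynomial.polyval(t, coefs)
    return resid - np.mean(resid)


def detrend_bold_volume(bold: BoldDataset, order: int = 5) -> np.ndarray:
    """Voxelwise detrend of all in-mask voxels; returns a 4-D percent array."""
    out = np.zeros_like(bold.data)
    idx = np.argwhere(bold.mask)
    for i, j, k in idx:
        out[i, j, k, :] = detrend_bold(bold.data[i, j, k, :], order=order)
    return out


def extract_roi(
    bold: BoldDataset,
    labels: dict[str, int] | list[str] | None = None,
    order: int = 5,
) -> dict[str, HemoSeries]:
    """Mean detrended percent-BOLD series per parcellation ROI.

    ``labels`` maps ROI names to parcellation label ids (defaults to the
    hemisphere gray/white set LGM/RGM/LWM/RWM).  Each ROI series is the
    per-volume mean over label voxels after voxelwise detrending.  Any
    initial dummy-volume discard is the reader's job and happens before this.
    """
    if labels is None:
        labels = ROI_LABELS
    elif isinstance(labels, (list, tuple)):
        labels = {name: ROI_LABELS[name] for name in labels}
    pct = detrend_bold_volume(bold, order=order)
    t = bold.frame_times
    out: dict[str, HemoSeries] = {}
    for name, lab in labels.items():
        sel = (bold.parcellation == lab) & bold.mask
        if not sel.any():
            raise ValueError(f"empty ROI label: {name} (id {lab})")
        out[name] = HemoSeries(t, pct[sel].mean(axis=0), source_label=name)
    return out


def discard_initial_volumes(bold: BoldDataset, n: int = 12) -> BoldDataset:
    """Drop the first ``n`` pre-equilibrium volumes (applied once, on read)."""
    if n >= bold.n_volumes:
        raise ValueError("cannot discard all volumes")
    return BoldDataset(
        data=bold.data[..., n:],
        tr_s=bold.tr_s,
        mask=bold.mask,
        parcellation=bold.parcellation,
        voxel_dims_mm=bold.voxel_dims_mm,
        truth_cvr=bold.truth_cvr,
        meta={**bold.meta, "discarded_volumes": n},
    )
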