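"""Time-domain coupling of RGE metrics with hemodynamic responses.

Pearson correlation on a common uniform grid, Fisher Z transform for group
statistics, paired comparisons of the bER coupling against the other metrics,
and the metric intercorrelation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Fisher Z saturates here instead of diverging when |r| == 1
_R_CAP = 1.0 - 1e-15


@dataclass
class CouplingResult:
    metric_name: str
    source_label: str
    r: float
    p: float
    z: float
    n_points: int
    saturated: bool = False


@dataclass
class GroupComparison:
    metric_a: str
    metric_b: str
    t: float
    p: float
    n_subjects: int
    mean_dz: float
    degenerate: bool = False


def align_series(
    t_a: np.ndarray, v_a: np.ndarray,
    t_b: np.ndarray, v_b: np.ndarray,
    grid_dt_s: float = 0.5,
    min_points: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate two irregular series onto a shared uniform grid.

    The grid covers the overlap of the two time supports; length is
    floor(overlap/dt)+1.  Fewer than ``min_points`` overlapping grid points
    is an error.
    """
    t_a, v_a = np.asarray(t_a, float), np.asarray(v_a, float)
    t_b, v_b = np.asarray(t_b, float), np.asarray(v_b, float)
    lo = max(t_a[0], t_b[0])
    hi = min(t_a[-1], t_b[-1])
    if hi <= lo:
        raise ValueError("series have disjoint time supports")
    grid = lo + np.arange(int(np.floor((hi - lo) / grid_dt_s)) + 1) * grid_dt_s
    if len(grid) < min_points:
        raise ValueError(f"overlap shorter than {min_points} grid points")
    return grid, np.interp(grid, t_a, v_a), np.interp(grid, t_b, v_b)


def correlate(
    a: np.ndarray, b: np.ndarray,
    metric_name: str = "metric", source_label: str = "custom",
) -> CouplingResult:
    """Pearson r with a two-sided p (t distribution, n-2 df) and Fisher Z.

    Exact |r| = 1 saturates the Z transform at atanh(1 - 1e-15) with a flag so
    group statistics stay finite.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two equal-length series with >= 3 points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(a, b)
    r = float(r)
    saturated = abs(r) >= _R_CAP
    r_for_z = np.clip(r, -_R_CAP, _R_CAP)
    return CouplingResult(metric_name=metric_name, source_label=source_label,
                          r=r, p=float(p), z=float(np.arctanh(r_for_z)),
                          n_points=len(a), saturated=saturated)


def couple_metric_with_hemo(
    rge_interp: pd.DataFrame,
    hemo,
    metrics: tuple[str, ...] = ("ber", "dpo2", "dpco2", "tob_s"),
    grid_dt_s: float = 0.5,
) -> list[CouplingResult]:
    """Correlate each interpolated RGE metric with one hemodynamic series."""
    out = []
    for m in metrics:
        grid, x, y = align_series(
            rge_interp["time_s"].to_numpy(), rge_interp[m].to_numpy(),
            hemo.time_s, hemo.value, grid_dt_s=grid_dt_s)
        out.append(correlate(x, y, metric_name=m, source_label=hemo.source_label))
    return out


def compare_metric_correlations(
    z_table: pd.DataFrame,
    reference_metric: str = "ber",
) -> list[GroupComparison]:
    """Paired t-tests of the reference metric's Fisher Z against each other.

    ``z_table`` has one row per subject and one column per metric (Fisher Z
    of the subject's hemodynamic coupling).  Incomplete pairs are dropped
    pairwise and logged.  A zero-variance paired difference is flagged
    degenerate (t undefined; p reported as 0 for a nonzero constant
    difference, 1 for an identically zero difference).
    """
    if reference_metric not in z_table.columns:
        raise ValueError(f"reference metric {reference_metric!r} missing")
    out = []
    for m in z_table.columns:
        if m == reference_metric:
            continue
        pair = z_table[[reference_metric, m]].dropna()
        dropped = len(z_table) - len(pair)
        if dropped:
            logger.info("dropped %d incomplete pair(s) for %s vs %s",
                        dropped, reference_metric, m)
        if len(pair) < 3:
            raise ValueError("fewer than 3 complete subject pairs")
        d = pair[reference_metric] - pair[m]
        if np.std(d) < 1e-10 * max(1.0, float(np.abs(np.mean(d)))):
            mean_d = float(np.mean(d))
            out.append(GroupComparison(reference_metric, m,
                                       t=np.inf if mean_d != 0 else 0.0,
                                       p=0.0 if mean_d != 0 else 1.0,
                                       n_subjects=len(pair), mean_dz=mean_d,
                                       degenerate=True))
            continue
        t, p = stats.ttest_rel(pair[reference_metric], pair[m])
        out.append(GroupComparison(reference_metric, m, t=float(t), p=float(p),
                                   n_subjects=len(pair),
                                   mean_dz=float(np.mean(d))))
    return out


def metric_intercorrelation(
    rge: pd.DataFrame,
    metrics: tuple[str, ...] = ("ber", "dpo2", "dpco2", "petco2", "peto2", "tob_s"),
) -> pd.DataFrame:
    """Pairwise Pearson r among RGE metrics over breaths (symmetric, unit
    diagonal).  Rows with any NaN among the metrics (e.g. the first breath's
    ToB) are dropped."""
    cols = [m for m in metrics if m in rge.columns]
    sub = rge[list(cols)].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete breaths")
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            try:
                r = correlate(sub[a].to_numpy(), sub[b].to_numpy()).r
            except ValueError:  # constant metric: correlation undefined
                r = np.nan
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def results_to_frame(results: list[CouplingResult], subject: str | int = 0) -> pd.DataFrame:
    """Tidy table (subject, source_label, metric, r, p, z, n) for CSV export."""
    return pd.DataFrame([{
        "subject": subject, "source_label": c.source_label, "metric": c.metric_name,
        "r": c.r, "p": c.p, "z": c.z, "n": c.n_points, "saturated": c.saturated,
    } for c in results])
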