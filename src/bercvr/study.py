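"""Cohort-level study drivers: simulate subjects and run the group analyses.

These functions string the package together the way the study is organized:
each synthetic subject follows the breath-hold paradigm with gas-exchange
parameters taken from the reported per-subject table rows
(``synthetic.MRI_SESSION_SUBJECTS``), the hemodynamic response is driven by
the subject's own z-scored bER series, and the group summaries are the ones
the study reports: Fisher-Z couplings per RGE metric, band-mean
time-averaged coherence, and regional vCVR per regressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coupling, cvr, gas, hemo, synthetic, wtc

COUPLING_METRICS = ("ber", "dpo2", "dpco2", "tob_s")
CVR_REGRESSORS = ("ber", "petco2", "tob_s")


@dataclass
class SubjectData:
    protocol: synthetic.ProtocolSchedule
    traces: gas.GasTraces
    rge: pd.DataFrame
    interp: pd.DataFrame
    drive: tuple[np.ndarray, np.ndarray]
    cbfv_pct: hemo.HemoSeries | None = None
    bold: hemo.BoldDataset | None = None


def simulate_subject(
    seed: int,
    table_row: tuple | None = None,
    grid_dt_s: float = 0.5,
    with_cbfv: bool = True,
    with_bold: bool = False,
    bold_grid: tuple[int, int, int] = (8, 8, 4),
    tr_s: float = 1.45,
    hemo_overrides: dict | None = None,
    gas_overrides: dict | None = None,
) -> SubjectData:
    """One synthetic subject: protocol, gas traces, breath metrics, responses.

    The hemodynamic drive is the subject's interpolated, z-scored bER series.
    """
    protocol = synthetic.generate_protocol(seed=seed)
    if table_row is not None:
        gparams = synthetic.subject_gas_params(table_row, seed=seed + 500,
                                               **(gas_overrides or {}))
    else:
        gparams = synthetic.GasSimParams(seed=seed + 500, **(gas_overrides or {}))
    traces = synthetic.simulate_gas_traces(protocol, gparams)
    breaths = gas.detect_breath_markers(traces, resp=traces.resp)
    rge = gas.compute_rge_metrics(breaths)
    interp = gas.interpolate_over_breath_holds(rge, protocol, grid=grid_dt_s)
    drive = (interp["time_s"].to_numpy(),
             synthetic.standardize(interp["ber"].to_numpy()))
    hparams = synthetic.HemoSimParams(seed=seed + 700, **(hemo_overrides or {}))
    out = SubjectData(protocol=protocol, traces=traces, rge=rge,
                      interp=interp, drive=drive)
    if with_cbfv:
        trace = synthetic.simulate_cbfv(protocol, drive, hparams)
        trace = hemo.despike_median(trace)
        beats = hemo.detect_cardiac_cycles(trace)
        bt, bv = hemo.beat_average(trace, beats)
        out.cbfv_pct = hemo.percent_change(bt, bv, source_label="RMCA")
    if with_bold:
        truth = synthetic.default_truth_map(bold_grid)
        out.bold = synthetic.simulate_bold(protocol, drive, truth, hparams,
                                           grid=bold_grid, tr_s=tr_s)
    return out


def correlation_cohort(cohort_seed: int,
                       rows=None, grid_dt_s: float = 0.5) -> pd.DataFrame:
    """Fisher-Z couplings of each RGE metric with dCBFv, one row per subject."""
    rows = rows if rows is not None else synthetic.MRI_SESSION_SUBJECTS
    out = []
    for i, row in enumerate(rows):
        subj = simulate_subject(cohort_seed * 1000 + i, table_row=row,
                                grid_dt_s=grid_dt_s)
        res = coupling.couple_metric_with_hemo(subj.interp, subj.cbfv_pct,
                                               metrics=COUPLING_METRICS,
                                               grid_dt_s=grid_dt_s)
        out.append({c.metric_name: c.z for c in res})
    return pd.DataFrame(out)


def vcvr_cohort(cohort_seed: int, rows=None,
                grid: tuple[int, int, int] = (8, 8, 4),
                voxel_p: float = 0.005, alpha: float = 0.05,
                calib_iters: int = 300) -> pd.DataFrame:
    """Whole-volume vCVR (% significant voxels) per CVR regressor per subject.

    BOLD is driven by each subject's bER series; the regressors are the raw
    interpolated metric series resampled at the TR, exactly as a CVR mapping
    analysis would use them.  One cluster-extent calibration per cohort (the
    null depends only on the grid).
    """
    rows = rows if rows is not None else synthetic.MRI_SESSION_SUBJECTS
    calib = None
    out = []
    for i, row in enumerate(rows):
        subj = simulate_subject(cohort_seed * 1000 + i, table_row=row,
                                with_cbfv=False, with_bold=True, bold_grid=grid)
        bold = subj.bold
        if calib is None:
            calib = cvr.cluster_extent_calibrate(
                bold.mask, bold.voxel_dims_mm, voxel_p=voxel_p, alpha=alpha,
                n_iter=calib_iters, smoothness_fwhm_mm=0.0,
                seed=cohort_seed)
        rec = {}
        tvec = subj.interp["time_s"].to_numpy()
        for m in CVR_REGRESSORS:
            reg = np.interp(bold.frame_times, tvec, subj.interp[m].to_numpy())
            maps = cvr.regress_bold_dataset(bold, reg, regressor_name=m)
            maps = cvr.apply_cluster_threshold(maps, calib.cluster_min_mm3,
                                               voxel_p=voxel_p)
            rec[m] = 100.0 * maps.sig_mask[bold.mask].mean()
        out.append(rec)
    return pd.DataFrame(out)


def tac_cohort(cohort_seed: int, rows=None, n_subjects: int = 4,
               grid_dt_s: float = 1.0, n_surrogates: int = 100,
               band_hz: tuple[float, float] = (0.008, 0.03),
               metrics=COUPLING_METRICS) -> pd.DataFrame:
    """Band-mean time-averaged coherence (in-phase quadrant pair) per metric.

    Uses a coarser 1 s analysis grid so the red-noise Monte Carlo stays
    affordable; the band of interest (periods 33-125 s) is far above that
    grid's Nyquist limit.
    """
    rows = rows if rows is not None else synthetic.MRI_SESSION_SUBJECTS
    out = []
    for i, row in enumerate(rows[:n_subjects]):
        subj = simulate_subject(cohort_seed * 1000 + i, table_row=row,
                                grid_dt_s=grid_dt_s)
        rec = {}
        for m in metrics:
            grid_t, x, y = coupling.align_series(
                subj.interp["time_s"].to_numpy(), subj.interp[m].to_numpy(),
                subj.cbfv_pct.time_s, subj.cbfv_pct.value, grid_dt_s=grid_dt_s)
            w = wtc.wavelet_coherence(x, y, dt=grid_dt_s)
            wtc.attach_significance(w, x, y, n_surrogates=n_surrogates,
                                    seed=cohort_seed * 100 + i)
            tac = wtc.time_averaged_coherence(w, quadrant="0")
            rec[m] = wtc.band_mean_tac(tac, band_hz=band_hz)
        out.append(rec)
    return pd.DataFrame(out)
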