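"""End-to-end pipeline: simulate -> gas metrics -> hemo -> couple -> wtc -> cvr.

``run_pipeline`` executes the stages in dependency order from a single config
(dict or YAML path), writes every product with provenance into an output
directory, and returns a manifest (also written as JSON) with parameters,
seeds, and content hashes.  Stages without the inputs they need are skipped
with a log notice, so a coupling-only run works without any BOLD settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import coupling, cvr, gas, hemo, io, synthetic, wtc

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "pipeline_out",
    "protocol": {"kind": "breath_hold", "n_epochs": 6, "bh_duration_s": 30.0,
                 "free_range_s": [60.0, 90.0]},
    "gas": {},            # GasSimParams overrides
    "hemo": {},           # HemoSimParams overrides
    "grid_dt_s": 0.5,
    "wtc": {"enabled": True, "n_surrogates": 300, "period_range_s": [4.0, 256.0]},
    "bold": {"enabled": True, "grid": [8, 8, 4], "tr_s": 1.45,
             "voxel_p": 0.005, "alpha": 0.05, "n_iter": 500,
             "smoothness_fwhm_mm": 0.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the synthetic breath-hold analysis end to end; returns the manifest."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(DEFAULT_CONFIG, config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"config": cfg, "stages": {}, "outputs": {}}

    def log_stage(name, t0, **counts):
        dt = time.time() - t0
        manifest["stages"][name] = {"wall_s": round(dt, 3), **counts}
        logger.info("stage %-10s %6.2fs %s", name, dt, counts)

    # --- simulate -----------------------------------------------------------
    t0 = time.time()
    protocol = synthetic.generate_protocol(
        kind=cfg["protocol"]["kind"], n_epochs=cfg["protocol"]["n_epochs"],
        bh_duration_s=cfg["protocol"]["bh_duration_s"],
        free_range_s=tuple(cfg["protocol"]["free_range_s"]), seed=seed)
    gparams = synthetic.GasSimParams(seed=seed, **cfg["gas"])
    traces = synthetic.simulate_gas_traces(protocol, gparams)
    io.write_protocol_json(out_dir / "protocol.json", protocol)
    log_stage("simulate", t0, n_samples=len(traces.time_s))

    # --- gas metrics --------------------------------------------------------
    t0 = time.time()
    breaths = gas.detect_breath_markers(traces, resp=traces.resp)
    rge = gas.compute_rge_metrics(breaths)
    interp = gas.interpolate_over_breath_holds(rge, protocol, grid=cfg["grid_dt_s"])
    io.write_rge_csv(out_dir / "rge.csv", rge)
    interp.to_csv(out_dir / "rge_interp.csv", index=False)
    log_stage("gas", t0, n_breaths=len(rge))

    # --- hemo (CBFv) --------------------------------------------------------
    t0 = time.time()
    hparams = synthetic.HemoSimParams(seed=seed + 1, **cfg["hemo"])
    drive = (interp["time_s"].to_numpy(),
             synthetic.standardize(interp["ber"].to_numpy()))
    trace = synthetic.simulate_cbfv(protocol, drive, hparams)
    trace = hemo.despike_median(trace)
    beats = hemo.detect_cardiac_cycles(trace)
    bt, bv = hemo.beat_average(trace, beats)
    cbfv_pct = hemo.percent_change(bt, bv, source_label="RMCA")
    io.write_trace_csv(out_dir / "traces.csv", traces, cbfv=trace)
    log_stage("hemo", t0, n_beats=len(beats))

    # --- coupling -----------------------------------------------------------
    t0 = time.time()
    results = coupling.couple_metric_with_hemo(interp, cbfv_pct,
                                               grid_dt_s=cfg["grid_dt_s"])
    coupling.results_to_frame(results).to_csv(out_dir / "coupling.csv", index=False)
    log_stage("coupling", t0, n_metrics=len(results))

    # --- wavelet coherence --------------------------------------------------
    if cfg["wtc"].get("enabled", True):
        t0 = time.time()
        grid, x, y = coupling.align_series(
            interp["time_s"].to_numpy(), interp["ber"].to_numpy(),
            cbfv_pct.time_s, cbfv_pct.value, grid_dt_s=cfg["grid_dt_s"])
        w = wtc.wavelet_coherence(x, y, dt=cfg["grid_dt_s"],
                                  period_range_s=tuple(cfg["wtc"]["period_range_s"]))
        wtc.attach_significance(w, x, y, n_surrogates=cfg["wtc"]["n_surrogates"],
                                seed=seed + 2)
        tac = wtc.time_averaged_coherence(w, quadrant="0")
        np.savez(out_dir / "wtc.npz", coherence=w.coherence, phase=w.phase,
                 periods=w.periods, times=w.times, coi=w.coi,
                 sig_threshold=w.sig_threshold)
        import pandas as pd
        pd.DataFrame({"freq_hz": tac.freqs, "tac": tac.tac,
                      "quadrant": tac.quadrant}).to_csv(out_dir / "tac.csv",
                                                        index=False)
        log_stage("wtc", t0, n_scales=len(w.scales))
    else:
        logger.info("stage wtc skipped (disabled)")

    # --- CVR mapping --------------------------------------------------------
    if cfg["bold"].get("enabled", True):
        t0 = time.time()
        b = cfg["bold"]
        grid3 = tuple(b["grid"])
        truth = synthetic.default_truth_map(grid3)
        bold = synthetic.simulate_bold(protocol, drive, truth, hparams,
                                       grid=grid3, tr_s=b["tr_s"])
        reg = np.interp(bold.frame_times, drive[0], drive[1])
        maps = cvr.regress_bold_dataset(bold, reg, regressor_name="ber")
        calib = cvr.cluster_extent_calibrate(
            bold.mask, bold.voxel_dims_mm, voxel_p=b["voxel_p"],
            alpha=b["alpha"], n_iter=b["n_iter"],
            smoothness_fwhm_mm=b["smoothness_fwhm_mm"], seed=seed + 3)
        maps = cvr.apply_cluster_threshold(maps, calib.cluster_min_mm3,
                                           voxel_p=b["voxel_p"])
        table = cvr.regional_summary(maps, bold.parcellation,
                                     {v: k for k, v in hemo.ROI_LABELS.items()})
        table.to_csv(out_dir / "vcvr.csv", index=False)
        (out_dir / "cluster_calibration.json").write_text(json.dumps({
            "voxel_p": calib.voxel_p, "alpha": calib.alpha,
            "n_iter": calib.n_iter, "seed": calib.seed,
            "cluster_min_mm3": calib.cluster_min_mm3}, indent=2))
        io.write_bold_nifti(out_dir / "synthetic", bold)
        log_stage("cvr", t0, n_voxels=int(bold.mask.sum()))
    else:
        logger.info("stage cvr skipped (no BOLD configured)")

    for p in sorted(out_dir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    return manifest
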