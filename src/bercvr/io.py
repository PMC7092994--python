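"""Readers and writers: trace CSV/TSV, RGE tables, protocol JSON, NIfTI."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .gas import GasTraces
from .hemo import BoldDataset, CBFvTrace, discard_initial_volumes
from .synthetic import ProtocolSchedule

TRACE_COLUMNS = {"time_s", "po2_mmHg", "pco2_mmHg"}


def write_trace_csv(path, gas: GasTraces, cbfv: CBFvTrace | None = None) -> None:
    df = pd.DataFrame({"time_s": gas.time_s, "po2_mmHg": gas.po2,
                       "pco2_mmHg": gas.pco2})
    if gas.resp is not None:
        df["resp"] = gas.resp
    if cbfv is not None:
        df["cbfv_cm_s"] = np.interp(gas.time_s, cbfv.time_s, cbfv.velocity)
    df.to_csv(path, index=False)


def read_trace_csv(path, jitter_tol: float = 0.01):
    """Read a physiological trace file (sniffed delimiter).

    Requires time_s, po2_mmHg, pco2_mmHg columns with monotone time.  Slightly
    jittered timestamps (< 1% of the median step) are regridded onto a uniform
    axis; larger jitter is an error.  Returns (GasTraces, CBFvTrace | None).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = TRACE_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time not monotone")
    steps = np.diff(t)
    med = float(np.median(steps))
    if np.max(np.abs(steps - med)) / med > jitter_tol:
        raise ValueError("time grid jitter exceeds tolerance")
    fs = 1.0 / med
    tg = t[0] + np.arange(len(t)) * med
    def col(name):
        return np.interp(tg, t, df[name].to_numpy(dtype=float))
    gas = GasTraces(time_s=tg, po2=col("po2_mmHg"), pco2=col("pco2_mmHg"),
                    fs=fs, resp=col("resp") if "resp" in df.columns else None)
    cbfv = None
    if "cbfv_cm_s" in df.columns:
        cbfv = CBFvTrace(time_s=tg, velocity=col("cbfv_cm_s"), fs=fs)
    return gas, cbfv


def write_rge_csv(path, rge: pd.DataFrame) -> None:
    rge.to_csv(path, index=False)


def read_rge_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_protocol_json(path, protocol: ProtocolSchedule) -> None:
    Path(path).write_text(json.dumps(protocol.to_dict(), indent=2))


def read_protocol_json(path) -> ProtocolSchedule:
    return ProtocolSchedule.from_dict(json.loads(Path(path).read_text()))


def _affine(voxel_dims_mm):
    aff = np.diag([*voxel_dims_mm, 1.0])
    return aff


def write_bold_nifti(prefix, bold: BoldDataset) -> dict:
    """Write data/mask/parcellation (+ truth) NIfTI-1 files and a JSON sidecar.

    ``prefix`` is a path stem; files are <prefix>_bold.nii.gz etc.  Returns
    the mapping of roles to paths.
    """
    prefix = Path(prefix)
    aff = _affine(bold.voxel_dims_mm)
    paths = {}
    def save(name, arr, dtype):
        p = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), p)
        paths[name] = str(p)
    save("bold", bold.data, np.float32)
    save("mask", bold.mask, np.uint8)
    save("parc", bold.parcellation, np.int16)
    if bold.truth_cvr is not None:
        save("truth", bold.truth_cvr, np.float32)
    sidecar = prefix.parent / f"{prefix.name}_bold.json"
    sidecar.write_text(json.dumps({
        "tr_s": bold.tr_s,
        "voxel_dims_mm": list(bold.voxel_dims_mm),
        "seed": bold.meta.get("seed"),
    }, indent=2))
    paths["sidecar"] = str(sidecar)
    return paths


def read_bold_nifti(prefix, discard_volumes: int = 0) -> BoldDataset:
    """Read a BOLD dataset written by :func:`write_bold_nifti`.

    ``discard_volumes`` drops pre-equilibrium volumes once, on read (the
    conventional 12-volume discard for real acquisitions; synthetic data
    needs none).
    """
    prefix = Path(prefix)
    def load(name):
        return nib.load(prefix.parent / f"{prefix.name}_{name}.nii.gz").get_fdata()
    sidecar = json.loads((prefix.parent / f"{prefix.name}_bold.json").read_text())
    truth_path = prefix.parent / f"{prefix.name}_truth.nii.gz"
    ds = BoldDataset(
        data=load("bold"), tr_s=sidecar["tr_s"],
        mask=load("mask").astype(bool),
        parcellation=load("parc").astype(int),
        voxel_dims_mm=tuple(sidecar["voxel_dims_mm"]),
        truth_cvr=load("truth") if truth_path.exists() else None,
    )
    if discard_volumes:
        ds = discard_initial_volumes(ds, discard_volumes)
    return ds
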