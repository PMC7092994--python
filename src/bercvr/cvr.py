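"""Voxelwise cerebrovascular reactivity (CVR) mapping.

CVR is the percent BOLD signal change per unit change of a vasoactive
regressor -- the slope of an ordinary least-squares fit of the detrended
percent-BOLD series on the regressor.  Voxelwise maps are corrected for
multiple comparisons by cluster-extent thresholding: a Monte Carlo simulation
of smooth Gaussian null volumes gives the minimum cluster volume (face
adjacency) such that suprathreshold clusters at voxel p < 0.005 survive at a
corrected alpha < 0.05.  vCVR summarizes precision per region: the percentage
of a region's voxels inside the significant mask.  Group inference uses
voxelwise one-sample / paired t-tests with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .hemo import BoldDataset

#: face adjacency (6-neighbor) connectivity for clustering
FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class CVRMaps:
    slope: np.ndarray
    tstat: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    regressor_name: str = "ber"
    challenge: str = "BH"
    sig_mask: np.ndarray | None = None
    cluster_min_mm3: float | None = None
    voxel_p: float | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class ClusterCalibration:
    cluster_min_voxels: int
    cluster_min_mm3: float
    voxel_p: float
    alpha: float
    n_iter: int
    smoothness_fwhm_mm: float
    seed: int
    max_sizes: np.ndarray  # null distribution of max cluster size (voxels)


def regress_voxelwise(
    bold_pct: np.ndarray,
    mask: np.ndarray,
    regressor: np.ndarray,
    voxel_dims_mm: tuple[float, float, float],
    regressor_name: str = "ber",
    challenge: str = "BH",
) -> CVRMaps:
    """OLS of each in-mask voxel's percent-BOLD series on the regressor.

    ``bold_pct`` is the detrended percent-change 4-D array.  Returns slope,
    t, and two-sided p volumes (t distribution with n-2 df); no cluster
    correction yet.
    """
    reg = np.asarray(regressor, dtype=float)
    n = bold_pct.shape[-1]
    if len(reg) != n:
        raise ValueError("regressor length does not match number of volumes")
    if np.std(reg) == 0:
        raise ValueError("constant regressor")
    Y = bold_pct[mask]  # (n_vox, n_t)
    xc = reg - reg.mean()
    sxx = float(np.dot(xc, xc))
    yc = Y - Y.mean(axis=1, keepdims=True)
    slope = yc @ xc / sxx
    resid = yc - slope[:, None] * xc[None, :]
    dof = n - 2
    mse = np.sum(resid ** 2, axis=1) / dof
    se = np.sqrt(mse / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.isfinite(t), p, 0.0)

    def vol(v, fill=0.0):
        out = np.full(mask.shape, fill)
        out[mask] = v
        return out

    return CVRMaps(slope=vol(slope), tstat=vol(t), p=vol(p, fill=1.0),
                   mask=mask, voxel_dims_mm=tuple(voxel_dims_mm),
                   regressor_name=regressor_name, challenge=challenge)


def regress_bold_dataset(bold: BoldDataset, regressor: np.ndarray,
                         detrend_order: int | None = None, **kw) -> CVRMaps:
    """Convenience wrapper: optional voxelwise detrend, then regression."""
    from .hemo import detrend_bold_volume
    if detrend_order is not None:
        pct = detrend_bold_volume(bold, order=detrend_order)
    else:
        pct = bold.data - 100.0  # already percent around a 100 baseline
    return regress_voxelwise(pct, bold.mask, regressor, bold.voxel_dims_mm, **kw)


def max_cluster_size(binary: np.ndarray) -> int:
    """Largest face-connected cluster in a boolean volume (voxels)."""
    labels, n = ndimage.label(binary, structure=FACE_STRUCTURE)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))))


def cluster_extent_calibrate(
    mask: np.ndarray,
    voxel_dims_mm: tuple[float, float, float],
    voxel_p: float = 0.005,
    alpha: float = 0.05,
    n_iter: int = 2000,
    smoothness_fwhm_mm: float = 8.0,
    seed: int = 0,
) -> ClusterCalibration:
    """Monte Carlo estimate of the cluster-extent threshold.

    Simulates ``n_iter`` Gaussian null volumes, smooths each to the stated
    FWHM, rescales to unit variance within the mask, thresholds two-sided at
    ``voxel_p``, and records the maximum face-connected cluster size.  The
    (1-alpha) quantile of that null distribution, converted to mm^3, is the
    minimum cluster volume controlling the corrected error rate at alpha.
    """
    if n_iter < 100:
        raise ValueError("need at least 100 iterations")
    mask = np.asarray(mask, dtype=bool)
    fov = np.array(mask.shape) * np.asarray(voxel_dims_mm)
    if smoothness_fwhm_mm >= fov.min():
        raise ValueError("smoothness exceeds the field of view")
    rng = np.random.default_rng(seed)
    zthr = stats.norm.isf(voxel_p / 2.0)
    sigma_vox = (smoothness_fwhm_mm / 2.3548) / np.asarray(voxel_dims_mm)
    max_sizes = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        if smoothness_fwhm_mm > 0:
            noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        sd = noise[mask].std()
        noise = noise / (sd if sd > 0 else 1.0)
        supra = (np.abs(noise) >= zthr) & mask
        max_sizes[i] = max_cluster_size(supra)
    cluster_min_vox = int(np.ceil(np.quantile(max_sizes, 1.0 - alpha)))
    cluster_min_vox = max(cluster_min_vox, 1)
    voxvol = float(np.prod(voxel_dims_mm))
    return ClusterCalibration(
        cluster_min_voxels=cluster_min_vox,
        cluster_min_mm3=cluster_min_vox * voxvol,
        voxel_p=voxel_p, alpha=alpha, n_iter=n_iter,
        smoothness_fwhm_mm=smoothness_fwhm_mm, seed=seed,
        max_sizes=max_sizes)


def apply_cluster_threshold(
    maps: CVRMaps,
    cluster_min_mm3: float,
    voxel_p: float = 0.005,
) -> CVRMaps:
    """Suprathreshold (p < voxel_p) voxels grouped by face adjacency;
    clusters smaller than the calibrated volume are removed (>= retained)."""
    supra = (maps.p < voxel_p) & maps.mask
    labels, n = ndimage.label(supra, structure=FACE_STRUCTURE)
    sig = np.zeros_like(supra)
    voxvol = float(np.prod(maps.voxel_dims_mm))
    if n:
        sizes = ndimage.sum_labels(supra, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes * voxvol >= cluster_min_mm3) + 1
        sig = np.isin(labels, keep)
    maps.sig_mask = sig
    maps.cluster_min_mm3 = float(cluster_min_mm3)
    maps.voxel_p = voxel_p
    return maps


def regional_summary(maps: CVRMaps, parcellation: np.ndarray,
                     region_names: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-region mean CVR and vCVR (% of region voxels in the sig mask)."""
    if parcellation.shape != maps.slope.shape:
        raise ValueError("parcellation not aligned with maps")
    if maps.sig_mask is None:
        raise ValueError("apply the cluster threshold first")
    rows = []
    for rid in np.unique(parcellation):
        if rid == 0:
            continue
        sel = (parcellation == rid) & maps.mask
        n_vox = int(sel.sum())
        rows.append({
            "region_id": int(rid),
            "region_name": (region_names or {}).get(int(rid), f"region_{rid}"),
            "mean_cvr": float(maps.slope[sel].mean()) if n_vox else np.nan,
            "vcvr": 100.0 * maps.sig_mask[sel].sum() / n_vox if n_vox else np.nan,
            "n_voxels": n_vox,
        })
    return pd.DataFrame(rows)


def _fdr_volume(t: np.ndarray, p: np.ndarray, mask: np.ndarray):
    p_fdr = np.ones_like(p)
    flat = p[mask]
    ok = np.isfinite(flat)
    adj = np.full(flat.shape, np.nan)
    if ok.any():
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    p_fdr[mask] = adj
    return p_fdr


def group_onesample(volumes: list[np.ndarray], mask: np.ndarray):
    """Voxelwise one-sample t vs 0 across subjects with BH-FDR adjustment.

    Returns (t_volume, p_fdr_volume).  Zero-variance voxels get NaN t/p and
    are excluded from the FDR family.
    """
    if len(volumes) < 3:
        raise ValueError("need at least 3 subjects")
    stack = np.stack(volumes, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_1samp(stack, 0.0, axis=0)
    var0 = np.isclose(np.var(stack, axis=0), 0.0)
    t = np.where(var0, np.nan, t)
    p = np.where(var0, np.nan, p)
    return t, _fdr_volume(t, p, mask)


def group_paired(volumes_a: list[np.ndarray], volumes_b: list[np.ndarray],
                 mask: np.ndarray):
    """Voxelwise paired t (a - b) with BH-FDR; subjects must be matched."""
    if len(volumes_a) != len(volumes_b):
        raise ValueError("unmatched subject sets")
    diffs = [a - b for a, b in zip(volumes_a, volumes_b)]
    return group_onesample(diffs, mask)
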