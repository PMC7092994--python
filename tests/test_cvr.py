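"""Voxelwise CVR regression, cluster-extent calibration against a
brute-force oracle, vCVR summaries, and group FDR inference."""

from collections import deque

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bercvr import cvr, synthetic
from bercvr.cvr import (apply_cluster_threshold, cluster_extent_calibrate,
                        group_onesample, group_paired, max_cluster_size,
                        regional_summary, regress_voxelwise)

GRID = (6, 6, 3)
VOX = (3.4, 3.4, 6.0)


def maps_from_p(p_vol, mask=None):
    mask = np.ones(p_vol.shape, bool) if mask is None else mask
    return cvr.CVRMaps(slope=np.zeros(p_vol.shape), tstat=np.zeros(p_vol.shape),
                       p=p_vol, mask=mask, voxel_dims_mm=(1.0, 1.0, 1.0))


class TestRegression:
    def test_exact_linear_fit(self):
        x = np.linspace(-1, 1, 50)
        data = np.broadcast_to(2.0 * x + 1.0, (*GRID, 50)).copy()
        maps = regress_voxelwise(data, np.ones(GRID, bool), x, VOX)
        assert np.allclose(maps.slope, 2.0)
        assert (maps.p < 1e-12).all()

    def test_independent_noise_null_slope(self, rng):
        x = rng.standard_normal(200)
        data = rng.standard_normal((*GRID, 200))
        maps = regress_voxelwise(data, np.ones(GRID, bool), x, VOX)
        se = 1.0 / (np.std(x) * np.sqrt(200))
        assert abs(maps.slope.mean()) < 3 * se / np.sqrt(np.prod(GRID))
        # p-values roughly uniform: about half below 0.5
        frac = (maps.p[np.ones(GRID, bool)] < 0.5).mean()
        assert 0.35 < frac < 0.65

    def test_truth_recovery_within_two_se(self):
        from bercvr import study
        subj = study.simulate_subject(11, with_cbfv=False, with_bold=True)
        bold = subj.bold
        # regress on the convolved drive: same units the data were built in
        conv = bold.meta["regressor_conv"]
        maps = cvr.regress_bold_dataset(bold, conv)
        err = np.abs(maps.slope - bold.truth_cvr)
        # slope SE under the generator's AR(1) noise (effective sample size
        # shrinks by (1+phi)/(1-phi))
        p = bold.meta["params"]
        n_eff = bold.n_volumes * (1 - p["ar1_coef"]) / (1 + p["ar1_coef"])
        se = p["noise_sd"] / (np.std(conv) * np.sqrt(n_eff))
        assert err.mean() < 2 * se

    def test_constant_regressor_rejected(self):
        data = np.zeros((*GRID, 20))
        with pytest.raises(ValueError, match="constant"):
            regress_voxelwise(data, np.ones(GRID, bool), np.ones(20), VOX)


def bfs_max_cluster(binary):
    """Independent face-adjacency max-cluster search (oracle)."""
    visited = np.zeros_like(binary, bool)
    best = 0
    for idx in map(tuple, np.argwhere(binary)):
        if visited[idx]:
            continue
        q = deque([idx])
        visited[idx] = True
        size = 0
        while q:
            c = q.popleft()
            size += 1
            for d in range(3):
                for off in (-1, 1):
                    nb = list(c)
                    nb[d] += off
                    nb = tuple(nb)
                    if (0 <= nb[d] < binary.shape[d] and binary[nb]
                            and not visited[nb]):
                        visited[nb] = True
                        q.append(nb)
        best = max(best, size)
    return best


class TestClusterCalibration:
    def test_permissive_alpha_limit(self):
        calib = cluster_extent_calibrate(np.ones((8, 8, 4), bool), VOX,
                                         voxel_p=0.005, alpha=0.999,
                                         n_iter=200, smoothness_fwhm_mm=0.0,
                                         seed=0)
        assert calib.cluster_min_voxels == 1

    def test_stricter_voxel_p_shrinks_clusters(self):
        mask = np.ones((12, 12, 6), bool)
        kw = dict(n_iter=200, smoothness_fwhm_mm=4.0, seed=3)
        strict = cluster_extent_calibrate(mask, VOX, voxel_p=0.001, **kw)
        loose = cluster_extent_calibrate(mask, VOX, voxel_p=0.005, **kw)
        assert strict.cluster_min_mm3 <= loose.cluster_min_mm3

    def test_matches_bruteforce_on_shared_noise(self):
        """Same null fields, independent BFS clustering: identical max-size
        distribution (isolates the labeling logic)."""
        mask = np.ones((16, 16, 16), bool)
        calib = cluster_extent_calibrate(mask, (1, 1, 1), voxel_p=0.005,
                                         n_iter=100, smoothness_fwhm_mm=0.0,
                                         seed=7)
        rng = np.random.default_rng(7)
        zthr = stats.norm.isf(0.0025)
        oracle = []
        for _ in range(100):
            noise = rng.standard_normal(mask.shape)
            noise = noise / noise.std()
            oracle.append(bfs_max_cluster(np.abs(noise) >= zthr))
        assert np.array_equal(calib.max_sizes, np.array(oracle))

    def test_null_distribution_stable_across_seeds(self):
        """Independent-seed replication: the max-cluster null distribution
        agrees within sampling error (chi-square on size counts)."""
        mask = np.ones((16, 16, 16), bool)
        kw = dict(voxel_p=0.005, n_iter=500, smoothness_fwhm_mm=0.0)
        a = cluster_extent_calibrate(mask, (1, 1, 1), seed=1, **kw).max_sizes
        b = cluster_extent_calibrate(mask, (1, 1, 1), seed=2, **kw).max_sizes
        cats = [1, 2, 3]
        ca = [np.sum(a == c) for c in cats[:-1]] + [np.sum(a >= 3)]
        cb = [np.sum(b == c) for c in cats[:-1]] + [np.sum(b >= 3)]
        chi2 = sum((x - y) ** 2 / max(x + y, 1) for x, y in zip(ca, cb))
        assert chi2 < stats.chi2.isf(0.001, df=2)

    def test_excessive_smoothness_rejected(self):
        with pytest.raises(ValueError, match="field of view"):
            cluster_extent_calibrate(np.ones(GRID, bool), VOX,
                                     smoothness_fwhm_mm=500.0, n_iter=100)


class TestApplyThreshold:
    def test_all_null_p_empty_mask(self):
        maps = apply_cluster_threshold(maps_from_p(np.ones(GRID)), 1.0)
        assert not maps.sig_mask.any()

    def test_cluster_at_exact_threshold_retained(self):
        p = np.ones(GRID)
        p[1:3, 1, 1] = 1e-4  # 2-voxel cluster, 2 mm^3 at unit voxels
        maps = apply_cluster_threshold(maps_from_p(p), cluster_min_mm3=2.0)
        assert maps.sig_mask.sum() == 2

    def test_checkerboard_singletons_removed(self):
        p = np.ones((6, 6, 2))
        xs, ys, zs = np.meshgrid(*[np.arange(s) for s in (6, 6, 2)],
                                 indexing="ij")
        p[(xs + ys + zs) % 2 == 0] = 1e-4
        maps = apply_cluster_threshold(maps_from_p(p), cluster_min_mm3=2.0)
        assert not maps.sig_mask.any()

    def test_max_cluster_size_helper(self):
        vol = np.zeros((4, 4, 4), bool)
        vol[0, 0, :3] = True      # size 3, face-connected
        vol[2, 2, 0] = vol[3, 3, 0] = True  # diagonal: separate singletons
        assert max_cluster_size(vol) == 3


class TestRegionalSummary:
    def make_maps(self, sig):
        parc = synthetic.quadrant_parcellation(GRID)
        maps = maps_from_p(np.ones(GRID))
        maps.slope = np.where(parc == 1, 2.0, 1.0)
        maps.sig_mask = sig
        return maps, parc

    def test_vcvr_extremes_and_half(self):
        parc = synthetic.quadrant_parcellation(GRID)
        sig = np.zeros(GRID, bool)
        sig[parc == 1] = True          # region 1 fully covered
        half = np.argwhere(parc == 2)
        for idx in half[: len(half) // 2]:
            sig[tuple(idx)] = True     # region 2 half covered
        maps, parc = self.make_maps(sig)
        table = regional_summary(maps, parc).set_index("region_id")
        n2 = int((parc == 2).sum())
        assert table.loc[1, "vcvr"] == pytest.approx(100.0)
        assert table.loc[2, "vcvr"] == pytest.approx(100.0 * (n2 // 2) / n2)
        assert table.loc[3, "vcvr"] == pytest.approx(0.0)
        assert table.loc[1, "mean_cvr"] == pytest.approx(2.0)

    def test_vcvr_monotone_in_cluster_threshold(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=GRID) * 0.2
        parc = synthetic.quadrant_parcellation(GRID)
        prev = None
        for thr in (0.0, 100.0, 300.0, 1000.0):
            maps = apply_cluster_threshold(maps_from_p(p.copy()), thr,
                                           voxel_p=0.05)
            vcvr = regional_summary(maps, parc)["vcvr"].mean()
            if prev is not None:
                assert vcvr <= prev + 1e-12
            prev = vcvr


class TestGroupStats:
    def test_identical_constant_voxel_flagged(self):
        vols = [np.full(GRID, 0.7) for _ in range(5)]
        t, pf = group_onesample(vols, np.ones(GRID, bool))
        assert np.isnan(t).all()

    def test_power_at_clear_effect(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            vols = [rng.normal(0.5, 0.1, GRID) for _ in range(10)]
            _, pf = group_onesample(vols, np.ones(GRID, bool))
            hits += (pf < 0.05).mean() > 0.95
        assert hits >= 19

    def test_bh_stepup_worked_example(self):
        """Step-up arithmetic by hand: p=(.01,.02,.03,.5), m=4 ->
        adjusted (.04,.04,.04,.5)."""
        vol = np.array([0.01, 0.02, 0.03, 0.5]).reshape(4, 1, 1)
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(vol.ravel(), method="fdr_bh")[1]
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_null_cohort_fdr_controlled(self):
        fracs = []
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            vols = [rng.standard_normal(GRID) for _ in range(8)]
            _, pf = group_onesample(vols, np.ones(GRID, bool))
            fracs.append((pf < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_paired_identical_maps_null(self, rng):
        vols = [rng.standard_normal(GRID) for _ in range(6)]
        t, pf = group_paired(vols, [v.copy() for v in vols],
                             np.ones(GRID, bool))
        assert np.isnan(t).all() or np.allclose(t[~np.isnan(t)], 0.0)

    def test_paired_constant_offset_detected(self):
        rng = np.random.default_rng(9)
        base = [rng.standard_normal(GRID) for _ in range(10)]
        shifted = [v + 1.0 + 0.1 * rng.standard_normal(GRID) for v in base]
        _, pf = group_paired(shifted, base, np.ones(GRID, bool))
        assert (pf < 0.05).mean() > 0.99

    def test_unmatched_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="unmatched"):
            group_paired([np.zeros(GRID)] * 3, [np.zeros(GRID)] * 4,
                         np.ones(GRID, bool))


class TestExogenousCO2Reference:
    def test_petco2_regressor_recovers_co2_driven_response(self):
        """Under the exogenous-CO2 arm the end-tidal CO2 series is the true
        drive, so regressing on it marks most responsive voxels significant
        (the reference condition for breath-hold comparisons)."""
        from bercvr import gas as gasmod
        prot = synthetic.generate_protocol("co2", seed=13)
        traces = synthetic.simulate_gas_traces(prot,
                                               synthetic.GasSimParams(seed=13))
        rge = gasmod.compute_rge_metrics(
            gasmod.detect_breath_markers(traces, resp=traces.resp))
        interp = gasmod.interpolate_over_breath_holds(rge, prot, grid=0.5)
        tvec = interp["time_s"].to_numpy()
        drive = (tvec, synthetic.standardize(interp["petco2"].to_numpy()))
        grid = (8, 8, 4)
        bold = synthetic.simulate_bold(prot, drive,
                                       synthetic.default_truth_map(grid),
                                       synthetic.HemoSimParams(seed=14),
                                       grid=grid)
        calib = cluster_extent_calibrate(bold.mask, bold.voxel_dims_mm,
                                         n_iter=200, smoothness_fwhm_mm=0.0,
                                         seed=13)
        reg = np.interp(bold.frame_times, tvec, interp["petco2"].to_numpy())
        maps = cvr.regress_bold_dataset(bold, reg, regressor_name="petco2",
                                        challenge="CO2")
        maps = apply_cluster_threshold(maps, calib.cluster_min_mm3)
        assert 100.0 * maps.sig_mask[bold.mask].mean() > 80.0


class TestVcvrOrdering:
    def test_generated_cohort_reproduces_vcvr_ordering(self):
        """Sanity (not evidence): BOLD driven by bER yields median vCVR in
        the order bER > ToB > PETCO2."""
        from bercvr import study
        df = study.vcvr_cohort(5, rows=synthetic.MRI_SESSION_SUBJECTS,
                               calib_iters=200)
        med = df.median()
        assert med["ber"] >= med["tob_s"] >= med["petco2"]
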