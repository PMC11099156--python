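"""Pair correlation, fractal fits, hinge fits, densities, domain sizes."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_locs
from nucleodyn import spatial, synth
from nucleodyn.types import CDCMap


def _csr_locs(rng, n, box=((0, 1000), (0, 2000), (0, 2000))):
    lows = np.array([lo for lo, _ in box])
    highs = np.array([hi for _, hi in box])
    zyx = lows + (highs - lows) * rng.random((n, 3))
    return make_locs(zyx[:, ::-1])  # make_locs takes (x, y, z)


def _power_law_pc(r, G, label="whole-cell"):
    return spatial.PairCorrelation(r=np.asarray(r, dtype=float),
                                   G=np.asarray(G, dtype=float),
                                   DD=np.ones_like(r), RR=np.ones_like(r),
                                   N=2, N_R=2, label=label)


class TestAxialBias:
    def test_gaussian_envelope_recovered(self):
        gt = synth.CloudGroundTruth(n_molecules=20000, d_f_true=3.0,
                                    blink_mean=1.0, blink_radius=0.0,
                                    axial_sigma=300.0, loc_error_z=0.0,
                                    loc_error_xy=0.0, seed=1)
        cloud = synth.simulate_fractal_cloud(gt)
        model = spatial.fit_axial_bias(cloud)
        assert model.sigma == pytest.approx(300.0, rel=0.1)
        assert model.center == pytest.approx(750.0, abs=50.0)

    def test_uniform_z_falls_back_with_warning(self):
        rng = np.random.default_rng(2)
        locs = _csr_locs(rng, 5000)
        with pytest.warns(UserWarning):
            model = spatial.fit_axial_bias(locs)
        assert model.sigma is None
        assert np.all(model.acceptance(np.linspace(0, 1000, 7)) == 1.0)

    def test_degenerate_identical_z_rejected(self):
        locs = make_locs(np.column_stack([np.arange(200.0), np.arange(200.0),
                                          np.full(200, 5.0)]))
        with pytest.raises(ValueError):
            spatial.fit_axial_bias(locs)


class TestPairCorrelation:
    def test_matches_brute_force_double_loop(self):
        """Package G(r) equals an O(N²) pair-histogram oracle bin by bin,
        recomputed from the stored data and reference realizations."""
        rng = np.random.default_rng(3)
        locs = _csr_locs(rng, 300)
        bins = spatial.default_bins(30, 600)
        region = spatial.BoxRegion(((0, 1000), (0, 2000), (0, 2000)))
        pc = spatial.pair_correlation(locs, region, bins=bins, n_random_factor=3,
                                      seed=7, keep_points=True)

        def brute_counts(pts):
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
            iu = np.triu_indices(len(pts), k=1)
            h, _ = np.histogram(d[iu], bins=bins)
            return 2.0 * h  # ordered pairs, matching tree counts

        dd = brute_counts(pc.data_points)
        assert np.array_equal(dd, pc.DD)
        rr_norms = [brute_counts(ref) / len(ref) ** 2 for ref in pc.reference_points]
        g_oracle = (dd / pc.N ** 2) / np.mean(rr_norms, axis=0)
        ok = np.isfinite(pc.G)
        assert np.allclose(pc.G[ok], g_oracle[ok], equal_nan=True)

    def test_csr_gives_unit_correlation(self):
        rng = np.random.default_rng(4)
        locs = _csr_locs(rng, 20000)
        region = spatial.BoxRegion(((0, 1000), (0, 2000), (0, 2000)))
        pc = spatial.pair_correlation(locs, region,
                                      bins=spatial.default_bins(50, 500),
                                      n_random_factor=3, seed=1)
        assert np.nanmean(np.abs(pc.G - 1.0)) < 0.05

    def test_clustered_cloud_exceeds_unity_at_small_r(self):
        gt = synth.CloudGroundTruth(n_molecules=15000, d_f_true=2.2,
                                    blink_mean=1.0, blink_radius=0.0,
                                    loc_error_xy=0.0, loc_error_z=0.0, seed=5)
        cloud = synth.simulate_fractal_cloud(gt)
        pc = spatial.pair_correlation(cloud, spatial.BoxRegion(gt.region),
                                      bins=spatial.default_bins(30, 600),
                                      n_random_factor=3, seed=2)
        assert pc.G[0] > 2.0
        assert abs(np.nanmean(pc.G[-10:]) - 1.0) < 0.3  # decays toward 1

    def test_invariant_to_data_thinning(self):
        """G is a density-normalized statistic: thinning the cloud leaves
        it statistically unchanged."""
        gt = synth.CloudGroundTruth(n_molecules=16000, d_f_true=2.5,
                                    blink_mean=1.0, blink_radius=0.0,
                                    loc_error_xy=0.0, loc_error_z=0.0, seed=6)
        cloud = synth.simulate_fractal_cloud(gt)
        region = spatial.BoxRegion(gt.region)
        bins = spatial.default_bins(50, 250)
        full = spatial.pair_correlation(cloud, region, bins=bins,
                                        n_random_factor=3, seed=3)
        thin = spatial.pair_correlation(cloud.sample(8000, random_state=0),
                                        region, bins=bins, n_random_factor=3,
                                        seed=3)
        ok = np.isfinite(full.G) & np.isfinite(thin.G)
        assert np.median(np.abs(thin.G[ok] - full.G[ok]) / full.G[ok]) < 0.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            spatial.pair_correlation(make_locs(np.zeros((1, 3))),
                                     spatial.BoxRegion(((0, 1), (0, 1), (0, 1))))


class TestFractalFit:
    def test_exact_power_law_curve(self):
        r = np.arange(35.0, 400.0, 10.0)
        pc = _power_law_pc(r, (r / 50.0) ** (-1.0))
        est = spatial.fit_fractal_dimension(pc)
        assert est.gamma == pytest.approx(1.0, abs=1e-12)
        assert est.d_f == pytest.approx(2.0, abs=1e-12)
        assert est.r2 == pytest.approx(1.0)
        assert est.retained

    def test_flat_curve_gives_space_filling_dimension(self):
        r = np.arange(35.0, 300.0, 10.0)
        est = spatial.fit_fractal_dimension(_power_law_pc(r, np.ones_like(r)))
        assert est.gamma == pytest.approx(0.0, abs=1e-12)
        assert est.d_f == pytest.approx(3.0)

    def test_lower_bound_respected(self):
        r = np.arange(5.0, 300.0, 10.0)
        pc = _power_law_pc(r, (r / 50.0) ** (-0.5))
        est = spatial.fit_fractal_dimension(pc, r_min=35.0)
        assert est.r_min >= 35.0

    def test_too_few_bins_rejected(self):
        pc = _power_law_pc(np.array([40.0, 50.0]), np.array([2.0, 1.5]))
        with pytest.raises(ValueError):
            spatial.fit_fractal_dimension(pc)

    def test_synthetic_cloud_dimension_recovered(self):
        ests = []
        for seed in (1, 2):
            gt = synth.CloudGroundTruth(n_molecules=20000, d_f_true=2.5,
                                        blink_mean=1.0, blink_radius=0.0,
                                        loc_error_xy=0.0, loc_error_z=0.0,
                                        seed=seed)
            cloud = synth.simulate_fractal_cloud(gt)
            pc = spatial.pair_correlation(cloud, spatial.BoxRegion(gt.region),
                                          bins=spatial.default_bins(30, 250),
                                          n_random_factor=3, seed=seed + 50)
            ests.append(spatial.fit_fractal_dimension(pc).d_f)
        assert abs(np.mean(ests) - 2.5) < 0.15


class TestHingeFit:
    def test_constructed_breakpoint_recovered_within_one_bin(self):
        r = np.arange(75.0, 510.0, 10.0)
        hinge = 205.0
        logG = np.where(r <= hinge,
                        -0.3 * np.log(r / hinge),
                        -0.1 * np.log(r / hinge))
        pc = _power_law_pc(r, np.exp(logG))
        fit = spatial.fit_two_regime_hinge(pc)
        assert abs(fit.hinge_r - hinge) <= 10.0
        assert fit.lower.gamma == pytest.approx(0.3, abs=0.02)
        assert fit.upper.gamma == pytest.approx(0.1, abs=0.02)
        assert fit.lower.d_f == pytest.approx(3.0 - 0.3, abs=0.02)
        assert not fit.degenerate

    def test_single_slope_curve_flagged_degenerate(self):
        r = np.arange(75.0, 510.0, 10.0)
        pc = _power_law_pc(r, (r / 100.0) ** (-0.4))
        fit = spatial.fit_two_regime_hinge(pc)
        assert fit.degenerate
        assert fit.lower.d_f == pytest.approx(2.6, abs=1e-6)
        assert fit.upper.d_f == pytest.approx(2.6, abs=1e-6)

    def test_window_outside_support_rejected(self):
        r = np.arange(600.0, 700.0, 10.0)
        with pytest.raises(ValueError):
            spatial.fit_two_regime_hinge(_power_law_pc(r, np.ones_like(r)))


class TestDensities:
    def test_localization_density_arithmetic(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[:1] = 1  # 100 voxels of class 1
        cdc = CDCMap(labels, K=2, voxel_size=(110.0, 110.0, 110.0))
        rng = np.random.default_rng(9)
        # 100 localizations inside class-1 voxels (z in [0, 55))
        zyx = rng.uniform([0, 0, 0], [50, 1000, 1000], (100, 3))
        locs = make_locs(zyx[:, ::-1])
        rho = spatial.localization_density(locs, cdc)
        assert rho[1] == pytest.approx(100 / (100 * 0.110 ** 3), rel=1e-6)
        assert np.isnan(rho[2])  # empty class flagged with NaN

    def test_class_densities_consistent_with_whole_mask(self):
        rng = np.random.default_rng(10)
        labels = rng.integers(1, 4, (8, 8, 8))
        cdc = CDCMap(labels, K=3, voxel_size=(100.0, 100.0, 100.0))
        # voxel i spans [(i-1/2)v, (i+1/2)v) under the divide-and-round rule
        zyx = rng.uniform(-50, 750, (5000, 3))
        locs = make_locs(zyx[:, ::-1])
        rho = spatial.localization_density(locs, cdc)
        vol_um3 = {k: (labels == k).sum() * 0.1 ** 3 for k in (1, 2, 3)}
        total = sum(rho[k] * vol_um3[k] for k in (1, 2, 3))
        assert total == pytest.approx(5000, rel=1e-6)

    def test_blink_count_from_sparse_clusters(self):
        rng = np.random.default_rng(11)
        mols = rng.uniform(0, 10000, (300, 3))  # ~1 molecule / 3.3 µm³
        bursts = np.repeat(mols, 4, axis=0) + rng.normal(0, 15, (1200, 3))
        locs = make_locs(bursts)
        est = spatial.estimate_blinks(locs, eps=100.0)
        assert est == pytest.approx(4.0, rel=0.15)

    def test_two_molecule_mean(self):
        pts = np.concatenate([np.zeros((3, 3)), np.full((5, 3), 5000.0)])
        est = spatial.estimate_blinks(make_locs(pts), eps=100.0)
        assert est == pytest.approx(4.0)

    def test_corrected_density_formula(self):
        assert spatial.corrected_nucleosome_density(100.0, 4.0, 0.044, 1.0) == \
            pytest.approx(100 / 4 / 0.044)
        assert spatial.corrected_nucleosome_density(5.0, 1.0, 1.0, 1.0) == 5.0

    def test_corrected_density_inverse_linearity(self):
        base = spatial.corrected_nucleosome_density(50.0, 2.0, 0.05, 0.5)
        assert spatial.corrected_nucleosome_density(50.0, 4.0, 0.05, 0.5) == \
            pytest.approx(base / 2)
        assert spatial.corrected_nucleosome_density(100.0, 2.0, 0.05, 0.5) == \
            pytest.approx(base * 2)

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            spatial.corrected_nucleosome_density(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            spatial.corrected_nucleosome_density(1.0, 1.0, -0.1)


class TestDomainSize:
    def test_constructed_flattening_radius_detected(self):
        r = np.arange(35.0, 800.0, 10.0)
        G = np.where(r < 400.0, (r / 400.0) ** (-0.8), 1.0)
        dom = spatial.estimate_domain_size(_power_law_pc(r, G), slope_tol=0.05)
        assert dom.r_detect == pytest.approx(400.0, abs=30.0)
        assert dom.R2_nm2 == pytest.approx(dom.r_detect ** 2)

    def test_flat_curve_flattens_immediately(self):
        r = np.arange(35.0, 300.0, 10.0)
        dom = spatial.estimate_domain_size(_power_law_pc(r, np.ones_like(r)))
        assert dom.r_detect == pytest.approx(r[0], abs=10.0)

    def test_steep_curve_never_flattens(self):
        r = np.arange(35.0, 300.0, 10.0)
        with pytest.raises(ValueError, match="never flattens"):
            spatial.estimate_domain_size(_power_law_pc(r, (r / 50.0) ** (-1.5)))
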