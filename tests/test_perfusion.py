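"""CT perfusion analytics: unmixing, regions, Homogeneity Index, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gradedtpms import perfusion_analysis as pa
from gradedtpms import synthetic_ct as sc


class TestPorosityFromHU:
    def test_pure_water_voxel(self):
        eps = pa.porosity_from_hu(np.array([[[0.0]]]), -1000.0, 0.0)
        assert eps[0, 0, 0] == 1.0

    def test_pure_air_voxel_clipped_to_floor(self):
        eps = pa.porosity_from_hu(np.array([[[-1000.0]]]), -1000.0, 0.0)
        assert eps[0, 0, 0] == pa.EPS_FLOOR

    def test_midpoint_is_half(self):
        eps = pa.porosity_from_hu(np.array([[[-500.0]]]), -1000.0, 0.0)
        assert eps[0, 0, 0] == pytest.approx(0.5)

    def test_air_scan_reference_cancels_material(self):
        # 40% solid voxel: scalar reference is biased, air-scan field is exact
        eps_true, mat = 0.6, 120.0
        water_scan = np.full((2, 2, 2), (1 - eps_true) * mat + eps_true * 0.0)
        air_scan = np.full((2, 2, 2), (1 - eps_true) * mat + eps_true * -1000.0)
        eps = pa.porosity_from_hu(water_scan, -1000.0, 0.0, air_scan=air_scan)
        assert np.allclose(eps, eps_true, atol=1e-12)

    def test_misregistration_detected(self):
        hu = np.full((4, 4, 4), 500.0)  # far above pure water
        with pytest.raises(ValueError, match="mis-registered"):
            pa.porosity_from_hu(hu, -1000.0, 0.0)

    def test_equal_constants_rejected(self):
        with pytest.raises(ValueError):
            pa.porosity_from_hu(np.zeros((2, 2, 2)), 0.0, 0.0)


class TestConcentrationFromHU:
    def test_pure_water_fluid_gives_zero(self):
        c = pa.HUConstants()
        eps = np.full((3, 3, 3), 0.4)
        hu = (1 - eps) * c.material + eps * c.water
        phi, frac = pa.concentration_from_hu(hu, eps, c)
        assert np.allclose(phi, 0.0, atol=1e-12) and frac == 0.0

    def test_pure_ca_fluid_gives_one(self):
        c = pa.HUConstants()
        eps = np.full((3, 3, 3), 0.4)
        hu = (1 - eps) * c.material + eps * c.ca
        phi, _ = pa.concentration_from_hu(hu, eps, c)
        assert np.allclose(phi, 1.0, atol=1e-12)

    def test_porosity_below_floor_rejected(self):
        c = pa.HUConstants()
        with pytest.raises(ValueError, match="floor"):
            pa.concentration_from_hu(np.zeros((2, 2, 2)), np.full((2, 2, 2), 0.01), c)

    def test_round_trip_with_phantom_is_exact(self, rng):
        eps = rng.uniform(0.1, 1.0, (6, 6, 6))
        phi = rng.uniform(0.0, 0.2, (4, 6, 6, 6))
        stack = sc.make_phantom(sc.PhantomSpec(eps, phi, np.arange(4) * 0.5))
        c = stack.constants
        eps_r = pa.porosity_from_hu(stack.water, c.air, c.water, air_scan=stack.air)
        assert np.abs(eps_r - eps).max() < 1e-10
        for frame, truth in zip(stack.frames, phi):
            rec, _ = pa.concentration_from_hu(frame, eps_r, c)
            assert np.abs(rec - truth).max() < 1e-10

    def test_recovery_error_scales_linearly_with_noise(self):
        c = pa.HUConstants()
        eps = np.full((12, 12, 12), 0.5)
        phi = np.full((1, 12, 12, 12), 0.1)
        errs = []
        for sd in (2.0, 4.0, 8.0):
            stack = sc.make_phantom(
                sc.PhantomSpec(eps, phi, np.zeros(1), noise_sd=sd, seed=7))
            rec, _ = pa.concentration_from_hu(stack.frames[0], eps, c)
            errs.append(np.abs(rec - 0.1).mean())
        assert errs[1] / errs[0] == pytest.approx(2.0, rel=0.15)
        assert errs[2] / errs[1] == pytest.approx(2.0, rel=0.15)


class TestDownsample:
    def test_constant_preserved(self):
        f = np.full((8, 8, 8), 3.3)
        assert np.allclose(pa.downsample(f, 0.5, 2.0), 3.3)

    def test_block_mean(self):
        f = np.zeros((2, 2, 2))
        f[1] = 20.0
        out = pa.downsample(f, 1.0, 2.0)
        assert out.shape == (1, 1, 1) and out[0, 0, 0] == pytest.approx(10.0)

    def test_global_mean_preserved_for_exact_blocks(self, rng):
        f = rng.random((8, 8, 8))
        assert pa.downsample(f, 1.0, 2.0).mean() == pytest.approx(f.mean())

    def test_target_below_source_rejected(self):
        with pytest.raises(ValueError):
            pa.downsample(np.zeros((4, 4, 4)), 1.0, 0.5)


class TestRegions:
    def test_partition_is_disjoint_and_covering(self):
        masks = pa.default_regions((10, 10, 4))
        total = sum(m.astype(int) for m in masks.labels.values())
        assert np.all(total == 1)

    def test_uniform_frame_reads_same_everywhere(self):
        masks = pa.default_regions((10, 10, 4))
        frames = np.full((3, 10, 10, 4), 0.07)
        curves = pa.region_curves(frames, masks)
        for c in curves.values():
            assert np.allclose(c, 0.07)

    def test_tracer_confined_to_bottom_region(self):
        masks = pa.default_regions((10, 10, 4))
        frames = np.zeros((2, 10, 10, 4))
        frames[:, masks.labels["B"]] = 0.2
        curves = pa.region_curves(frames, masks)
        assert np.all(curves["B"] > 0)
        for name in "LCRT":
            assert np.all(curves[name] == 0)

    def test_region_totals_partition_domain_total(self):
        masks = pa.default_regions((10, 10, 4))
        rng = np.random.default_rng(3)
        frames = rng.random((2, 10, 10, 4))
        curves = pa.region_curves(frames, masks)
        total = sum(curves[n] * masks.labels[n].sum() for n in curves)
        assert np.allclose(total, frames.sum(axis=(1, 2, 3)))

    def test_empty_region_rejected(self):
        masks = pa.RegionMask.__new__(pa.RegionMask)
        masks.labels = {"B": np.zeros((2, 2, 2), bool), "rest": np.ones((2, 2, 2), bool)}
        with pytest.raises(ValueError, match="empty"):
            pa.region_curves(np.zeros((1, 2, 2, 2)), masks)


class TestRegionShares:
    def test_identical_curves_equal_regions_split_evenly(self):
        curves = {k: np.array([0.0, 0.1, 0.0]) for k in "BLCRT"}
        shares = pa.region_shares(curves)
        for v in shares.values():
            assert v == pytest.approx(0.2)

    def test_single_active_region_takes_all(self):
        curves = {"B": np.array([0.1, 0.2]), "T": np.zeros(2)}
        shares = pa.region_shares(curves)
        assert shares["B"] == 1.0 and shares["T"] == 0.0

    def test_shares_sum_to_one(self, rng):
        curves = {k: rng.random(10) for k in "BLCRT"}
        assert sum(pa.region_shares(curves).values()) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_uniform_scaling(self, rng):
        curves = {k: rng.random(10) for k in "BLCRT"}
        s1 = pa.region_shares(curves)
        s2 = pa.region_shares({k: 7.0 * v for k, v in curves.items()})
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pa.region_shares({"B": np.zeros(3)})


class TestHomogeneityIndex:
    def test_uniform_field_gives_exactly_one(self):
        assert pa.homogeneity_index(np.full((6, 6, 6), 0.13)) == 1.0

    def test_two_level_plane_approaches_zero(self):
        # half the points at 20%, half at 0%, SD_max = 10 → HI → 0 as m → ∞
        m = 20000
        frame = np.zeros((1, m, 1))
        frame[0, : m // 2, 0] = 0.20
        hi = pa.homogeneity_index(frame, axis=0, sd_max=10.0)
        assert hi == pytest.approx(0.0, abs=1e-4)
        # small m: sample SD exceeds 10 → HI < 0, reported raw (no clamp)
        small = np.zeros((1, 4, 1))
        small[0, :2, 0] = 0.20
        assert pa.homogeneity_index(small, axis=0, sd_max=10.0) < 0.0

    def test_never_exceeds_one(self, rng):
        frame = rng.uniform(0, 0.2, (5, 8, 8))
        assert pa.homogeneity_index(frame, axis=0) <= 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(-0.05, 0.05))
    def test_shift_invariance(self, shift):
        rng = np.random.default_rng(5)
        frame = rng.uniform(0.05, 0.15, (4, 6, 6))
        h1 = pa.homogeneity_index(frame, axis=0)
        h2 = pa.homogeneity_index(frame + shift, axis=0)
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_downsampled_uniform_field_stays_exactly_one(self):
        f = np.full((8, 8, 8), 0.1)
        ds = pa.downsample(f, 1.0, 2.0)
        assert pa.homogeneity_index(ds) == 1.0

    def test_single_point_planes_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pa.homogeneity_index(np.zeros((4, 1, 1)), axis=0)


class TestMaxExpectedSD:
    def test_half_range_for_20_percent(self):
        assert pa.max_expected_sd(20.0) == 10.0

    def test_matches_numeric_maximization(self, rng):
        """No distribution on [0, 20] has population SD above range/2."""
        best = 0.0
        for _ in range(300):
            n = rng.integers(2, 12)
            sample = rng.uniform(0, 20, n)
            best = max(best, sample.std())  # population SD
        assert best <= pa.max_expected_sd(20.0) + 1e-12
        # equal mass at the extremes attains the bound
        attained = np.array([0.0, 20.0]).std()
        assert attained == pa.max_expected_sd(20.0)


class TestSpearman:
    def test_identical_series(self, rng):
        x = rng.random(30)
        r, p, _ = pa.spearman_validation(x, x.copy())
        assert r == 1.0

    def test_reversed_ranks(self):
        x = np.arange(20.0)
        r, _, _ = pa.spearman_validation(x, -x)
        assert r == -1.0

    def test_matches_rank_then_pearson_oracle(self, rng):
        sim = rng.random(20)
        meas = sim + 0.3 * rng.random(20)
        r, _, _ = pa.spearman_validation(sim, meas)
        oracle = np.corrcoef(stats.rankdata(sim), stats.rankdata(meas))[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pa.spearman_validation(np.ones(10), np.arange(10.0))

    def test_tie_fraction_reported(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, _, tie_frac = pa.spearman_validation(x, y)
        assert tie_frac == pytest.approx(0.2)
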