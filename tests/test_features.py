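import math

import numpy as np
import pytest

from conftest import make_mask, make_volume
from oracles import brute_gas_volume_ml, brute_hyper_volume_ml, flood_fill_components

from pleuraquant.features import (
    FeatureConfig,
    compute_gas_features,
    compute_hyper_features,
    detect_effusion,
    extract_all,
    filtered_components,
    partition_pleura,
    split_sides,
    volume_ml,
)


def ball(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    idx = np.indices(shape).astype(float)
    for d in range(3):
        idx[d] = (idx[d] - center[d]) * spacing[d]
    return (idx**2).sum(axis=0) <= radius**2


class TestVolumeMl:
    def test_simple_counts(self):
        assert volume_ml(2000, (1, 1, 1)) == pytest.approx(2.0)
        assert volume_ml(1, (2, 2, 2)) == pytest.approx(0.008)

    def test_digital_ball_matches_analytic(self):
        b = ball((24, 24, 24), (11.5, 11.5, 11.5), 10.0)
        analytic = 4.0 / 3.0 * math.pi * 10.0**3 / 1000.0  # 4.18879 mL
        assert volume_ml(b, (1, 1, 1)) == pytest.approx(analytic, rel=0.02)

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            volume_ml(10, (1.0, 0.0, 1.0))


class TestPartitionPleura:
    def test_slab_thinner_than_twice_rim_has_no_cavity(self):
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        data[6:14, 5:13, :] = 2  # 8 mm slab along x at 1 mm spacing
        mask = make_mask(data)
        rim, cavity = partition_pleura(mask, rim_mm=4.0)
        pleura = data == 2
        assert not cavity.any()
        np.testing.assert_array_equal(rim, pleura)

    def test_partition_is_exact(self):
        rng = np.random.default_rng(7)
        data = (rng.random((16, 16, 16)) > 0.5).astype(np.uint8) * 2
        mask = make_mask(data)
        rim, cavity = partition_pleura(mask, rim_mm=2.0)
        assert not (rim & cavity).any()
        np.testing.assert_array_equal(rim | cavity, data == 2)

    def test_ball_cavity_matches_analytic_erosion(self):
        b = ball((48, 48, 48), (23.5, 23.5, 23.5), 20.0)
        mask = make_mask(b.astype(np.uint8) * 2)
        _, cavity = partition_pleura(mask, rim_mm=4.0)
        inner = 4.0 / 3.0 * math.pi * 16.0**3 / 1000.0
        assert volume_ml(cavity, (1, 1, 1)) == pytest.approx(inner, rel=0.05)

    def test_cavity_matches_distance_transform_oracle(self):
        from scipy.ndimage import distance_transform_edt

        rng = np.random.default_rng(3)
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        data[4:17, 3:18, 5:16] = 2
        mask = make_mask(data, spacing=(1.0, 1.2, 0.8))
        rim, cavity = partition_pleura(mask, rim_mm=3.0)
        dist = distance_transform_edt(data == 2, sampling=(1.0, 1.2, 0.8))
        np.testing.assert_array_equal(cavity, dist - 0.2 > 3.0)


class TestFilteredComponents:
    def test_uniform_region_yields_nothing(self):
        data = np.full((10, 10, 10), 10.0)
        ct = make_volume(data)
        region = np.ones(data.shape, dtype=bool)
        assert filtered_components(ct, region, (">", 30.0), 2.0) == []

    def test_minimum_volume_prerequisite(self):
        data = np.zeros((30, 30, 30))
        data[2:22, 2:18, 2:18] = 10.0
        big = ball((30, 30, 30), (10, 10, 10), 10.6)  # ~5 mL
        small = ball((30, 30, 30), (25, 25, 25), 6.2)  # ~1 mL
        data[big] = 60.0
        data[small] = 60.0
        ct = make_volume(data)
        comps = filtered_components(
            ct, np.ones(data.shape, bool), (">", 30.0), 2.0
        )
        assert len(comps) == 1
        assert volume_ml(comps[0], (1, 1, 1)) == pytest.approx(5.0, rel=0.05)

    def test_connectivity_merging_and_separation(self):
        data = np.zeros((40, 20, 20))
        # two face-sharing cubes of ~3 mL each
        data[2:16, 2:17, 2:16] = 0.0
        data[2:10, 4:16, 4:16] = 60.0   # 8*12*12 ~ 1.15 mL... use bigger
        data[:] = 0.0
        data[2:12, 2:17, 2:22 - 2] = 0.0
        a = np.zeros_like(data, dtype=bool)
        b = np.zeros_like(data, dtype=bool)
        a[2:17, 2:16, 2:16] = True  # 15*14*14 = 2.94 mL
        b[17:32, 2:16, 2:16] = True  # face-adjacent along x
        data[a | b] = 60.0
        ct = make_volume(data)
        comps = filtered_components(ct, np.ones(data.shape, bool), (">", 30), 2.0)
        assert len(comps) == 1
        assert volume_ml(comps[0], (1, 1, 1)) == pytest.approx(5.88, rel=0.01)
        # separate by one empty voxel plane: two components
        data[17, :, :] = 0.0
        ct = make_volume(data)
        comps = filtered_components(ct, np.ones(data.shape, bool), (">", 30), 2.0)
        assert len(comps) == 2

    def test_matches_flood_fill_oracle_on_random_grids(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            from scipy.ndimage import gaussian_filter

            field = gaussian_filter(rng.normal(size=(20, 20, 20)), 1.5)
            data = np.where(field > np.quantile(field, 0.8), 60.0, 0.0)
            ct = make_volume(data)
            comps = filtered_components(
                ct, np.ones(data.shape, bool), (">", 30.0), 0.05
            )
            oracle = [
                c
                for c in flood_fill_components(data > 30.0)
                if len(c) >= 50
            ]
            assert len(comps) == len(oracle)
            got = {frozenset(zip(*np.nonzero(c))) for c in comps}
            want = {frozenset(c) for c in oracle}
            assert got == want

    def test_ordering_deterministic(self):
        data = np.zeros((30, 30, 30))
        data[2:12, 2:12, 2:12] = 60.0  # 1 mL
        data[15:28, 15:28, 15:28] = 60.0  # 2.2 mL
        ct = make_volume(data)
        comps = filtered_components(ct, np.ones(data.shape, bool), (">", 30), 0.5)
        vols = [volume_ml(c, (1, 1, 1)) for c in comps]
        assert vols == sorted(vols, reverse=True)


class TestDetectEffusion:
    def test_empty_side(self):
        mask = make_mask(np.zeros((8, 8, 8), dtype=np.uint8))
        present, vol = detect_effusion(mask)
        assert (present, vol) == (False, 0.0)

    def test_one_ml_below_default_threshold(self):
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        data[:10, :10, :10] = 0
        data[0:10, 0:10, 0:10][ball((10, 10, 10), (5, 5, 5), 6.2)[:10, :10, :10]] = 0
        d = np.zeros((20, 20, 20), dtype=np.uint8)
        d.flat[:1000] = 2  # exactly 1 mL at 1 mm
        present, vol = detect_effusion(make_mask(d))
        assert not present
        assert vol == pytest.approx(1.0)

    def test_large_effusion_detected(self, plain_phantom):
        ct, mask, gt = plain_phantom
        sides = split_sides(mask)
        present, vol = detect_effusion(sides["right"])
        assert present
        assert vol == pytest.approx(gt.per_side["right"]["effusion_ml"], rel=1e-6)


class TestSplitSides:
    def test_bilateral_volumes_match_ground_truth(self, bilateral_phantom):
        ct, mask, gt = bilateral_phantom
        sides = split_sides(mask)
        for side in ("left", "right"):
            vol = volume_ml(sides[side].region(2), mask.spacing)
            assert vol == pytest.approx(gt.per_side[side]["effusion_ml"], rel=1e-6)

    def test_unilateral_leaves_other_side_empty(self, plain_phantom):
        _, mask, _ = plain_phantom
        sides = split_sides(mask)
        assert not sides["left"].region(2).any()

    def test_union_is_partition(self, bilateral_phantom):
        _, mask, _ = bilateral_phantom
        sides = split_sides(mask)
        joint = (mask.data == 1) | (mask.data == 2)
        union = np.zeros_like(joint)
        both = np.zeros_like(joint)
        for m in sides.values():
            part = (m.data == 1) | (m.data == 2)
            both |= union & part
            union |= part
        np.testing.assert_array_equal(union, joint)
        assert not both.any()


class TestHyperFeatures:
    def _uniform_effusion(self):
        data = np.zeros((38, 38, 38), dtype=np.uint8)
        data[4:34, 4:34, 4:34] = 2
        hu = np.where(data == 2, 10.0, 0.0)
        return make_volume(hu), make_mask(data)

    def test_uniform_effusion_all_zero(self):
        ct, mask = self._uniform_effusion()
        f = compute_hyper_features(ct, mask)
        assert f["f_hyper"] == 0.0
        assert f["f_hyper_rate"] == 0.0
        assert f["f_pleura_rate"] == 0.0
        assert f["f_cavity_rate"] == 0.0
        assert math.isnan(f["f_inout_ratio"])
        assert math.isnan(f["f_inout_ratio_index"])

    def test_cavity_blob(self):
        ct, mask = self._uniform_effusion()
        blob = ball((38, 38, 38), (18.5, 18.5, 18.5), 8.0)
        ct.data[blob] = 60.0
        f = compute_hyper_features(ct, mask)
        blob_ml = volume_ml(blob, (1, 1, 1))
        assert f["f_hyper"] == pytest.approx(blob_ml, rel=1e-6)
        assert f["f_cavity_rate"] > 0
        assert f["f_pleura_rate"] == 0.0
        assert math.isnan(f["f_inout_ratio"])

    def test_hot_rim_cold_cavity(self):
        ct, mask = self._uniform_effusion()
        rim, cavity = partition_pleura(mask, 4.0)
        ct.data[rim] = 45.0
        f = compute_hyper_features(ct, mask)
        assert f["f_pleura_rate"] == pytest.approx(100.0)
        assert f["f_cavity_rate"] == pytest.approx(0.0)
        assert f["f_inout_ratio"] == pytest.approx(0.0)
        assert f["f_inout_ratio_index"] == pytest.approx(0.0)

    def test_inout_identity(self, bilateral_phantom):
        ct, mask, _ = bilateral_phantom
        for side_mask in split_sides(mask).values():
            if not side_mask.region(2).any():
                continue
            f = compute_hyper_features(ct, side_mask)
            if not math.isnan(f["f_inout_ratio"]):
                assert f["f_inout_ratio"] == pytest.approx(
                    f["f_cavity_rate"] / f["f_pleura_rate"], rel=1e-9
                )
                assert f["f_inout_ratio_index"] == pytest.approx(
                    f["f_inout_ratio"] * f["f_hyper_rate"], rel=1e-9
                )

    def test_monotone_in_threshold_and_min_volume(self):
        ct, mask = self._uniform_effusion()
        rng = np.random.default_rng(0)
        ct.data[mask.data == 2] += rng.normal(0, 25, int((mask.data == 2).sum()))
        prev = math.inf
        for thr in (10.0, 20.0, 30.0, 50.0):
            f = compute_hyper_features(
                ct, mask, FeatureConfig(hu_hyper=thr, min_volume_ml=0.01)
            )
            assert f["f_hyper"] <= prev
            prev = f["f_hyper"]
        prev = math.inf
        for mv in (0.01, 0.1, 0.5, 2.0):
            f = compute_hyper_features(
                ct, mask, FeatureConfig(min_volume_ml=mv)
            )
            assert f["f_hyper"] <= prev
            prev = f["f_hyper"]


class TestGasFeatures:
    def test_no_gas_anywhere(self):
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        data[4:16, 4:16, 4:16] = 2
        hu = np.where(data == 2, 10.0, 40.0)
        f_gas, f_pneu = compute_gas_features(make_volume(hu), make_mask(data))
        assert (f_gas, f_pneu) == (0.0, 0.0)

    def test_intrapleural_bubble_measured(self, bilateral_phantom):
        ct, mask, gt = bilateral_phantom
        sides = split_sides(mask)
        f_gas, _ = compute_gas_features(ct, sides["right"])
        assert f_gas == pytest.approx(gt.per_side["right"]["gas_ml"], rel=0.05)

    def test_pneumothorax_requires_no_airway_connection(self):
        shape = (24, 24, 24)
        mask = np.zeros(shape, dtype=np.uint8)
        hu = np.full(shape, 40.0)
        mask[4:12, 8:20, 4:20] = 1  # lung
        hu[mask == 1] = -800.0
        # airway: thin column entering the lung
        mask[13, 13, 4:20] = 3
        hu[mask == 3] = -1000.0
        # gas pocket adjacent to the lung, not touching the airway
        pocket = np.zeros(shape, dtype=bool)
        pocket[4:12, 2:8, 4:20] = True
        pocket &= mask == 0
        hu[pocket] = -1000.0
        sp = (1.5, 1.5, 1.5)
        m = make_mask(mask, spacing=sp)
        _, f_pneu = compute_gas_features(make_volume(hu, spacing=sp), m)
        assert f_pneu == pytest.approx(volume_ml(pocket, sp), rel=1e-6)
        # bridge the pocket to the airway with a sub-threshold channel
        hu2 = hu.copy()
        hu2[12:14, 2:14, 10] = -1000.0
        hu2[13, 13, 4:20] = -1000.0
        _, f_pneu2 = compute_gas_features(make_volume(hu2, spacing=sp), m)
        assert f_pneu2 == 0.0

    def test_matches_oracle_on_phantom(self, bilateral_phantom):
        ct, mask, gt = bilateral_phantom
        sides = split_sides(mask)
        f_gas, _ = compute_gas_features(ct, sides["right"])
        oracle = brute_gas_volume_ml(
            ct.data, sides["right"].data, mask.spacing, min_ml=2.0
        )
        assert f_gas == pytest.approx(oracle, abs=1e-9)


class TestExtractAll:
    def test_effusion_free_side_row(self, plain_phantom):
        ct, mask, _ = plain_phantom
        fsets = extract_all(ct, mask, radiomics="off")
        left = fsets["left"]
        assert left.total_effusion_ml == 0.0
        assert left.f_hyper == 0.0
        assert math.isnan(left.f_hyper_rate)

    def test_repeated_call_identical(self, bilateral_phantom):
        ct, mask, _ = bilateral_phantom
        a = extract_all(ct, mask, radiomics="off")
        b = extract_all(ct, mask, radiomics="off")
        for side in a:
            da, db = a[side].to_dict(), b[side].to_dict()
            assert set(da) == set(db)
            for k, v in da.items():
                if isinstance(v, float) and math.isnan(v):
                    assert math.isnan(db[k])
                else:
                    assert v == db[k]

    def test_f_hyper_matches_flood_fill_oracle(self, bilateral_phantom):
        ct, mask, _ = bilateral_phantom
        fsets = extract_all(ct, mask, radiomics="off")
        for side, side_mask in split_sides(mask).items():
            oracle = brute_hyper_volume_ml(
                ct.data, side_mask.data, mask.spacing
            )
            assert fsets[side].f_hyper == pytest.approx(oracle, abs=1e-9)
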