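import numpy as np
import pytest
from scipy import ndimage

from zernseg.errors import ContractError, DomainError
from zernseg.morphometry import (
    cleanup,
    connected_units,
    merge_and_crop,
    porosity,
    report,
    thickness_map,
)
from zernseg.volumes import CLASSES, LabelVolume


def lab4(data):
    return LabelVolume(np.asarray(data, np.uint8), CLASSES, 94.0)


def brute_force_thickness(mask: np.ndarray) -> np.ndarray:
    """Independent oracle: largest inscribed sphere by direct enumeration.

    Sphere radius at a centre voxel is EDT - 0.5; every in-mask voxel within
    that radius is covered; thickness is twice the largest covering radius.
    """
    mask = np.asarray(mask, bool)
    rad = ndimage.distance_transform_edt(mask) - 0.5
    out = np.zeros(mask.shape)
    for c in np.argwhere(mask):
        r = rad[tuple(c)]
        lo = np.maximum(0, np.floor(c - r).astype(int))
        hi = np.minimum(mask.shape, np.ceil(c + r + 1).astype(int))
        sub = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].reshape(3, -1).T
        cov = sub[((sub - c) ** 2).sum(1) <= r * r + 1e-9]
        for v in cov:
            t = tuple(v)
            if mask[t]:
                out[t] = max(out[t], 2 * r)
    return out


class TestCleanup:
    def test_small_island_reassigned_to_neighbor_majority(self):
        data = np.ones((8, 8, 8), np.uint8) * 3  # lcn everywhere
        data[3:4, 3:5, 3:5] = 1  # 4-voxel bone island inside lcn
        out = cleanup(lab4(data), island_min_vox=10, closing_radius=0)
        assert (out.data == 3).all()

    def test_clean_labels_are_fixed_point(self):
        data = np.zeros((8, 8, 8), np.uint8)
        data[2:6, 2:6, 2:6] = 1
        lab = lab4(data)
        out = cleanup(lab, island_min_vox=5, closing_radius=0)
        assert np.array_equal(out.data, lab.data)

    def test_closing_radius_zero_is_identity_component(self):
        rng = np.random.default_rng(4)
        data = (rng.random((10, 10, 10)) > 0.5).astype(np.uint8)
        lab = lab4(data)
        out0 = cleanup(lab, island_min_vox=1, closing_radius=0)  # min 1: no islands removed
        assert np.array_equal(out0.data, lab.data)

    def test_voxel_count_conserved(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 4, (12, 12, 12)).astype(np.uint8)
        out = cleanup(lab4(data), island_min_vox=5, closing_radius=1)
        assert out.data.size == data.size  # reassignment, never removal


class TestMergeAndCrop:
    def test_shade_off_merged_into_bone(self):
        data = np.zeros((6, 6, 6), np.uint8)
        data[1:5, 1:5, 1:5] = 1
        data[2, 2, 2] = 2
        out = merge_and_crop(lab4(data))
        assert "shade_off" not in out.class_set or (out.data == out.class_set.index("shade_off")).sum() == 0
        assert out.class_set == ("background", "bone", "lcn")

    def test_crop_to_bounding_box(self):
        data = np.zeros((30, 30, 30), np.uint8)
        data[10:20, 10:20, 10:20] = 1
        out = merge_and_crop(lab4(data))
        assert out.shape == (10, 10, 10)

    def test_all_background_is_error(self):
        with pytest.raises(DomainError):
            merge_and_crop(lab4(np.zeros((6, 6, 6))))


class TestPorosity:
    def test_printed_arithmetic(self):
        data = np.ones((10, 10, 10), np.uint8)  # 1000 bone voxels
        data.ravel()[:21] = 3  # 21 lcn
        assert porosity(lab4(data)) == pytest.approx(2.1)

    def test_zero_lcn_is_zero_percent(self):
        data = np.ones((5, 5, 5), np.uint8)
        assert porosity(lab4(data)) == 0.0

    def test_alternative_denominator(self):
        data = np.ones((10, 10, 10), np.uint8)
        data.ravel()[:21] = 3
        assert porosity(lab4(data), denominator="bone") == pytest.approx(100 * 21 / 979)

    def test_empty_volume_is_domain_error(self):
        with pytest.raises(DomainError):
            porosity(lab4(np.zeros((4, 4, 4))))


class TestThickness:
    def test_matches_brute_force_on_random_masks(self):
        # >= 20 seeded random masks, all <= 20^3
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mask = ndimage.binary_closing(rng.random((10, 10, 10)) > 0.6)
            if not mask.any():
                continue
            impl, _ = thickness_map(mask, 94.0)
            assert np.allclose(impl, brute_force_thickness(mask)), f"seed {seed}"

    def test_solid_ball_radius_five(self):
        g = np.mgrid[-8:9, -8:9, -8:9]
        ball = (g**2).sum(axis=0) <= 25
        impl, stats = thickness_map(ball, 94.0)
        expected = brute_force_thickness(ball).max()  # 9.198 under the EDT-1/2 convention
        assert impl.max() == pytest.approx(expected)
        assert impl.max() == pytest.approx(9.198, abs=1e-3)
        assert stats.max_um == pytest.approx(impl.max() * 0.094, rel=1e-6)

    def test_single_voxel_thickness_one(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        impl, _ = thickness_map(m, 94.0)
        assert impl[2, 2, 2] == pytest.approx(1.0)

    def test_three_voxel_tube_interior(self):
        tube = np.zeros((20, 9, 9), bool)
        tube[:, 3:6, 3:6] = True
        impl, _ = thickness_map(tube, 94.0)
        assert impl[10, 4, 4] == pytest.approx(3.0)
        assert impl[10, 4, 4] == pytest.approx(brute_force_thickness(tube)[10, 4, 4])

    def test_empty_mask_is_domain_error(self):
        with pytest.raises(DomainError):
            thickness_map(np.zeros((4, 4, 4), bool), 94.0)


class TestConnectedUnits:
    def test_min_size_filter(self):
        m = np.zeros((20, 20, 20), bool)
        m[1:6, 1:7, 1:6] = True  # 150 voxels
        m[10:12, 10:15, 10:15] = True  # 50 voxels
        units = connected_units(m, 94.0, component_min_vox=100)
        assert len(units) == 1
        assert units[0]["voxel_count"] == 150

    def test_diagonal_voxels_connectivity(self):
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = m[1, 1, 1] = True
        assert len(connected_units(m, 94.0, component_min_vox=1, connectivity=26)) == 1
        assert len(connected_units(m, 94.0, component_min_vox=1, connectivity=6)) == 2

    def test_volume_conversion(self):
        m = np.zeros((10, 10, 10), bool)
        m.ravel()[:100] = True
        m = m.reshape(10, 10, 10)
        units = connected_units(m, 94.0, component_min_vox=1)
        total = sum(u["volume_um3"] for u in units)
        assert total == pytest.approx(100 * 0.094**3)  # 0.0830584 um^3

    def test_bad_connectivity(self):
        with pytest.raises(ContractError):
            connected_units(np.ones((2, 2, 2), bool), 94.0, connectivity=18)


class TestReport:
    def test_phantom_units_bounded_by_lacuna_graph(self, small_phantom):
        rep = report(small_phantom.labels, component_min_vox=100)
        assert 1 <= rep.n_components <= small_phantom.graph_components
        assert rep.porosity_percent == pytest.approx(
            100 * small_phantom.realized_porosity, abs=0.2
        )

    def test_empty_lcn_reports_zero(self):
        data = np.zeros((8, 8, 8), np.uint8)
        data[2:6, 2:6, 2:6] = 1
        rep = report(lab4(data))
        assert rep.porosity_percent == 0.0
        assert rep.components == []

    def test_rerun_is_identical(self, small_phantom):
        r1 = report(small_phantom.labels, component_min_vox=100)
        r2 = report(small_phantom.labels, component_min_vox=100)
        assert r1.to_json() == r2.to_json()

    def test_report_carries_params_and_hash(self, small_phantom):
        rep = report(small_phantom.labels, seed=3)
        assert rep.params["seed"] == 3
        assert len(rep.config_hash) == 12
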