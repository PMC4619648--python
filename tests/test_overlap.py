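"""Dice, occupancy, extents, regional fractions and the comparison report."""

import numpy as np
import pytest

from braincast import (
    BinaryMask,
    LabelVolume,
    RegionTable,
    RigidTransform,
    analytic_pair,
    build_report,
    dice_coefficient,
    extent_measurements,
    occupancy_fraction,
    region_length_fractions,
    resample_mask,
)
from braincast.distance import DistanceSummary


def cube_mask(n, lo, size, spacing=1.0):
    g = np.zeros((n, n, n), dtype=np.uint8)
    g[lo : lo + size, lo : lo + size, lo : lo + size] = 1
    return BinaryMask(grid=g, spacing=(spacing,) * 3)


class TestDice:
    def test_identity_is_one_and_symmetric(self):
        a = cube_mask(10, 2, 5)
        assert dice_coefficient(a, a) == 1.0
        b = cube_mask(10, 3, 5)
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_disjoint_masks_give_zero(self):
        a = cube_mask(12, 1, 3)
        b = cube_mask(12, 7, 3)
        assert dice_coefficient(a, b) == 0.0

    def test_offset_spheres_match_lens_formula_oracle(self):
        a, b, truth = analytic_pair("offset_spheres", radius_vox=10, offset_vox=5)
        measured = dice_coefficient(a, b)
        assert truth["dice"] == pytest.approx(0.6328, abs=5e-4)  # (pi/12)(4r+d)(2r-d)^2 / V_sphere
        assert measured == pytest.approx(truth["dice"], rel=0.02)

    def test_monotone_decrease_with_offset(self):
        dices = [
            dice_coefficient(*analytic_pair("offset_spheres", radius_vox=8, offset_vox=d)[:2])
            for d in (0, 2, 4, 6)
        ]
        assert all(x > y for x, y in zip(dices, dices[1:]))

    def test_grid_mismatch_and_double_empty_rejected(self):
        a = cube_mask(10, 2, 5)
        b = cube_mask(12, 2, 5)
        with pytest.raises(ValueError):
            dice_coefficient(a, b)
        e = BinaryMask(grid=np.zeros((10, 10, 10), dtype=np.uint8), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            dice_coefficient(e, e)


class TestResample:
    def test_identity_transform_keeps_mask(self):
        a = cube_mask(12, 3, 5)
        out = resample_mask(a, RigidTransform.identity(), a)
        assert np.array_equal(out.grid, a.grid)

    def test_integer_voxel_translation_is_exact_shift(self):
        a = cube_mask(16, 3, 5)
        T = RigidTransform(np.eye(3), np.array([2.0, 0.0, 0.0]))
        out = resample_mask(a, T, a)
        assert np.array_equal(out.grid, np.roll(a.grid, 2, axis=0))

    def test_90_degree_rotation_preserves_cube_voxel_count(self):
        n = 21
        g = np.zeros((n, n, n), dtype=np.uint8)
        g[8:14, 6:12, 9:15] = 1
        centre = (n - 1) / 2.0
        a = BinaryMask(grid=g, spacing=(1, 1, 1), origin=(-centre, -centre, -centre))
        T = RigidTransform.from_euler_deg((0, 0, 90))
        out = resample_mask(a, T, a)
        assert out.count == a.count  # axis permutation: exact
        expected = np.rot90(g, k=1, axes=(0, 1))  # oracle: +90 deg about z maps x->y
        assert np.array_equal(out.grid, expected)

    def test_voxel_count_conserved_within_2pct_for_moderate_rotations(self):
        a, _, _ = analytic_pair("offset_spheres", radius_vox=9, offset_vox=0)
        big = BinaryMask(
            grid=np.pad(a.grid, 6), spacing=a.spacing, origin=a.origin - 6 * a.spacing
        )
        c = (np.array(big.shape) - 1) / 2.0
        T = RigidTransform.from_euler_deg((12, -18, 7))
        T = RigidTransform(T.rotation, c - T.rotation @ c)  # rotate about grid centre
        out = resample_mask(big, T, big)
        assert out.count == pytest.approx(big.count, rel=0.02)

    def test_out_of_bounds_transform_rejected(self):
        a = cube_mask(10, 3, 4)
        T = RigidTransform(np.eye(3), np.array([50.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            resample_mask(a, T, a)


class TestOccupancy:
    def test_nested_cubes_exact(self):
        inner, outer, truth = analytic_pair("nested_cubes", inner_vox=10, outer_vox=20)
        occ, protrusion = occupancy_fraction(inner, outer)
        assert occ == truth["occupancy_pct"] == 12.5
        assert protrusion == 0

    def test_self_occupancy_is_100(self):
        a = cube_mask(10, 2, 6)
        occ, protrusion = occupancy_fraction(a, a)
        assert occ == 100.0 and protrusion == 0

    def test_protrusion_counted(self):
        inner = cube_mask(12, 2, 6)
        outer = cube_mask(12, 4, 6)
        occ, protrusion = occupancy_fraction(inner, outer)
        inter = np.count_nonzero(inner.grid & outer.grid)
        assert protrusion == inner.count - inter

    def test_empty_outer_rejected(self):
        a = cube_mask(8, 2, 3)
        e = BinaryMask(grid=np.zeros((8, 8, 8), dtype=np.uint8), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            occupancy_fraction(a, e)

    def test_cross_metric_consistency_with_dice(self):
        """occupancy * |outer| and Dice * (|A|+|B|) both recover 2|A∩B|."""
        a, b, _ = analytic_pair("offset_spheres", radius_vox=8, offset_vox=4)
        occ, _ = occupancy_fraction(a, b)
        dice = dice_coefficient(a, b)
        inter_from_occ = occ / 100.0 * b.count
        inter_from_dice = dice * (a.count + b.count) / 2.0
        assert inter_from_occ == pytest.approx(inter_from_dice, abs=1e-6)


class TestExtents:
    def test_cuboid_arithmetic(self):
        g = np.zeros((110, 60, 30), dtype=np.uint8)
        g[:100, :50, :25] = 1
        mask = BinaryMask(grid=g, spacing=(0.0165,) * 3)
        length, width, height = extent_measurements(mask)
        # anatomical mapping: length=z, width=x, height=y
        assert width == pytest.approx(100 * 0.0165)
        assert height == pytest.approx(50 * 0.0165)
        assert length == pytest.approx(25 * 0.0165)

    def test_single_voxel_reports_one_spacing(self):
        g = np.zeros((5, 5, 5), dtype=np.uint8)
        g[2, 2, 2] = 1
        assert extent_measurements(BinaryMask(grid=g, spacing=(0.1, 0.2, 0.3))) == (0.3, 0.1, 0.2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extent_measurements(BinaryMask(grid=np.zeros((3, 3, 3), dtype=np.uint8), spacing=(1, 1, 1)))


REGIONS = RegionTable(
    entries={
        1: {"name": "fore", "group": "forebrain"},
        2: {"name": "mid", "group": "midbrain"},
        3: {"name": "hind", "group": "hindbrain"},
    }
)


def slab_volume(spans, n=100):
    """Label volume with group spans along the AP axis: spans[label] = (lo, hi)."""
    g = np.zeros((4, 4, n), dtype=np.uint8)
    for label, (lo, hi) in spans.items():
        g[:, :, lo:hi] = label
    return LabelVolume(grid=g, spacing=(1, 1, 1))


class TestRegionFractions:
    def test_forty_ten_fifty_by_construction(self):
        vol = slab_volume({1: (0, 40), 2: (40, 50), 3: (50, 100)})
        for mode in ("raw", "partition"):
            f = region_length_fractions(vol, REGIONS, mode=mode)
            assert f["forebrain"] == pytest.approx(40.0)
            assert f["midbrain"] == pytest.approx(10.0)
            assert f["hindbrain"] == pytest.approx(50.0)

    def test_overlapping_spans_raw_exceeds_100_partition_sums_to_100(self):
        g = np.zeros((4, 4, 100), dtype=np.uint8)
        g[:, :, 0:45] = 1
        g[:2, :, 35:55] = 2  # overlaps the forebrain slab
        g[:, :, 55:100] = 3
        g[2:, :, 45:55] = 2
        vol = LabelVolume(grid=g, spacing=(1, 1, 1))
        raw = region_length_fractions(vol, REGIONS, mode="raw")
        # slice-histogram oracle for the raw spans
        for label, group in ((1, "forebrain"), (2, "midbrain"), (3, "hindbrain")):
            occupied = np.flatnonzero((g == label).any(axis=(0, 1)))
            assert raw[group] == pytest.approx(100.0 * (occupied.max() - occupied.min() + 1) / 100.0)
        assert sum(raw.values()) > 100.0
        part = region_length_fractions(vol, REGIONS, mode="partition")
        assert sum(part.values()) == pytest.approx(100.0, abs=1e-9)

    def test_missing_group_is_configuration_error(self):
        vol = slab_volume({1: (0, 50), 3: (50, 100)})
        with pytest.raises(ValueError):
            region_length_fractions(vol, REGIONS)

    def test_single_group_table_rejected_without_required_groups(self):
        only = RegionTable(entries={1: {"name": "fore", "group": "forebrain"}})
        vol = slab_volume({1: (0, 100)})
        with pytest.raises(ValueError):
            region_length_fractions(vol, only)

    def test_region_table_yaml_round_trip(self, tmp_path):
        path = REGIONS.to_yaml(tmp_path / "regions.yaml")
        back = RegionTable.from_yaml(path)
        assert back.entries == REGIONS.entries


def dummy_summary(mean=0.04, mx=0.59):
    return DistanceSummary(
        mean_abs=mean, max_abs=mx, mean_a_to_b=mean, mean_b_to_a=mean,
        max_a_to_b=mx, max_b_to_a=mx, n_a=10, n_b=10,
    )


class TestReport:
    def make(self):
        return build_report(
            dice=0.9,
            occupancy=(83.0, 12),
            summary=dummy_summary(),
            brain_volume_mm3=8.0,
            endocast_volume_mm3=9.6,
            extents_mm={"length": 6.0, "width": 3.1, "height": 1.7},
            region_length_pct={"forebrain": 40.0, "midbrain": 10.0, "hindbrain": 50.0},
        )

    def test_round_trip_and_determinism(self, tmp_path):
        r = self.make()
        j1 = r.to_json(tmp_path / "r1.json")
        j2 = self.make().to_json(tmp_path / "r2.json")
        assert j1 == j2  # byte-identical on identical inputs
        assert (tmp_path / "r1.json").read_bytes() == (tmp_path / "r2.json").read_bytes()
        from braincast import ComparisonReport

        back = ComparisonReport.from_json(tmp_path / "r1.json")
        assert back.dice == r.dice and back.occupancy_pct == r.occupancy_pct

    def test_csv_contains_all_metrics(self, tmp_path):
        frame = self.make().to_csv(tmp_path / "r.csv")
        assert set(frame.columns) == {"metric", "value"}
        assert "occupancy_pct" in set(frame.metric)
        assert (tmp_path / "r.csv").exists()

    def test_inconsistent_fractions_rejected(self):
        with pytest.raises(ValueError):
            build_report(
                dice=0.9,
                occupancy=(83.0, 0),
                summary=dummy_summary(),
                brain_volume_mm3=8.0,
                endocast_volume_mm3=9.6,
                extents_mm={"length": 6.0, "width": 3.1, "height": 1.7},
                region_length_pct={"forebrain": 60.0, "midbrain": 10.0, "hindbrain": 50.0},
            )

    def test_missing_required_metric_rejected(self):
        with pytest.raises(ValueError):
            build_report(
                dice=None,
                occupancy=(83.0, 0),
                summary=dummy_summary(),
                brain_volume_mm3=8.0,
                endocast_volume_mm3=9.6,
                extents_mm={},
            )

    def test_mean_above_max_rejected(self):
        with pytest.raises(ValueError):
            dummy_summary(mean=0.6, mx=0.5)
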