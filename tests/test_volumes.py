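"""Image I/O, mask construction, and grid <-> matrix round trips."""

import numpy as np
import pytest

from decm.errors import FormatError, ShapeError, ValidationError
from decm.volumes import (
    Mask3D,
    Volume4D,
    build_functional_mask,
    build_graymatter_mask,
    combine_group_masks,
    extract_timeseries,
    insert_map,
    intersect_masks,
    read_volume4d,
    write_volume4d,
)


class TestNiftiIO:
    def test_write_read_roundtrip_identity(self, small_volume, tmp_path):
        path = write_volume4d(small_volume, tmp_path / "vol.nii.gz")
        back = read_volume4d(path)
        np.testing.assert_array_equal(back.data, small_volume.data)
        np.testing.assert_allclose(back.affine, small_volume.affine)
        assert back.tr == pytest.approx(2.5)
        assert back.voxel_size == pytest.approx((3.0, 3.0, 3.0))

    def test_3d_promoted_to_single_frame(self, tmp_path):
        vol = Volume4D(data=np.ones((4, 4, 4)), affine=np.eye(4))
        path = write_volume4d(Volume4D(data=vol.data[..., 0]), tmp_path / "m.nii")
        assert read_volume4d(path).n_volumes == 1

    def test_5d_file_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((3, 3, 3, 2, 2)), np.eye(4)), tmp_path / "bad.nii")
        with pytest.raises(FormatError):
            read_volume4d(tmp_path / "bad.nii")

    def test_corrupt_file_raises_ioerror_naming_path(self, tmp_path):
        bad = tmp_path / "corrupt.nii"
        bad.write_bytes(b"this is not a nifti file")
        with pytest.raises(IOError, match="corrupt.nii"):
            read_volume4d(bad)


class TestGrayMatterMask:
    def test_strict_threshold(self):
        dens = np.zeros((3, 1, 1, 1))
        dens[:, 0, 0, 0] = [0.1, 0.25, 0.5]
        m = build_graymatter_mask(Volume4D(data=dens), threshold=0.2)
        np.testing.assert_array_equal(m.data[:, 0, 0], [0, 1, 1])

    @pytest.mark.parametrize(
        "fill,expected_count", [(0.0, 0), (1.0, 27)], ids=["all-zero", "uniform-one"]
    )
    def test_degenerate_densities(self, fill, expected_count):
        m = build_graymatter_mask(Volume4D(data=np.full((3, 3, 3, 1), fill)), threshold=0.2)
        assert m.count == expected_count

    def test_out_of_range_density_rejected(self):
        with pytest.raises(ValidationError):
            build_graymatter_mask(Volume4D(data=np.full((2, 2, 2, 1), 1.5)))


class TestFunctionalMask:
    def test_retains_complement_of_percentile(self, rng):
        # 1000 voxels with distinct temporal minima: 20th percentile keeps 800
        data = rng.uniform(1, 2, size=(10, 10, 10, 5))
        minima = rng.permutation(1000).reshape(10, 10, 10).astype(float)
        data = np.concatenate([data, minima[..., None] - 1000], axis=3)
        m = build_functional_mask(Volume4D(data=data), percentile=20)
        assert m.count == 800

    def test_constant_volume_excluded_by_strict_rule(self):
        m = build_functional_mask(Volume4D(data=np.ones((4, 4, 4, 3))), percentile=20)
        assert m.count == 0  # all minima tie at the threshold; strict > excludes

    def test_single_frame_equals_thresholding_that_frame(self, rng):
        frame = rng.standard_normal((6, 6, 6, 1))
        m = build_functional_mask(Volume4D(data=frame), percentile=50)
        thr = np.percentile(frame, 50)
        np.testing.assert_array_equal(m.data.astype(bool), frame[..., 0] > thr)


class TestGroupMasks:
    def _masks(self, present_counts):
        out = []
        for i in range(4):
            data = np.zeros((2, 1, 1))
            data[0, 0, 0] = 1 if i < present_counts[0] else 0
            data[1, 0, 0] = 1 if i < present_counts[1] else 0
            out.append(Mask3D(data=data))
        return out

    def test_inclusive_boundary(self):
        m = combine_group_masks(self._masks((3, 2)), fraction=0.75)
        assert m.data[0, 0, 0] == 1  # 3/4 = 0.75 >= 0.75
        assert m.data[1, 0, 0] == 0  # 2/4 < 0.75

    def test_single_mask_identity(self, ball_mask):
        np.testing.assert_array_equal(
            combine_group_masks([ball_mask], fraction=0.4).data, ball_mask.data
        )

    def test_monotone_in_fraction(self, rng):
        masks = [Mask3D(data=rng.integers(0, 2, size=(5, 5, 5))) for _ in range(6)]
        counts = [
            combine_group_masks(masks, fraction=f).count for f in (0.2, 0.5, 0.8, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_idempotent_on_identical_masks(self, ball_mask):
        m = combine_group_masks([ball_mask] * 5, fraction=0.75)
        np.testing.assert_array_equal(m.data, ball_mask.data)

    def test_mismatched_grids_rejected(self, ball_mask):
        other = Mask3D(data=np.ones((4, 4, 4)))
        with pytest.raises(ShapeError):
            combine_group_masks([ball_mask, other])


class TestIntersect:
    def test_disjoint_masks_empty(self):
        a = Mask3D(data=np.eye(3)[..., None] * 0)
        a.data[0] = 1
        b = Mask3D(data=np.zeros((3, 3, 1)))
        b.data[1] = 1
        assert intersect_masks([a, b]).count == 0

    def test_self_exclusion_empty(self, ball_mask):
        assert intersect_masks([ball_mask], [ball_mask]).count == 0

    def test_full_grid_identity(self, ball_mask):
        full = Mask3D(data=np.ones(ball_mask.shape))
        np.testing.assert_array_equal(
            intersect_masks([ball_mask, full]).data, ball_mask.data
        )


class TestExtractInsert:
    def test_roundtrip_restores_in_mask_values(self, small_volume, rng):
        mask = Mask3D(
            data=rng.integers(0, 2, size=small_volume.shape3d),
            affine=small_volume.affine,
        )
        ts = extract_timeseries(small_volume, mask)
        assert ts.values.shape == (mask.count, 20)
        back = insert_map(ts.values, mask, fill=-1.0)
        inmask = mask.data.astype(bool)
        np.testing.assert_array_equal(back.data[inmask], small_volume.data[inmask])
        assert np.all(back.data[~inmask] == -1.0)

    def test_traversal_order_x_fastest(self):
        data = np.arange(2 * 2 * 2 * 1, dtype=float).reshape(2, 2, 2, 1)
        mask = Mask3D(data=np.ones((2, 2, 2)))
        ts = extract_timeseries(Volume4D(data=data), mask)
        # Fortran order: (0,0,0),(1,0,0),(0,1,0),(1,1,0),(0,0,1)...
        np.testing.assert_array_equal(ts.voxel_index[:3], [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        np.testing.assert_array_equal(ts.values[:, 0], data[..., 0].ravel(order="F"))

    def test_full_grid_mask_gives_all_voxels(self, small_volume):
        mask = Mask3D(data=np.ones(small_volume.shape3d), affine=small_volume.affine)
        assert extract_timeseries(small_volume, mask).n_voxels == 1000

    def test_empty_mask_rejected(self, small_volume):
        mask = Mask3D(data=np.zeros(small_volume.shape3d), affine=small_volume.affine)
        with pytest.raises(ValidationError):
            extract_timeseries(small_volume, mask)

    def test_length_mismatch_rejected(self, ball_mask):
        with pytest.raises(ShapeError):
            insert_map(np.ones(ball_mask.count + 1), ball_mask)
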