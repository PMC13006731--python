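"""Volume data model, residual arithmetic, NIfTI round trips, slice batching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rst2g
from rst2g import (AlignmentError, DCEStudy, SliceBatch, ValidationError,
                   Volume, assemble_slice_batches, compute_residual,
                   load_manifest, load_study, normalize_volume, read_volume,
                   write_mask, write_volume)


def vol(arr, spacing=(1.0, 1.0, 1.0), pid="p0"):
    return Volume(np.asarray(arr, dtype=np.float32), spacing, pid)


class TestVolume:
    def test_rejects_non_finite_voxels(self):
        with pytest.raises(ValidationError):
            vol(np.array([[[np.nan]]]))

    def test_rejects_non_positive_spacing(self):
        with pytest.raises(ValidationError):
            vol(np.zeros((2, 2, 2)), spacing=(1.0, 0.0, 1.0))

    def test_rejects_wrong_rank(self):
        with pytest.raises(ValidationError):
            Volume(np.zeros((2, 2)))


class TestResidual:
    def test_identical_phases_give_zero_residual(self):
        v = vol(np.arange(8.0).reshape(2, 2, 2))
        assert np.all(compute_residual(v, v).voxels == 0)

    def test_zero_pre_returns_post_exactly(self):
        post = vol(np.arange(8.0).reshape(2, 2, 2))
        res = compute_residual(vol(np.zeros((2, 2, 2))), post)
        assert np.array_equal(res.voxels, post.voxels)

    def test_elementwise_subtraction(self):
        pre = vol([[[1, 2], [3, 4]]])
        post = vol([[[2, 2], [5, 3]]])
        expected = np.array([[[1, 0], [2, -1]]], dtype=np.float32)
        assert np.array_equal(compute_residual(pre, post).voxels, expected)

    def test_shape_mismatch_raises_alignment_error(self):
        with pytest.raises(AlignmentError):
            compute_residual(vol(np.zeros((2, 2, 2))), vol(np.zeros((2, 2, 3))))

    def test_spacing_mismatch_raises_alignment_error(self):
        with pytest.raises(AlignmentError):
            compute_residual(vol(np.zeros((2, 2, 2))),
                             vol(np.zeros((2, 2, 2)), spacing=(2.0, 1.0, 1.0)))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_residual_plus_pre_recovers_post(self, seed):
        r = np.random.default_rng(seed)
        pre = vol(r.normal(size=(3, 4, 4)))
        post = vol(r.normal(size=(3, 4, 4)))
        res = compute_residual(pre, post)
        assert np.allclose(res.voxels + pre.voxels, post.voxels, atol=1e-6)


class TestNormalize:
    def test_rescales_to_unit_range(self):
        v = normalize_volume(vol(np.array([2.0, 4.0, 6.0]).reshape(1, 1, 3)))
        assert np.allclose(v.voxels.ravel(), [0.0, 0.5, 1.0])

    def test_constant_volume_maps_to_zeros(self):
        v = normalize_volume(vol(np.full((2, 2, 2), 5.0)))
        assert np.all(v.voxels == 0)

    def test_unit_spanning_volume_keeps_endpoints(self):
        v = normalize_volume(vol(np.array([0.0, 0.3, 1.0]).reshape(1, 1, 3)))
        assert v.voxels.min() == 0.0 and v.voxels.max() == 1.0


class TestStudy:
    def test_mask_must_be_binary(self):
        pre = vol(np.zeros((2, 2, 2)))
        bad_mask = vol(np.full((2, 2, 2), 2.0))
        with pytest.raises(ValidationError, match="binary"):
            DCEStudy.from_phases(pre, [pre], bad_mask)

    def test_residual_uses_selected_phase(self):
        pre = vol(np.zeros((2, 2, 2)))
        posts = [vol(np.full((2, 2, 2), float(i + 1))) for i in range(3)]
        mask = vol(np.zeros((2, 2, 2)))
        study = DCEStudy.from_phases(pre, posts, mask, phase_index=0,
                                     normalize=False)
        assert study.phase_index_used == 0
        assert np.all(study.residual.voxels == posts[0].voxels - pre.voxels)

    def test_normalized_residual_is_bounded(self, rng):
        pre = vol(rng.uniform(0, 500, (3, 4, 4)))
        post = vol(rng.uniform(0, 900, (3, 4, 4)))
        mask = vol((rng.uniform(size=(3, 4, 4)) > 0.8).astype(np.float32))
        study = DCEStudy.from_phases(pre, [post], mask)
        assert study.residual.voxels.min() >= -1.0
        assert study.residual.voxels.max() <= 1.0


class TestNiftiIO:
    def test_round_trip_preserves_voxels_and_spacing(self, tmp_path, rng):
        v = vol(rng.normal(size=(5, 6, 7)), spacing=(2.5, 0.75, 0.75))
        path = write_volume(v, tmp_path / "v.nii.gz")
        back = read_volume(path)
        assert np.array_equal(back.voxels, v.voxels)
        assert np.allclose(back.spacing, v.spacing, rtol=1e-6)

    def test_write_mask_rejects_non_binary(self, tmp_path):
        with pytest.raises(ValidationError):
            write_mask(vol(np.full((2, 2, 2), 0.5)), tmp_path / "m.nii.gz")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "absent.nii.gz")

    def test_load_study_rejects_misaligned_phases(self, tmp_path):
        write_volume(vol(np.zeros((2, 3, 3))), tmp_path / "pre.nii.gz")
        write_volume(vol(np.zeros((2, 3, 4))), tmp_path / "post.nii.gz")
        write_mask(vol(np.zeros((2, 3, 3))), tmp_path / "mask.nii.gz")
        with pytest.raises(AlignmentError):
            load_study(tmp_path / "pre.nii.gz", [tmp_path / "post.nii.gz"],
                       tmp_path / "mask.nii.gz")

    def test_manifest_round_trip(self, tmp_path):
        cohort = rst2g.generate_cohort(3, shape=(4, 8, 8), seed=1)
        manifest = rst2g.write_cohort(cohort, tmp_path)
        loaded = load_manifest(manifest, normalize=False)
        assert [s.patient_id for s in loaded] == [s.patient_id for s in cohort]
        assert np.allclose(loaded[0].mask.voxels, cohort[0].mask.voxels)


class TestSliceBatches:
    @pytest.mark.parametrize("n_slices,B,n_batches,last_pad", [
        (60, 4, 15, 0),
        (60, 1, 60, 0),
        (7, 4, 2, 1),
    ])
    def test_batch_counting_and_padding(self, n_slices, B, n_batches, last_pad):
        pre = vol(np.zeros((n_slices, 4, 4)))
        mask = vol(np.zeros((n_slices, 4, 4)))
        study = DCEStudy.from_phases(pre, [pre], mask, normalize=False)
        batches = assemble_slice_batches(study, B)
        assert len(batches) == n_batches
        assert all(b.batch_size == B for b in batches)
        assert batches[-1].n_padded == last_pad
        # consecutive non-overlapping coverage in ascending order
        core = [i for b in batches
                for i in b.slice_indices[:b.batch_size - b.n_padded]]
        assert core == list(range(n_slices))

    def test_padding_replicates_edge_slice(self):
        voxels = np.arange(7, dtype=np.float32)[:, None, None] * np.ones((7, 4, 4))
        pre = vol(voxels)
        mask = vol(np.zeros((7, 4, 4)))
        study = DCEStudy.from_phases(pre, [pre], mask, normalize=False)
        last = assemble_slice_batches(study, 4)[-1]
        assert last.slice_indices == (4, 5, 6, 6)
        assert np.array_equal(last.pre[3], last.pre[2])

    def test_oversized_batch_without_padding_errors(self):
        pre = vol(np.zeros((3, 4, 4)))
        study = DCEStudy.from_phases(pre, [pre], vol(np.zeros((3, 4, 4))),
                                     normalize=False)
        with pytest.raises(ValidationError):
            assemble_slice_batches(study, 8, pad=False)

    def test_slice_batch_rejects_non_consecutive_indices(self):
        z = np.zeros((2, 1, 4, 4), dtype=np.float32)
        with pytest.raises(ValidationError):
            SliceBatch(pre=z, post=z, res=z, slice_indices=(0, 2))
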