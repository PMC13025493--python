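"""DICOM header model: axial detection, grouping/sorting, HU rescale, L3 runs."""

import json
import math

import numpy as np
import pytest

from musclequant.dicom_model import (
    L3NotFoundError,
    SliceHeader,
    VertebraLabelVolume,
    filter_groups_by_description,
    group_and_sort,
    header_from_dataset,
    hu_convert,
    hu_window_to_uint8,
    is_axial,
    l3_slice_range,
    load_label_volume,
    mid_slice,
    write_selection_manifest,
)

AXIAL = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)
SAGITTAL = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)
CORONAL = (1.0, 0.0, 0.0, 0.0, 0.0, -1.0)


def header(z=0.0, orientation=AXIAL, series="S1", acq=1, thickness=3.0, desc="", study_desc=""):
    return SliceHeader(
        study_uid="ST1",
        series_uid=series,
        frame_of_reference_uid="F1",
        orientation=orientation,
        position=(0.0, 0.0, z),
        pixel_spacing=(0.7, 0.7),
        slice_thickness=thickness,
        acquisition_number=acq,
        spacing_between_slices=3.0,
        series_description=desc,
        study_description=study_desc,
    )


class TestIsAxial:
    def test_canonical_planes(self):
        assert is_axial(AXIAL)
        assert not is_axial(SAGITTAL)
        assert not is_axial(CORONAL)

    def test_in_plane_rotation_is_still_axial(self):
        # rotate the row/column axes 30° about z: normal unchanged
        c, s = math.cos(math.pi / 6), math.sin(math.pi / 6)
        assert is_axial((c, s, 0.0, -s, c, 0.0))

    def test_tilt_beyond_tolerance_rejected(self):
        # tilt about the x-axis by 30°: |normal·ẑ| = cos30° ≈ 0.866 < 0.9
        c, s = math.cos(math.pi / 6), math.sin(math.pi / 6)
        assert not is_axial((1.0, 0.0, 0.0, 0.0, c, s))
        # 20° tilt: cos20° ≈ 0.940 > 0.9
        c, s = math.cos(math.radians(20)), math.sin(math.radians(20))
        assert is_axial((1.0, 0.0, 0.0, 0.0, c, s))

    def test_non_unit_or_non_orthogonal_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            is_axial((2.0, 0.0, 0.0, 0.0, 1.0, 0.0))
        with pytest.raises(ValueError, match="orthogonal"):
            is_axial((1.0, 0.0, 0.0, 1.0, 0.0, 0.0))


class TestGroupAndSort:
    def test_partition_and_z_sorting(self):
        hs = [header(z=30.0), header(z=0.0), header(z=15.0), header(z=5.0, series="S2")]
        groups = group_and_sort(hs)
        assert len(groups) == 2
        zs = [h.patient_z for h in groups[0].slices]
        assert zs == [0.0, 15.0, 30.0]
        assert len(groups[1].slices) == 1

    def test_acquisition_number_splits_groups(self):
        hs = [header(z=0.0, acq=1), header(z=3.0, acq=2)]
        assert len(group_and_sort(hs)) == 2

    def test_every_header_lands_in_exactly_one_group(self):
        hs = [header(z=float(i), series=f"S{i % 3}") for i in range(12)]
        groups = group_and_sort(hs)
        assert sum(len(g.slices) for g in groups) == 12

    def test_duplicate_positions_kept_and_reported(self):
        hs = [header(z=10.0), header(z=10.0), header(z=20.0)]
        (g,) = group_and_sort(hs)
        assert len(g.slices) == 3
        assert g.duplicate_positions == (10.0,)

    def test_first_appearance_order_and_empty_input(self):
        hs = [header(series="B"), header(series="A")]
        groups = group_and_sort(hs)
        assert [g.slices[0].series_uid for g in groups] == ["B", "A"]
        with pytest.raises(ValueError, match="no headers"):
            group_and_sort([])


class TestHuConvert:
    def test_identity_and_typical_ct_rescale(self):
        raw = np.array([0, 1024, 2048])
        assert np.array_equal(hu_convert(raw, 1.0, 0.0), raw.astype(float))
        assert np.array_equal(hu_convert(raw, 1.0, -1024.0), raw - 1024.0)

    def test_missing_or_zero_slope_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            hu_convert(np.zeros(3), None, 0.0, context="slice 4")
        with pytest.raises(ValueError, match="non-zero"):
            hu_convert(np.zeros(3), 0.0, 0.0)


def volume_with_l3(present):
    """Label volume whose slice i contains label 29 iff present[i]."""
    labels = np.zeros((len(present), 4, 4), dtype=np.int32)
    for i, p in enumerate(present):
        if p:
            labels[i, 1, 1] = 29
    return VertebraLabelVolume(labels=labels)


class TestL3Selection:
    def test_single_run_and_floor_midpoint(self):
        vol = volume_with_l3([0, 1, 1, 1, 1, 0])
        run = l3_slice_range(vol)
        assert run == (1, 4)
        assert mid_slice(run) == 2  # floor((1+4)/2)
        assert mid_slice(run, mode="end") == 4

    def test_longest_run_wins_over_fragment(self):
        vol = volume_with_l3([1, 0, 1, 1, 1, 0])
        assert l3_slice_range(vol) == (2, 4)

    def test_equal_runs_tie_breaks_low(self):
        vol = volume_with_l3([1, 1, 0, 1, 1])
        assert l3_slice_range(vol) == (0, 1)

    def test_absent_label_raises(self):
        with pytest.raises(L3NotFoundError, match="label 29"):
            l3_slice_range(volume_with_l3([0, 0, 0]))

    def test_single_slice_run(self):
        vol = volume_with_l3([0, 1, 0])
        run = l3_slice_range(vol)
        assert run == (1, 1)
        assert mid_slice(run) == 1

    def test_invalid_run_or_mode_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mid_slice((3, 2))
        with pytest.raises(ValueError, match="mode"):
            mid_slice((0, 2), mode="middleish")

    def test_volume_must_be_3d_and_alignment_checked(self):
        with pytest.raises(ValueError, match="3-D"):
            VertebraLabelVolume(labels=np.zeros((4, 4)))
        vol = volume_with_l3([1, 1])
        (g,) = group_and_sort([header(z=0.0), header(z=3.0), header(z=6.0)])
        with pytest.raises(ValueError, match="slices"):
            vol.check_alignment(g)


class TestDescriptionFilter:
    def test_include_and_exclude_keywords(self):
        groups = group_and_sort(
            [
                header(series="S1", desc="Abdomen venous phase"),
                header(series="S2", desc="Scout"),
                header(series="S3", desc="Venous thin bone kernel"),
            ]
        )
        kept = filter_groups_by_description(groups, include_keywords=["venous"], exclude_keywords=["bone"])
        assert [g.slices[0].series_uid for g in kept] == ["S1"]

    def test_no_include_keywords_passes_all(self):
        groups = group_and_sort([header(series="S1", desc="a"), header(series="S2", desc="b")])
        assert len(filter_groups_by_description(groups)) == 2

    def test_case_insensitive_and_study_description(self):
        groups = group_and_sort([header(series="S1", study_desc="CT ABDOMEN")])
        assert len(filter_groups_by_description(groups, include_keywords=["abdomen"])) == 1


class TestPydicomAndNifti:
    def test_header_from_dataset_roundtrip(self):
        from pydicom.dataset import Dataset

        ds = Dataset()
        ds.StudyInstanceUID = "1.2.3"
        ds.SeriesInstanceUID = "1.2.3.4"
        ds.FrameOfReferenceUID = "1.2.3.5"
        ds.ImageOrientationPatient = list(AXIAL)
        ds.ImagePositionPatient = [-170.0, -180.0, -95.5]
        ds.PixelSpacing = [0.78, 0.78]
        ds.SliceThickness = 2.5
        ds.AcquisitionNumber = 3
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.SeriesDescription = "Abd venous"
        h = header_from_dataset(ds, source_path="a.dcm")
        assert h.patient_z == -95.5
        assert h.acquisition_number == 3
        assert h.rescale_intercept == -1024.0
        assert is_axial(h.orientation)
        assert h.source_path == "a.dcm"

    def test_header_from_dataset_missing_optionals(self):
        from pydicom.dataset import Dataset

        ds = Dataset()
        ds.ImageOrientationPatient = list(AXIAL)
        ds.ImagePositionPatient = [0.0, 0.0, 1.0]
        ds.PixelSpacing = [1.0, 1.0]
        h = header_from_dataset(ds)
        assert h.acquisition_number is None
        assert h.rescale_slope is None
        assert math.isnan(h.slice_thickness)

    def test_load_label_volume_moves_slice_axis(self, tmp_path):
        import nibabel as nib

        data = np.zeros((4, 5, 6), dtype=np.int16)  # (rows, cols, slices)
        data[1, 1, 3] = 29
        nib.save(nib.Nifti1Image(data, np.eye(4)), tmp_path / "labels.nii")
        vol = load_label_volume(tmp_path / "labels.nii", slice_axis=2)
        assert vol.labels.shape == (6, 4, 5)
        assert l3_slice_range(vol) == (3, 3)


class TestWindowingAndManifest:
    def test_soft_tissue_window_endpoints(self):
        hu = np.array([-500.0, -160.0, 40.0, 240.0, 500.0])
        out = hu_window_to_uint8(hu)
        assert out.dtype == np.uint8
        assert out.tolist() == [0, 0, 128, 255, 255]

    def test_manifest_records_choice(self, tmp_path):
        (g,) = group_and_sort([header(z=0.0), header(z=3.0), header(z=6.0)])
        path = tmp_path / "manifest.json"
        write_selection_manifest(path, g, slice_index=1, l3_run=(0, 2), mode="mid")
        m = json.loads(path.read_text())
        assert m["slice_index"] == 1
        assert m["l3_run"] == [0, 2]
        assert m["patient_z"] == 3.0
        assert m["n_slices"] == 3
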