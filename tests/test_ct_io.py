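"""Volume/mask I/O and Hounsfield-unit normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cacvit.ct_io import (
    AnnotationMask,
    CTVolume,
    load_mask,
    load_volume,
    normalize_slice,
    save_mask,
    save_volume,
)


class TestNormalizeSlice:
    def test_constant_slice_maps_to_minus_one(self):
        out = normalize_slice(np.full((8, 8), 250.0))
        np.testing.assert_array_equal(out.values, -1.0)

    def test_three_value_slice_matches_hand_evaluation(self):
        # I in {0, 500, 1000}: min-max with eps=1e-7 then 2x-1
        out = normalize_slice(np.array([[0.0, 500.0, 1000.0]]))
        expected = 2.0 * (np.array([0.0, 500.0, 1000.0]) / (1000.0 + 1e-7)) - 1.0
        np.testing.assert_allclose(out.values[0], expected, atol=1e-12)
        assert out.values[0, 0] == -1.0
        assert abs(out.values[0, 1]) < 1e-6
        assert abs(out.values[0, 2] - 1.0) < 1e-6

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        sl = rng.uniform(-1000, 2000, size=(16, 16))
        a = normalize_slice(sl).values
        b = normalize_slice(sl + 1024.0).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_raw_hu_retained(self):
        sl = np.array([[130.0, 400.0]])
        out = normalize_slice(sl, source_slice_index=3)
        np.testing.assert_array_equal(out.raw_hu, sl)
        assert out.source_slice_index == 3

    def test_monotone_transform_preserves_ordering(self):
        rng = np.random.default_rng(1)
        sl = rng.normal(0, 300, size=(12, 12))
        out = normalize_slice(sl).values
        assert np.array_equal(np.argsort(sl.ravel()), np.argsort(out.ravel()))

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_always_within_bounds(self, seed):
        rng = np.random.default_rng(seed)
        sl = rng.uniform(-1024, 3000, size=(6, 6))
        out = normalize_slice(sl).values
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_idempotent_up_to_eps_on_rescaled_data(self):
        rng = np.random.default_rng(2)
        sl = rng.uniform(0, 1000, size=(10, 10))
        once = normalize_slice(sl).values
        # map back to a [0, K] range and renormalize
        again = normalize_slice((once + 1.0) * 500.0).values
        np.testing.assert_allclose(once, again, atol=1e-5)

    def test_empty_slice_rejected(self):
        with pytest.raises(ValueError):
            normalize_slice(np.empty((0, 0)))


class TestVolumeRoundTrip:
    def test_nifti_round_trip_is_exact(self, phantom_case, tmp_path):
        vol = phantom_case.volume
        path = tmp_path / "vol.nii.gz"
        save_volume(vol, path)
        back = load_volume(path, patient_id=vol.patient_id)
        np.testing.assert_array_equal(back.voxels, vol.voxels)
        assert back.pixel_spacing == pytest.approx(vol.pixel_spacing)
        assert back.slice_thickness == pytest.approx(vol.slice_thickness)

    def test_missing_path_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "absent.nii.gz")

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            CTVolume(voxels=np.zeros((2, 4, 4)), pixel_spacing=(0.0, 1.0),
                     slice_thickness=3.0)

    def test_nonfinite_hu_rejected(self):
        bad = np.zeros((1, 4, 4))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            CTVolume(voxels=bad, pixel_spacing=(1.0, 1.0), slice_thickness=3.0)


class TestDicom:
    def _write_series(self, path, n_slices=3, intercept=-1024.0, slope=1.0):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        path.mkdir(exist_ok=True)
        for i in range(n_slices):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(str(path / f"s{i}.dcm"), {}, file_meta=meta,
                             preamble=b"\0" * 128)
            ds.PatientID = "dcm01"
            ds.Rows = ds.Columns = 4
            ds.PixelSpacing = [0.7, 0.7]
            ds.SliceThickness = 3.0
            ds.ImagePositionPatient = [0.0, 0.0, 3.0 * i]
            ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
            ds.InstanceNumber = i + 1
            ds.RescaleIntercept = intercept
            ds.RescaleSlope = slope
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            arr = np.full((4, 4), 1154, dtype=np.uint16)
            ds.PixelData = arr.tobytes()
            ds.save_as(str(path / f"s{i}.dcm"), enforce_file_format=True)

    def test_rescale_applied(self, tmp_path):
        # stored value 1154 with intercept -1024 is exactly 130 HU
        self._write_series(tmp_path / "series")
        vol = load_volume(tmp_path / "series")
        assert vol.voxels.shape == (3, 4, 4)
        np.testing.assert_allclose(vol.voxels, 130.0)
        assert vol.pixel_spacing == (0.7, 0.7)

    def test_empty_directory_errors(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(ValueError, match="no readable"):
            load_volume(tmp_path / "empty")


class TestMasks:
    def test_label_values_validated(self):
        with pytest.raises(ValueError, match="invalid label"):
            AnnotationMask(labels=np.full((1, 2, 2), 7))

    @pytest.mark.parametrize("format", ["nifti", "png_stack"])
    def test_round_trip_preserves_labels(self, tmp_path, format):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 5, size=(4, 8, 8))
        mask = AnnotationMask(labels=labels)
        path = tmp_path / ("m.nii.gz" if format == "nifti" else "pngs")
        save_mask(mask, path, format=format)
        back = load_mask(path, format=format)
        np.testing.assert_array_equal(back.labels, labels)

    def test_all_zero_round_trip(self, tmp_path):
        mask = AnnotationMask(labels=np.zeros((2, 4, 4), dtype=int))
        save_mask(mask, tmp_path / "z.nii.gz")
        assert not load_mask(tmp_path / "z.nii.gz").labels.any()

    def test_positive_slices(self):
        labels = np.zeros((3, 4, 4), dtype=int)
        labels[1, 2, 2] = 2
        assert AnnotationMask(labels=labels).positive_slices().tolist() == [1]
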