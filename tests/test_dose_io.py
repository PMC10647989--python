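"""Dose grid IO: container round-trips, DICOM RTDOSE reading, normalisation."""

import numpy as np
import pytest

from isdqa import (
    DoseGrid,
    DoseIOError,
    load_dose_grid,
    save_dose_grid,
    to_percent,
)


def make_rtdose_file(path, frames, scaling=1.0e-3, spacing=(1.0, 1.0, 1.0),
                     origin=(-10.0, -12.0, -14.0), offsets=None):
    """Write a minimal synthetic RTDOSE object (stored as uint32 * scaling)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    frames = np.asarray(frames)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseGridScaling = scaling
    ds.Rows, ds.Columns = frames.shape[1], frames.shape[2]
    ds.NumberOfFrames = frames.shape[0]
    ds.ImagePositionPatient = list(origin)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [spacing[1], spacing[0]]  # [row=y, col=x]
    if offsets is None:
        offsets = [i * spacing[2] for i in range(frames.shape[0])]
    ds.GridFrameOffsetVector = list(offsets)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.PixelData = frames.astype(np.uint32).tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)
    return path


class TestContainer:
    def test_round_trip_is_bit_exact(self, sphere_grid_small, tmp_path):
        path = save_dose_grid(sphere_grid_small, tmp_path / "plan.npz")
        back = load_dose_grid(path)
        np.testing.assert_array_equal(back.values, sphere_grid_small.values)
        np.testing.assert_array_equal(back.spacing, sphere_grid_small.spacing)
        np.testing.assert_array_equal(back.origin, sphere_grid_small.origin)
        np.testing.assert_array_equal(back.isocenter, sphere_grid_small.isocenter)

    def test_single_hot_voxel_read_back(self, tmp_path):
        values = np.zeros((3, 3, 3))
        values[1, 2, 0] = 2.0
        grid = DoseGrid(values=values, spacing=(1, 1, 1), origin=(0, 0, 0),
                        isocenter=(1, 1, 1))
        back = load_dose_grid(save_dose_grid(grid, tmp_path / "g.npz"))
        assert back.d_max == 2.0
        assert back.values[1, 2, 0] == 2.0

    def test_isocenter_override_wins(self, sphere_grid_small, tmp_path):
        path = save_dose_grid(sphere_grid_small, tmp_path / "p.npz")
        back = load_dose_grid(path, isocenter_override=(1.0, 2.0, 3.0))
        np.testing.assert_array_equal(back.isocenter, [1.0, 2.0, 3.0])

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(DoseIOError, match="no such file"):
            load_dose_grid(tmp_path / "absent.npz")

    def test_corrupt_container_raises(self, tmp_path):
        bad = tmp_path / "bad.npz"
        bad.write_bytes(b"not an archive")
        with pytest.raises(DoseIOError, match="unreadable"):
            load_dose_grid(bad)


class TestRTDose:
    def test_scaling_and_geometry(self, tmp_path):
        frames = np.zeros((4, 5, 6), dtype=np.uint32)  # (z, y, x)
        frames[2, 3, 4] = 1500
        path = make_rtdose_file(tmp_path / "d.dcm", frames, scaling=2e-3,
                                spacing=(0.5, 1.0, 2.0))
        grid = load_dose_grid(path, isocenter_override=(0, 0, 0))
        assert grid.values.shape == (6, 5, 4)  # (x, y, z)
        assert grid.values[4, 3, 2] == pytest.approx(3.0)  # 1500 * 2e-3
        np.testing.assert_allclose(grid.spacing, [0.5, 1.0, 2.0])
        np.testing.assert_allclose(grid.origin, [-10, -12, -14])

    def test_missing_isocenter_raises(self, tmp_path):
        path = make_rtdose_file(tmp_path / "d.dcm", np.ones((3, 3, 3)))
        with pytest.raises(DoseIOError, match="isocenter"):
            load_dose_grid(path)

    def test_non_uniform_slice_spacing_raises(self, tmp_path):
        path = make_rtdose_file(
            tmp_path / "d.dcm", np.ones((4, 3, 3)), offsets=[0, 1, 2.2, 3.2]
        )
        with pytest.raises(DoseIOError, match="slice spacing"):
            load_dose_grid(path, isocenter_override=(0, 0, 0))


class TestToPercent:
    def test_global_max_examples(self):
        grid = DoseGrid(values=np.full((2, 2, 2), 2.0), spacing=(1, 1, 1),
                        origin=(0, 0, 0), isocenter=(0.5, 0.5, 0.5))
        pct = to_percent(grid)
        assert np.all(pct.values == 100.0)
        values = np.full((2, 2, 2), 2.0)
        values[0, 0, 0] = 1.0
        grid2 = DoseGrid(values=values, spacing=(1, 1, 1), origin=(0, 0, 0),
                         isocenter=(0.5, 0.5, 0.5))
        assert to_percent(grid2).values[0, 0, 0] == pytest.approx(50.0)

    def test_explicit_dose(self):
        grid = DoseGrid(values=np.full((2, 2, 2), 2.0), spacing=(1, 1, 1),
                        origin=(0, 0, 0), isocenter=(0.5, 0.5, 0.5))
        pct = to_percent(grid, "explicit_dose", dose=2.5)
        assert pct.values[0, 0, 0] == pytest.approx(80.0)

    def test_zero_normalisation_rejected(self):
        grid = DoseGrid(values=np.zeros((2, 2, 2)), spacing=(1, 1, 1),
                        origin=(0, 0, 0), isocenter=(0.5, 0.5, 0.5))
        with pytest.raises(DoseIOError, match="positive"):
            to_percent(grid)
        with pytest.raises(DoseIOError, match="positive"):
            to_percent(grid, "explicit_dose", dose=0.0)

    def test_percent_conversion_preserves_order(self, rng):
        values = rng.uniform(0, 3, size=(6, 6, 6))
        grid = DoseGrid(values=values, spacing=(1, 1, 1), origin=(0, 0, 0),
                        isocenter=(2.5, 2.5, 2.5))
        pct = to_percent(grid)
        order = np.argsort(values, axis=None)
        assert np.all(np.diff(pct.values.flatten()[order]) >= 0)
        assert pct.max_percent == pytest.approx(100.0)


class TestValidation:
    def test_negative_dose_rejected(self):
        with pytest.raises(DoseIOError, match="non-negative"):
            DoseGrid(values=np.full((2, 2, 2), -1.0), spacing=(1, 1, 1),
                     origin=(0, 0, 0), isocenter=(0, 0, 0))

    def test_bad_spacing_rejected(self):
        with pytest.raises(DoseIOError, match="spacing"):
            DoseGrid(values=np.ones((2, 2, 2)), spacing=(1, 0, 1),
                     origin=(0, 0, 0), isocenter=(0, 0, 0))

    def test_isocenter_outside_bbox_warns(self):
        with pytest.warns(UserWarning, match="isocenter"):
            DoseGrid(values=np.ones((2, 2, 2)), spacing=(1, 1, 1),
                     origin=(0, 0, 0), isocenter=(50, 0, 0))
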