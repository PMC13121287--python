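"""CT volume and annotation-mask I/O, plus Hounsfield-unit preprocessing.

Volumes are held as 3-D arrays of true Hounsfield units with axis order
(slice, row, col); masks share the same grid with integer labels
0=background, 1=RCA, 2=LAD, 3=LCA, 4=LCX.  NIfTI files are read and written
with :mod:`nibabel`, DICOM series with :mod:`pydicom`, PNG label stacks with
Pillow.

Normalization follows the slice-wise scheme used for the transformer input:
shift by the 1024 HU soft-tissue reference, min-max normalize with a small
epsilon guard, then scale linearly to [-1, 1].  The raw HU slice is kept on
the result because Agatston scoring must always read unnormalized HU.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ARTERY_CLASSES = {0: "background", 1: "RCA", 2: "LAD", 3: "LCA", 4: "LCX"}
ARTERY_NAMES = ("RCA", "LAD", "LCA", "LCX")
VALID_LABELS = frozenset(ARTERY_CLASSES)

#: epsilon guard in the min-max denominator
NORM_EPS = 1e-7
#: soft-tissue reference subtracted before min-max normalization
HU_SHIFT = 1024.0


@dataclass
class CTVolume:
    """A CT volume in true Hounsfield units.

    Attributes
    ----------
    voxels : (S, R, C) float array of HU values
    pixel_spacing : (row_mm, col_mm)
    slice_thickness : mm
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    patient_id: str = ""
    is_gated: bool = True

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D (slice, row, col), got {self.voxels.ndim}-D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        rs, cs = self.pixel_spacing
        if rs <= 0 or cs <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be strictly positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])


@dataclass
class AnnotationMask:
    """Integer label volume aligned with a :class:`CTVolume`."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D (slice, row, col)")
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise ValueError(f"mask contains invalid label values {sorted(bad)}; allowed: 0..4")
        self.labels = self.labels.astype(np.uint8)

    def validate_against(self, volume: CTVolume) -> None:
        if self.labels.shape != volume.voxels.shape:
            raise ValueError(
                f"mask shape {self.labels.shape} does not match volume {volume.voxels.shape}")

    def positive_slices(self) -> np.ndarray:
        """Indices of slices with at least one non-background pixel."""
        return np.flatnonzero(self.labels.reshape(self.labels.shape[0], -1).any(axis=1))


@dataclass
class NormalizedSlice:
    """A slice mapped to [-1, 1], keeping a reference to its raw HU data."""

    values: np.ndarray
    source_slice_index: int
    raw_hu: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.values.min() < -1.0 or self.values.max() > 1.0:
            raise ValueError("normalized values must lie in [-1, 1]")


def normalize_slice(hu_slice: np.ndarray, source_slice_index: int = 0) -> NormalizedSlice:
    """Normalize one HU slice to [-1, 1].

    The slice is shifted by the 1024 HU soft-tissue reference, min-max
    normalized with an epsilon guard in the denominator, and scaled linearly
    to [-1, 1].  The shift cancels under min-max normalization but is applied
    for fidelity to the preprocessing definition.  A constant slice maps to
    all -1 (zero numerator).
    """
    raw = np.asarray(hu_slice, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("slice must contain at least one pixel")
    if not np.all(np.isfinite(raw)):
        raise ValueError("slice contains non-finite HU values")
    shifted = raw - HU_SHIFT
    lo, hi = shifted.min(), shifted.max()
    norm = (shifted - lo) / (hi - lo + NORM_EPS)
    final = 2.0 * norm - 1.0
    return NormalizedSlice(values=np.clip(final, -1.0, 1.0),
                           source_slice_index=source_slice_index, raw_hu=raw)


def normalize_volume(volume: CTVolume) -> list[NormalizedSlice]:
    return [normalize_slice(volume.voxels[i], i) for i in range(volume.n_slices)]


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _nifti_affine(volume_spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = volume_spacing
    return aff


def save_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (float64 HU, spacing encoded in the affine)."""
    import nibabel as nib

    # (S, R, C) -> nibabel's (x=col, y=row, z=slice)
    data = np.ascontiguousarray(volume.voxels.transpose(2, 1, 0))
    aff = _nifti_affine((volume.pixel_spacing[1], volume.pixel_spacing[0],
                         volume.slice_thickness))
    img = nib.Nifti1Image(data, aff)
    img.header.set_zooms((volume.pixel_spacing[1], volume.pixel_spacing[0],
                          volume.slice_thickness))
    nib.save(img, str(path))


def _load_nifti_volume(path: Path, patient_id: str) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"NIfTI header of {path} has missing or non-positive spacing")
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    voxels = data.transpose(2, 1, 0)
    return CTVolume(voxels=voxels, pixel_spacing=(float(zooms[1]), float(zooms[0])),
                    slice_thickness=float(zooms[2]), patient_id=patient_id)


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def _load_dicom_volume(path: Path, patient_id: str) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir()
                   if p.is_file() and not p.name.startswith("."))
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no readable DICOM slices in {path}")

    orientations = {tuple(np.round(np.asarray(ds.ImageOrientationPatient, float), 4))
                    for ds in datasets if hasattr(ds, "ImageOrientationPatient")}
    if len(orientations) > 1:
        raise ValueError(f"mixed slice orientations in DICOM series {path}")

    def sort_key(ds):
        z = float(ds.ImagePositionPatient[2]) if hasattr(ds, "ImagePositionPatient") else 0.0
        inst = int(getattr(ds, "InstanceNumber", 0))
        return (z, inst)

    datasets.sort(key=sort_key)
    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError(f"DICOM series {path} lacks PixelSpacing")
    spacing = (float(first.PixelSpacing[0]), float(first.PixelSpacing[1]))
    thickness = float(getattr(first, "SliceThickness", 0) or 0)
    if thickness <= 0:
        # derive from slice positions when the tag is absent
        zs = [float(ds.ImagePositionPatient[2]) for ds in datasets
              if hasattr(ds, "ImagePositionPatient")]
        dz = np.diff(sorted(zs))
        if len(dz) == 0 or not np.all(dz > 0):
            raise ValueError(f"cannot determine slice thickness for {path}")
        thickness = float(np.median(dz))

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice shapes in DICOM series {path}: {shapes}")
    pid = patient_id or str(getattr(first, "PatientID", ""))
    return CTVolume(voxels=np.stack(slices), pixel_spacing=spacing,
                    slice_thickness=thickness, patient_id=pid)


def load_volume(path: str | Path, format: str | None = None,
                patient_id: str = "") -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom_dir"``; when omitted it is
    inferred from the path (directory => DICOM, file => NIfTI).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti_volume(path, patient_id)
    if format == "dicom_dir":
        return _load_dicom_volume(path, patient_id)
    raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'dicom_dir'")


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def save_mask(mask: AnnotationMask, path: str | Path, format: str = "nifti",
              spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a mask as NIfTI or as a stack of 8-bit PNGs (one per slice).

    ``spacing`` is (row_mm, col_mm, thickness_mm) for the NIfTI header.
    """
    path = Path(path)
    if format == "nifti":
        import nibabel as nib

        data = np.ascontiguousarray(mask.labels.transpose(2, 1, 0)).astype(np.uint8)
        aff = _nifti_affine((spacing[1], spacing[0], spacing[2]))
        img = nib.Nifti1Image(data, aff)
        img.header.set_zooms((spacing[1], spacing[0], spacing[2]))
        nib.save(img, str(path))
    elif format == "png_stack":
        from PIL import Image

        path.mkdir(parents=True, exist_ok=True)
        for i in range(mask.labels.shape[0]):
            Image.fromarray(mask.labels[i], mode="L").save(path / f"slice_{i:04d}.png")
    else:
        raise ValueError(f"unknown mask format {format!r}")


def load_mask(path: str | Path, format: str | None = None) -> AnnotationMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "png_stack" if path.is_dir() else "nifti"
    if format == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        labels = np.rint(data).astype(np.int64).transpose(2, 1, 0)
        return AnnotationMask(labels=labels)
    if format == "png_stack":
        from PIL import Image

        files = sorted(p for p in path.iterdir()
                       if re.fullmatch(r"slice_\d+\.png", p.name))
        if not files:
            raise ValueError(f"no slice_NNNN.png files in {path}")
        labels = np.stack([np.asarray(Image.open(f)) for f in files])
        return AnnotationMask(labels=labels.astype(np.int64))
    raise ValueError(f"unknown mask format {format!r}")
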