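"""Reading CT volumes and lesion masks, and cropping volumes of interest.

Volumes are held in (slice, row, column) axis order with per-axis spacing
in millimetres.  NIfTI files are read with nibabel (the on-disk (i, j, k)
axes map to (column, row, slice), so arrays are transposed on the way in
and out), DICOM series with pydicom, ordering slices by the projection of
ImagePositionPatient on the slice normal and applying the rescale
slope/intercept to obtain Hounsfield units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom


@dataclass
class CTVolume:
    """A 3D intensity grid in Hounsfield units.

    voxels : (n_slices, n_rows, n_cols) array
    spacing : physical voxel size (mm) per axis, same order
    origin : physical coordinates of voxel (0, 0, 0)
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise ValueError(f"spacings must be positive finite: {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LesionMask:
    """Binary lesion mask congruent with a :class:`CTVolume`."""

    flags: np.ndarray
    lesion_id: str = "lesion"

    def __post_init__(self):
        self.flags = np.asarray(self.flags).astype(bool)
        if self.flags.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.flags.any():
            raise ValueError("empty mask: a lesion must contain >= 1 voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())


def _nifti_affine(spacing, origin) -> np.ndarray:
    # on-disk (i, j, k) = (column, row, slice)
    aff = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    aff[:3, 3] = (origin[2], origin[1], origin[0])
    return aff


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (fixture/synthetic-cohort writer)."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.ascontiguousarray(volume.voxels.T),
        _nifti_affine(volume.spacing, volume.origin),
    )
    nib.save(img, str(path))
    return path


def write_mask(mask: LesionMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        np.ascontiguousarray(mask.flags.T.astype(np.uint8)),
        np.eye(4),
    )
    nib.save(img, str(path))
    return path


def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).T
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    t = img.affine[:3, 3]
    origin = (float(t[2]), float(t[1]), float(t[0]))
    return CTVolume(voxels=data, spacing=spacing, origin=origin)


def _read_dicom_series(
    directory: Path, slice_spacing_tol: float = 0.10
) -> CTVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except (pydicom.errors.InvalidDicomError, IsADirectoryError):
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM slices found in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed series in one directory: {sorted(map(str, uids))}")

    first = datasets[0]
    orient = np.asarray(
        getattr(first, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float
    )
    normal = np.cross(orient[:3], orient[3:])

    def _pos(ds):
        ipp = np.asarray(
            getattr(ds, "ImagePositionPatient", [0, 0, 0]), dtype=float
        )
        return float(np.dot(ipp, normal))

    datasets.sort(key=_pos)
    positions = np.array([_pos(ds) for ds in datasets])
    if len(datasets) > 1:
        gaps = np.diff(positions)
        med = float(np.median(gaps))
        if med <= 0:
            raise ValueError("duplicate or unordered slice positions")
        if np.any(np.abs(gaps - med) > slice_spacing_tol * med):
            raise ValueError(
                f"non-uniform slice spacing: gaps {gaps.tolist()} (median {med})"
            )
        dz = med
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)
    ps = getattr(first, "PixelSpacing", [1.0, 1.0])
    spacing = (dz, float(ps[0]), float(ps[1]))
    ipp0 = np.asarray(getattr(datasets[0], "ImagePositionPatient", [0, 0, 0]), float)
    origin = (float(ipp0[2]), float(ipp0[1]), float(ipp0[0]))
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin)


def read_volume(path: str | Path, slice_spacing_tol: float = 0.10) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    slice_spacing_tol is the tolerated relative deviation of slice gaps
    from their median before the series is rejected as non-uniform.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        return _read_dicom_series(path, slice_spacing_tol)
    return _read_nifti(path)


def read_mask(path: str | Path, reference: CTVolume) -> LesionMask:
    """Read a binary lesion mask and validate it against `reference`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).T
    if data.shape != reference.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match volume shape {reference.shape}"
        )
    flags = data != 0
    if not flags.any():
        raise ValueError(f"empty mask: {path}")
    return LesionMask(flags=flags, lesion_id=path.stem)


def extract_voi(
    volume: CTVolume, mask: LesionMask, margin: int = 2
) -> tuple[CTVolume, LesionMask]:
    """Crop the tight bounding box of the lesion, dilated by `margin` voxels.

    The box is clipped at the grid boundaries; voxel values and the set of
    true mask voxels are unchanged.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if mask.flags.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    idx = np.nonzero(mask.flags)
    sl = tuple(
        slice(max(int(ax.min()) - margin, 0), min(int(ax.max()) + margin + 1, n))
        for ax, n in zip(idx, volume.shape)
    )
    new_origin = tuple(
        o + s.start * sp
        for o, s, sp in zip(volume.origin, sl, volume.spacing)
    )
    voi = CTVolume(
        voxels=volume.voxels[sl].copy(), spacing=volume.spacing, origin=new_origin
    )
    sub = LesionMask(flags=mask.flags[sl].copy(), lesion_id=mask.lesion_id)
    return voi, sub
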