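"""Reading and writing volumes as NIfTI-1 files or DICOM series.

NIfTI is the working format between pipeline stages; DICOM is accepted for
scanner exports that store HU via the standard rescale slope/intercept.
Spacing must be isotropic on read: anisotropic headers raise unless an
explicit resample target is requested — never silent acceptance.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .volume import BinaryMask, CTVolume, resample_isotropic

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask", "FormatError"]


class FormatError(IOError):
    """Malformed or inconsistent image files (spacing, geometry, emptiness)."""


_SPACING_ATOL_UM = 0.1


def _nifti_spacing_um(img) -> float:
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float) * 1000.0  # mm -> um
    if np.ptp(zooms) > _SPACING_ATOL_UM:
        raise FormatError(
            f"anisotropic NIfTI spacing {zooms.tolist()} um; pass resample_um= to resample explicitly"
        )
    return float(zooms.mean())


def read_volume(path, *, resample_um: float | None = None) -> CTVolume:
    """Read a CT volume (HU) from a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        vol = _read_dicom_series(path)
    else:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
        if data.ndim != 3:
            raise FormatError(f"expected 3D NIfTI, got shape {data.shape}")
        try:
            spacing_um = _nifti_spacing_um(img)
        except FormatError:
            if resample_um is None:
                raise
            zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
            data = _resample_aniso(data, zooms * 1000.0, resample_um)
            spacing_um = resample_um
        origin = np.asarray(img.affine[:3, 3], dtype=float)[::-1]  # nifti x,y,z -> z,y,x
        # nibabel loads as (x, y, z); package convention is (z, y, x)
        vol = CTVolume(np.ascontiguousarray(data.transpose(2, 1, 0)), spacing_um, origin)
    if resample_um is not None and not np.isclose(vol.spacing_um, resample_um):
        vol = resample_isotropic(vol, resample_um)
    return vol


def _resample_aniso(data: np.ndarray, zooms_um: np.ndarray, target_um: float) -> np.ndarray:
    import scipy.ndimage as ndi

    factors = [z / target_um for z in zooms_um]
    return ndi.zoom(data, factors, order=1, mode="nearest")


def write_volume(vol: CTVolume, path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or a DICOM series (directory)."""
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        _write_nifti(vol.voxels.astype(np.float32), vol, path)
    else:
        _write_dicom_series(vol, path)


def _write_nifti(data_zyx: np.ndarray, vol, path: Path) -> None:
    s = vol.spacing_mm
    affine = np.diag([s, s, s, 1.0])
    affine[:3, 3] = np.asarray(vol.origin_mm, dtype=float)[::-1]
    img = nib.Nifti1Image(np.ascontiguousarray(data_zyx.transpose(2, 1, 0)), affine)
    img.header.set_zooms((s, s, s))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask((vol.voxels >= 0.5).astype(np.uint8), vol.spacing_um, vol.origin_mm)


def write_mask(mask: BinaryMask, path) -> None:
    _write_nifti(mask.voxels.astype(np.float32), mask, Path(path))


# ---------------------------------------------------------------- DICOM series

def _read_dicom_series(directory: Path) -> CTVolume:
    files = sorted(
        p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", "")
    )
    if not files:
        raise FormatError(f"no DICOM files found in {directory}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(str(f)))
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise FormatError(f"unreadable DICOM file {f}: {exc}") from exc
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    dz = np.diff(zs)
    if len(dz) == 0:
        raise FormatError("DICOM series needs at least 2 slices")
    if np.ptp(dz) > _SPACING_ATOL_UM / 1000.0:
        raise FormatError(f"inconsistent DICOM slice spacing: {sorted(set(np.round(dz, 4)))} mm")
    pix = np.asarray(slices[0].PixelSpacing, dtype=float)
    spacings_mm = np.array([dz.mean(), pix[0], pix[1]])
    if np.ptp(spacings_mm) * 1000.0 > _SPACING_ATOL_UM:
        raise FormatError(f"anisotropic DICOM spacing {spacings_mm.tolist()} mm")
    data = np.stack(
        [
            ds.pixel_array.astype(np.float32) * float(getattr(ds, "RescaleSlope", 1.0))
            + float(getattr(ds, "RescaleIntercept", 0.0))
            for ds in slices
        ]
    )
    origin = np.array(
        [zs[0], float(slices[0].ImagePositionPatient[1]), float(slices[0].ImagePositionPatient[0])]
    )
    return CTVolume(data, float(spacings_mm.mean() * 1000.0), origin)


def _write_dicom_series(vol: CTVolume, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    data = np.rint(np.clip(vol.voxels, -32768, 32767)).astype(np.int16)
    series_uid = generate_uid()
    study_uid = generate_uid()
    s = vol.spacing_mm
    for i in range(data.shape[0]):
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = data.shape[1], data.shape[2]
        ds.PixelSpacing = [f"{s:.6f}", f"{s:.6f}"]
        ds.SliceThickness = f"{s:.6f}"
        ds.ImagePositionPatient = [
            f"{vol.origin_mm[2]:.6f}",
            f"{vol.origin_mm[1]:.6f}",
            f"{vol.origin_mm[0] + i * s:.6f}",
        ]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.PixelData = data[i].tobytes()
        ds.save_as(str(directory / f"slice_{i:04d}.dcm"), enforce_file_format=True)


def _is_dicom_dir(path) -> bool:
    return Path(path).is_dir()
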