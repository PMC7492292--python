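"""Reading and writing of Dixon/IDEAL series and segmentation masks.

Data model
----------
A :class:`DixonSeries` holds the four co-registered channels produced by an
IDEAL water-fat reconstruction — water, fat, fat-fraction (percent) and R2*
(1/s) — as ``(n_slices, rows, cols)`` arrays plus geometry metadata.  The
canonical orientation is: slice index runs left-to-right through the sagittal
stack, row index runs superior-to-inferior, column index runs
anterior-to-posterior.  Fat-fraction maps are stored in percent (0-100) and
are clipped into that range exactly once, on read.  Signal intensities are
kept at their original values; no normalisation is applied at the I/O layer.

Masks (:class:`MaskVolume`) are either binary {0,1} or probability [0,1]
volumes aligned to a series.  Binary masks round-trip bit-exactly through
every supported on-disk format (NIfTI, DICOM Secondary Capture, PNG stack).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
from PIL import Image

from .errors import FormatError, GeometryMismatchError, IncompleteSeriesError, ValidationError

#: canonical channel order of a Dixon series
CHANNELS = ("water", "fat", "fat_fraction", "r2star")

#: filename suffixes used for NIfTI channel files
CHANNEL_SUFFIXES = {"water": "_water", "fat": "_fat", "fat_fraction": "_ff", "r2star": "_r2s"}


@dataclass
class DixonSeries:
    """Four co-registered channels of one subject's sagittal IDEAL series."""

    subject_id: str
    water: np.ndarray
    fat: np.ndarray
    fat_fraction: np.ndarray
    r2star: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.375, 1.375)
    slice_thickness_mm: float = 4.0

    def __post_init__(self) -> None:
        shapes = {ch: getattr(self, ch).shape for ch in CHANNELS}
        if len(set(shapes.values())) != 1:
            raise GeometryMismatchError(f"geometry mismatch across channels: {shapes}")
        if self.water.ndim != 3:
            raise ValidationError("channels must be 3D [slice, row, col] arrays")
        ff = self.fat_fraction
        if ff.size and (np.nanmin(ff) < 0 or np.nanmax(ff) > 100):
            raise ValidationError("fat_fraction must lie in [0, 100] percent")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.water.shape

    @property
    def n_slices(self) -> int:
        return self.water.shape[0]

    def channel_stack(self, dtype=np.float32) -> np.ndarray:
        """Stack the four channels as ``[slice, row, col, 4]`` in canonical order."""
        return np.stack(
            [np.asarray(getattr(self, ch), dtype=dtype) for ch in CHANNELS], axis=-1
        )


@dataclass
class MaskVolume:
    """A per-pixel vertebra labelling aligned to a :class:`DixonSeries`.

    ``kind`` is ``"binary"`` ({0,1} integer data) or ``"probability"``
    ([0,1] float data).
    """

    data: np.ndarray
    kind: Literal["binary", "probability"] = "binary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError("mask data must be 3D [slice, row, col]")
        if self.kind == "binary":
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError("binary mask contains values other than {0, 1}")
            self.data = self.data.astype(np.uint8)
        elif self.kind == "probability":
            if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
                raise ValidationError("probability mask values must lie in [0, 1]")
            self.data = self.data.astype(np.float64)
        else:
            raise ValidationError(f"unknown mask kind: {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# Dixon series I/O
# ---------------------------------------------------------------------------

def _find_channel_nifti(directory: Path, channel: str) -> Path | None:
    suffix = CHANNEL_SUFFIXES[channel]
    for ext in (".nii", ".nii.gz"):
        hits = sorted(directory.glob(f"*{suffix}{ext}"))
        if hits:
            return hits[0]
    return None


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float], float]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    # Volumes are written with axes (slice, row, col); nibabel returns the
    # stored axis order unchanged for our writer's identity affine.
    zooms = img.header.get_zooms()
    slice_thickness = float(zooms[0]) if len(zooms) >= 1 else 4.0
    spacing = (float(zooms[1]), float(zooms[2])) if len(zooms) >= 3 else (1.375, 1.375)
    return data, spacing, slice_thickness


def _load_dicom_dir(directory: Path) -> tuple[np.ndarray, tuple[float, float], float]:
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FormatError(f"no DICOM files in {directory}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise FormatError(f"unreadable DICOM file {f}: {exc}") from exc
        arr = ds.pixel_array.astype(np.float64)
        if "RescaleSlope" in ds or "RescaleIntercept" in ds:
            arr = arr * float(getattr(ds, "RescaleSlope", 1.0)) + float(
                getattr(ds, "RescaleIntercept", 0.0)
            )
        slices.append((int(getattr(ds, "InstanceNumber", len(slices))), arr, ds))
    slices.sort(key=lambda t: t[0])
    shapes = {s[1].shape for s in slices}
    if len(shapes) != 1:
        raise GeometryMismatchError(f"geometry mismatch across DICOM slices: {shapes}")
    ds0 = slices[0][2]
    spacing = tuple(float(v) for v in getattr(ds0, "PixelSpacing", (1.375, 1.375)))
    thickness = float(getattr(ds0, "SliceThickness", 4.0))
    return np.stack([s[1] for s in slices]), spacing, thickness


def read_dixon_series(
    path: str | os.PathLike,
    layout: Literal["auto", "nifti", "dicom"] = "auto",
    subject_id: str | None = None,
) -> DixonSeries:
    """Read a 4-channel Dixon series from NIfTI files or DICOM directories.

    For ``layout="nifti"`` the directory must contain one volume per channel
    named ``*_water``, ``*_fat``, ``*_ff``, ``*_r2s`` (``.nii``/``.nii.gz``).
    For ``layout="dicom"`` the directory must contain four sub-directories
    named ``water``, ``fat``, ``ff`` and ``r2s``, each holding one DICOM
    series.  Fat-fraction values are clipped into [0, 100] on read.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    if layout == "auto":
        layout = "dicom" if (directory / "water").is_dir() else "nifti"

    arrays: dict[str, np.ndarray] = {}
    spacing, thickness = (1.375, 1.375), 4.0
    dicom_dirnames = {"water": "water", "fat": "fat", "fat_fraction": "ff", "r2star": "r2s"}
    for ch in CHANNELS:
        if layout == "nifti":
            src = _find_channel_nifti(directory, ch)
            if src is None:
                raise IncompleteSeriesError(f"incomplete series: {ch}")
            arrays[ch], spacing, thickness = _load_nifti(src)
        else:
            sub = directory / dicom_dirnames[ch]
            if not sub.is_dir():
                raise IncompleteSeriesError(f"incomplete series: {ch}")
            arrays[ch], spacing, thickness = _load_dicom_dir(sub)

    shapes = {ch: a.shape for ch, a in arrays.items()}
    if len(set(shapes.values())) != 1:
        raise GeometryMismatchError(f"geometry mismatch across channels: {shapes}")
    arrays["fat_fraction"] = np.clip(arrays["fat_fraction"], 0.0, 100.0)
    return DixonSeries(
        subject_id=subject_id or directory.name,
        water=arrays["water"],
        fat=arrays["fat"],
        fat_fraction=arrays["fat_fraction"],
        r2star=arrays["r2star"],
        pixel_spacing_mm=spacing,
        slice_thickness_mm=thickness,
    )


def write_dixon_series(
    series: DixonSeries,
    dest: str | os.PathLike,
    layout: Literal["nifti", "dicom"] = "nifti",
) -> list[Path]:
    """Write a series as NIfTI channel volumes or DICOM channel series.

    The DICOM layout mirrors what :func:`read_dixon_series` expects: one
    sub-directory per channel (``water``, ``fat``, ``ff``, ``r2s``) of
    single-frame Secondary Capture slices, stored as uint16 with per-channel
    rescale slope/intercept covering the value range.
    """
    directory = Path(dest)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    if layout == "nifti":
        for ch in CHANNELS:
            p = directory / f"{series.subject_id}{CHANNEL_SUFFIXES[ch]}.nii.gz"
            img = nib.Nifti1Image(np.asarray(getattr(series, ch), dtype=np.float64), np.eye(4))
            img.header.set_zooms(
                (series.slice_thickness_mm, *series.pixel_spacing_mm)
            )
            nib.save(img, str(p))
            paths.append(p)
        return paths
    if layout != "dicom":
        raise ValidationError(f"unknown series layout: {layout!r}")

    dicom_dirnames = {"water": "water", "fat": "fat", "fat_fraction": "ff", "r2star": "r2s"}
    for ch in CHANNELS:
        arr = np.asarray(getattr(series, ch), dtype=np.float64)
        lo, hi = float(arr.min()), float(arr.max())
        integral = np.allclose(arr, np.round(arr)) and 0 <= lo and hi <= 65535
        if integral:
            slope, intercept = 1.0, 0.0
            stored = np.round(arr).astype(np.uint16)
        else:
            slope = (hi - lo) / 65535.0 if hi > lo else 1.0
            intercept = lo
            stored = np.round((arr - intercept) / slope).astype(np.uint16)
        sub = directory / dicom_dirnames[ch]
        sub.mkdir(parents=True, exist_ok=True)
        series_uid = generate_uid()
        for i in range(stored.shape[0]):
            ds = Dataset()
            ds.file_meta = FileMetaDataset()
            ds.file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
            ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
            ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.SOPClassUID = SecondaryCaptureImageStorage
            ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
            ds.SeriesInstanceUID = series_uid
            ds.Modality = "OT"
            ds.PatientID = series.subject_id
            ds.SeriesDescription = ch
            ds.InstanceNumber = i + 1
            ds.Rows, ds.Columns = stored.shape[1:]
            ds.PixelSpacing = [str(v) for v in series.pixel_spacing_mm]
            ds.SliceThickness = str(series.slice_thickness_mm)
            ds.RescaleSlope = str(slope)
            ds.RescaleIntercept = str(intercept)
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.PixelData = stored[i].tobytes()
            p = sub / f"{ch}_{i:03d}.dcm"
            ds.save_as(str(p), enforce_file_format=True)
            paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Mask I/O
# ---------------------------------------------------------------------------

def write_mask_volume(
    mask: MaskVolume,
    template: DixonSeries,
    dest: str | os.PathLike,
    format: Literal["dicom", "nifti", "png_stack"] = "nifti",
) -> list[Path]:
    """Write a binary mask; geometry metadata is copied from ``template``.

    DICOM output uses one Secondary Capture object per slice so that a mask
    produced from any series can be stored without private tags.  A
    write-then-read round trip reproduces ``mask.data`` bit-exactly.
    """
    if mask.kind != "binary":
        raise ValidationError("binarize first: only binary masks can be written")
    if mask.shape != template.shape:
        raise GeometryMismatchError(
            f"mask shape {mask.shape} does not match template {template.shape}"
        )
    dest = Path(dest)
    data = mask.data.astype(np.uint8)

    if format == "nifti":
        dest.parent.mkdir(parents=True, exist_ok=True)
        if not str(dest).endswith((".nii", ".nii.gz")):
            dest = dest.with_suffix(".nii.gz")
        img = nib.Nifti1Image(data, np.eye(4))
        img.header.set_zooms((template.slice_thickness_mm, *template.pixel_spacing_mm))
        nib.save(img, str(dest))
        return [dest]

    if format == "png_stack":
        dest.mkdir(parents=True, exist_ok=True)
        paths = []
        for i in range(data.shape[0]):
            p = dest / f"mask_{i:03d}.png"
            Image.fromarray(data[i] * 255).save(str(p))
            paths.append(p)
        return paths

    if format == "dicom":
        dest.mkdir(parents=True, exist_ok=True)
        series_uid = generate_uid()
        paths = []
        for i in range(data.shape[0]):
            ds = Dataset()
            ds.file_meta = FileMetaDataset()
            ds.file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
            ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
            ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.SOPClassUID = SecondaryCaptureImageStorage
            ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
            ds.SeriesInstanceUID = series_uid
            ds.Modality = "OT"
            ds.PatientID = template.subject_id
            ds.SeriesDescription = "vertebra mask"
            ds.InstanceNumber = i + 1
            ds.Rows, ds.Columns = data.shape[1:]
            ds.PixelSpacing = [str(v) for v in template.pixel_spacing_mm]
            ds.SliceThickness = str(template.slice_thickness_mm)
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 8
            ds.BitsStored = 8
            ds.HighBit = 7
            ds.PixelRepresentation = 0
            ds.PixelData = data[i].tobytes()
            p = dest / f"mask_{i:03d}.dcm"
            ds.save_as(str(p), enforce_file_format=True)
            paths.append(p)
        return paths

    raise ValidationError(f"unknown mask format: {format!r}")


def read_mask_volume(src: str | os.PathLike) -> MaskVolume:
    """Read a binary mask written by :func:`write_mask_volume`.

    Any nonzero stored value is coerced to 1.  The source may be a NIfTI
    file, a directory of DICOM slices, or a directory of PNG slices.
    """
    src = Path(src)
    if src.is_file() or str(src).endswith((".nii", ".nii.gz")):
        data, _, _ = _load_nifti(src)
        return MaskVolume((data != 0).astype(np.uint8), kind="binary")
    if not src.is_dir():
        raise FormatError(f"no such mask source: {src}")
    dcm = sorted(src.glob("*.dcm"))
    png = sorted(src.glob("*.png"))
    if dcm:
        data, _, _ = _load_dicom_dir(src)
    elif png:
        slices = [np.asarray(Image.open(str(p))) for p in png]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise GeometryMismatchError(f"geometry mismatch across PNG slices: {shapes}")
        data = np.stack(slices)
    else:
        raise FormatError(f"no DICOM or PNG mask slices in {src}")
    return MaskVolume((data != 0).astype(np.uint8), kind="binary")


def check_same_geometry(mask: MaskVolume, series: DixonSeries) -> None:
    """Raise :class:`GeometryMismatchError` unless shapes agree."""
    if mask.shape != series.shape:
        raise GeometryMismatchError(
            f"mask shape {mask.shape} does not match series shape {series.shape}"
        )
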