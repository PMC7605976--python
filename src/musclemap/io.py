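"""Reading and writing the formats the toolkit touches.

* CT slices: single-frame DICOM, converted to Hounsfield units on read via
  the file's rescale slope/intercept (HU = raw * slope + intercept).
* Compartment label masks: NIfTI or 8-bit PNG with the fixed dialect
  {0: background, 1: TAMA, 2: visceral fat, 3: subcutaneous fat}.
* Composition reports: JSON (nested) or CSV (flat, one row per slice);
  both round-trip all numeric fields losslessly.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

from musclemap.errors import (
    AlignmentError,
    DialectError,
    FormatError,
    MetadataError,
    UnsupportedInputError,
)
from musclemap.quality import CompositionReport, round_half_away_from_zero

__all__ = [
    "CTSlice",
    "MaskImage",
    "MASK_CODE_TABLE",
    "read_ct_slice",
    "write_ct_slice",
    "read_mask",
    "write_mask",
    "write_report",
    "read_report",
]

#: the one documented label dialect for compartment masks
MASK_CODE_TABLE = {0: "background", 1: "tama", 2: "vfa", 3: "sfa"}


@dataclass
class CTSlice:
    """A calibrated axial CT slice: HU pixels plus physical pixel spacing.

    Pixels are stored as floats *after* HU conversion; ``meta`` records the
    slope/intercept that were applied (``hu_calibrated`` guards against a
    second conversion) along with modality, contrast-phase label and source.
    """

    pixels: np.ndarray
    row_spacing_mm: float
    col_spacing_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise FormatError(f"CT slice pixels must be 2-D, got {self.pixels.ndim}-D")
        if not (self.row_spacing_mm > 0 and self.col_spacing_mm > 0):
            raise MetadataError(
                f"pixel spacing must be positive, got "
                f"({self.row_spacing_mm}, {self.col_spacing_mm})"
            )
        self.meta.setdefault("hu_calibrated", True)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def pixel_area_cm2(self) -> float:
        return self.row_spacing_mm * self.col_spacing_mm / 100.0


@dataclass
class MaskImage:
    """A label image aligned to a CT slice, codes per :data:`MASK_CODE_TABLE`."""

    labels: np.ndarray
    code_table: dict = field(default_factory=lambda: dict(MASK_CODE_TABLE))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels).tolist())
        unknown = sorted(present - set(self.code_table))
        if unknown:
            raise DialectError(
                f"mask contains codes outside the documented dialect: {unknown} "
                f"(allowed: {sorted(self.code_table)})"
            )


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

_REQUIRED_TAGS = ("RescaleSlope", "RescaleIntercept", "PixelSpacing")


def read_ct_slice(path) -> CTSlice:
    """Read a single-frame CT DICOM file and convert raw values to HU.

    HU = raw * RescaleSlope + RescaleIntercept, applied exactly once.
    MONOCHROME1 data are inverted about the raw range before rescale;
    multi-frame files are rejected.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pydicom raises several unrelated types
        raise FormatError(f"cannot parse {path} as DICOM: {exc}") from exc

    nframes = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if nframes > 1:
        raise UnsupportedInputError(
            f"{path}: multi-frame file ({nframes} frames); only single-frame "
            "axial slices are supported"
        )
    if "PixelData" not in ds:
        raise FormatError(f"{path}: no PixelData element")
    for tag in _REQUIRED_TAGS:
        if getattr(ds, tag, None) is None:
            raise MetadataError(f"{path}: missing required DICOM attribute {tag}")

    raw = ds.pixel_array.astype(float)
    if raw.ndim != 2:
        raise UnsupportedInputError(f"{path}: expected 2-D pixel data, got {raw.ndim}-D")

    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric == "MONOCHROME1":
        raw = raw.max() - raw

    slope = float(ds.RescaleSlope)
    intercept = float(ds.RescaleIntercept)
    hu = raw * slope + intercept

    spacing = ds.PixelSpacing  # (row spacing, column spacing) in mm
    meta = {
        "hu_calibrated": True,
        "rescale_slope": slope,
        "rescale_intercept": intercept,
        "modality": str(getattr(ds, "Modality", "")),
        "contrast_phase": str(getattr(ds, "SeriesDescription", "")),
        "photometric": photometric,
        "source": str(path),
    }
    return CTSlice(
        pixels=hu,
        row_spacing_mm=float(spacing[0]),
        col_spacing_mm=float(spacing[1]),
        meta=meta,
    )


def write_ct_slice(ct_slice: CTSlice, path) -> None:
    """Write a CTSlice as a single-frame CT DICOM file.

    Stored raw values are int16 with slope 1 / intercept -1024, i.e.
    raw = round(HU) + 1024.  HU values are quantized to the nearest integer
    (half away from zero) on write, as on a real scanner; the read-back of a
    slice with integer-valued HU reproduces the pixels exactly.  All UIDs
    and descriptive fields are derived deterministically from the pixel
    content, so identical slices produce byte-identical files.
    """
    intercept = -1024.0
    raw = round_half_away_from_zero(ct_slice.pixels) - intercept
    if raw.min() < 0 or raw.max() > 32767:
        raise FormatError(
            f"HU range [{ct_slice.pixels.min():.0f}, {ct_slice.pixels.max():.0f}] "
            "does not fit the int16 raw encoding with intercept -1024"
        )
    raw = raw.astype(np.int16)

    digest = hashlib.sha256(raw.tobytes()).hexdigest()
    # deterministic UID under the pydicom example root (content-addressed)
    uid_suffix = str(int(digest[:16], 16))
    sop_uid = f"1.2.826.0.1.3680043.8.498.{uid_suffix}"

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = CTImageStorage
    file_meta.MediaStorageSOPInstanceUID = sop_uid
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=file_meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "CT"
    ds.SeriesDescription = str(ct_slice.meta.get("contrast_phase", ""))
    ds.PatientName = ""
    ds.PatientID = str(ct_slice.meta.get("source", "musclemap"))
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.SamplesPerPixel = 1
    ds.Rows, ds.Columns = raw.shape
    ds.PixelSpacing = [ct_slice.row_spacing_mm, ct_slice.col_spacing_mm]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.RescaleSlope = 1
    ds.RescaleIntercept = int(intercept)
    ds.PixelData = raw.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def read_mask(path, reference: CTSlice) -> MaskImage:
    """Read a NIfTI or PNG label image and validate it against ``reference``.

    Codes must follow :data:`MASK_CODE_TABLE`; any other code raises a
    :class:`DialectError` naming the offending codes, and a shape mismatch
    with the reference slice raises an :class:`AlignmentError`.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise FormatError(f"{path}: mask must be a single 2-D image")
        labels = data.astype(np.int64)
    elif suffixes.endswith(".png"):
        img = iio.imread(str(path))
        if img.ndim != 2:
            raise FormatError(f"{path}: mask PNG must be single-channel")
        labels = img.astype(np.int64)
    else:
        raise FormatError(f"{path}: unsupported mask format (use .nii/.nii.gz/.png)")

    if labels.shape != reference.pixels.shape:
        raise AlignmentError(
            f"{path}: mask shape {labels.shape} does not match "
            f"slice shape {reference.pixels.shape}"
        )
    return MaskImage(labels=labels)


def write_mask(labels: np.ndarray, path) -> None:
    """Write a label array as PNG (uint8) or NIfTI, by file extension."""
    path = Path(path)
    labels = np.asarray(labels)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(labels.astype(np.uint8), affine=np.eye(4)), str(path))
    elif suffixes.endswith(".png"):
        iio.imwrite(str(path), labels.astype(np.uint8))
    else:
        raise FormatError(f"{path}: unsupported mask format (use .nii/.nii.gz/.png)")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

#: flat CSV column order (histogram and provenance serialized as JSON cells)
REPORT_CSV_COLUMNS = [
    "tama_cm2", "nama_cm2", "lama_cm2", "imat_cm2", "other_cm2",
    "sma_cm2", "myosteatosis_cm2", "vfa_cm2", "sfa_cm2",
    "mean_tama_density_hu", "mean_sma_density_hu",
    "pixel_area_cm2", "histogram_bin_width_hu",
    "histogram_edges_hu", "histogram_counts", "provenance",
]


def write_report(report: CompositionReport, path, format: str = "json") -> None:
    """Serialize a composition report as JSON or a one-row CSV.

    Floats are written with shortest round-tripping repr, so a read-back
    reproduces every numeric field exactly.
    """
    d = report.to_dict()
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        row = dict(d)
        for key in ("histogram_edges_hu", "histogram_counts", "provenance"):
            row[key] = json.dumps(row[key])
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=REPORT_CSV_COLUMNS)
            writer.writeheader()
            writer.writerow(row)
    else:
        raise FormatError(f"unknown report format {format!r} (use 'json' or 'csv')")


def read_report(path, format: str | None = None) -> CompositionReport:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if format == "json":
        with open(path) as fh:
            return CompositionReport.from_dict(json.load(fh))
    if format == "csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if len(rows) != 1:
            raise FormatError(f"{path}: expected exactly one report row")
        row = dict(rows[0])
        d: dict = {}
        for key in ("histogram_edges_hu", "histogram_counts", "provenance"):
            d[key] = json.loads(row.pop(key))
        for key, val in row.items():
            d[key] = None if val == "" else float(val)
        return CompositionReport.from_dict(d)
    raise FormatError(f"unknown report format {format!r}")
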