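"""Image I/O: 16-bit PNG/TIFF grayscale and DICOM with rescale handling.

DICOM pixel data are returned in physical units (``slope * stored +
intercept``); PNG and TIFF are read/written as 16-bit grayscale.  Writing a
DICOM creates a minimal secondary-capture dataset carrying the pixel
spacing, suitable for round-tripping pipeline intermediates.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np

__all__ = ["read_image", "write_image"]


def _read_dicom(path: str):
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    spacing = getattr(ds, "PixelSpacing", None)
    spacing_mm = float(spacing[0]) if spacing is not None else None
    return arr, spacing_mm


def _write_dicom(path: str, image: np.ndarray, spacing_mm: Optional[float]):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    stored = np.round(image).astype(np.int16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(path, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = stored.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = 0.0
    if spacing_mm is not None:
        ds.PixelSpacing = [spacing_mm, spacing_mm]
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_image(path: str):
    """Read a grayscale image; returns (array, spacing_mm or None)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".dcm", ".dicom"):
        return _read_dicom(path)
    if ext in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path).astype(float), None
    import imageio.v3 as iio

    return iio.imread(path).astype(float), None


def write_image(path: str, image: np.ndarray,
                spacing_mm: Optional[float] = None) -> None:
    """Write a grayscale image in the format implied by the extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".dcm", ".dicom"):
        _write_dicom(path, image, spacing_mm)
        return
    if ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.round(image).astype(np.uint16))
        return
    import imageio.v3 as iio

    iio.imwrite(path, np.clip(np.round(image), 0, 65535).astype(np.uint16))
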