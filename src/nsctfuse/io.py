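"""Readers and writers for the standard single-slice image formats.

Every reader returns a :class:`LoadedImage` whose ``pixels`` are a float64
2-D array in [0, 1]; the rescaling is recorded so outputs can be written back
at the source bit depth.  Integer inputs are scaled by the dtype's full range
(e.g. uint8 by 255), float inputs by their min–max range.  RGB inputs are
collapsed to luminance with the ITU-R BT.601 weights (0.299, 0.587, 0.114).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["LoadedImage", "read_image", "write_image"]

log = logging.getLogger(__name__)

_LUMA = np.array([0.299, 0.587, 0.114])

_EXT_FORMAT = {
    ".png": "PNG", ".jpg": "PNG", ".jpeg": "PNG", ".bmp": "PNG",
    ".tif": "TIFF", ".tiff": "TIFF",
    ".nii": "NIfTI", ".gz": "NIfTI",
    ".dcm": "DICOM", ".dicom": "DICOM", ".ima": "DICOM",
}


@dataclass
class LoadedImage:
    pixels: np.ndarray          # float64 in [0, 1]
    source_dtype: np.dtype
    source_path: str
    format: str                 # {PNG, TIFF, NIfTI, DICOM}
    offset: float = 0.0         # original = pixels * scale + offset
    scale: float = 1.0


def _sniff_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext == ".gz" and path.name.lower().endswith(".nii.gz"):
        return "NIfTI"
    if ext in _EXT_FORMAT:
        return _EXT_FORMAT[ext]
    with open(path, "rb") as fh:
        head = fh.read(132)
    if head[:8] == b"\x89PNG\r\n\x1a\n":
        return "PNG"
    if head[:4] in (b"II*\x00", b"MM\x00*"):
        return "TIFF"
    if head[128:132] == b"DICM":
        return "DICOM"
    raise ValueError(f"unsupported image format: {path}")


def _to_gray(arr: np.ndarray, path: Path, slice_index: int | None,
             channels_possible: bool) -> np.ndarray:
    # PNG/TIFF trailing dims of 3/4 are colour channels; volume formats never are
    if channels_possible and arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3] @ _LUMA
    if arr.ndim == 3:
        if slice_index is None:
            raise ValueError(
                f"{path} is a 3-D volume with shape {arr.shape}; "
                "pass an explicit slice index"
            )
        arr = arr[..., slice_index] if arr.shape[2] < arr.shape[0] else arr[slice_index]
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret {path} (shape {arr.shape}) as a 2-D image")
    return np.asarray(arr, dtype=np.float64)


def read_image(path: str | Path, slice_index: int | None = None) -> LoadedImage:
    """Read one single-channel 2-D image, rescaled to [0, 1].

    3-D volumes (NIfTI, multi-frame DICOM) need an explicit ``slice_index``;
    multi-channel inputs are converted by luminance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    fmt = _sniff_format(path)

    if fmt == "PNG":
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path))
    elif fmt == "TIFF":
        import tifffile

        raw = tifffile.imread(path)
    elif fmt == "NIfTI":
        import nibabel as nib

        img = nib.load(str(path))
        raw = np.asarray(img.dataobj)
        raw = np.squeeze(raw)
    else:  # DICOM
        import pydicom

        ds = pydicom.dcmread(path)
        raw = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        raw = raw * slope + intercept

    source_dtype = np.asarray(raw).dtype
    arr = _to_gray(np.asarray(raw), path, slice_index, fmt in ("PNG", "TIFF"))
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path} contains non-finite pixel values")

    if np.issubdtype(source_dtype, np.integer) and fmt != "DICOM":
        info = np.iinfo(source_dtype)
        offset, scale = float(info.min), float(info.max - info.min) or 1.0
    else:
        lo, hi = float(arr.min()), float(arr.max())
        offset, scale = lo, (hi - lo) or 1.0
    pixels = (arr - offset) / scale
    return LoadedImage(
        pixels=pixels,
        source_dtype=source_dtype,
        source_path=str(path),
        format=fmt,
        offset=offset,
        scale=scale,
    )


_WRITE_DTYPES = {"uint8": np.uint8, "uint16": np.uint16, "float32": np.float32}


def write_image(image: np.ndarray, path: str | Path, dtype: str = "uint16") -> None:
    """Write a [0, 1] image, format chosen by extension (PNG/TIFF/NIfTI).

    Out-of-range values are clipped with a logged warning.  Integer dtypes
    scale by the full dtype range (the inverse of the read rescaling);
    ``float32`` writes raw values (TIFF/NIfTI only).
    """
    path = Path(path)
    if dtype not in _WRITE_DTYPES:
        raise ValueError(f"dtype must be one of {sorted(_WRITE_DTYPES)}, got {dtype!r}")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if image.min() < 0.0 or image.max() > 1.0:
        log.warning(
            "clipping out-of-range values [%.4g, %.4g] to [0, 1] for %s",
            image.min(), image.max(), path,
        )
        image = np.clip(image, 0.0, 1.0)

    ext = path.suffix.lower()
    np_dtype = _WRITE_DTYPES[dtype]
    if dtype == "float32":
        data = image.astype(np.float32)
    else:
        data = np.rint(image * np.iinfo(np_dtype).max).astype(np_dtype)

    if ext in (".png", ".bmp"):
        if dtype == "float32":
            raise ValueError("PNG output requires an integer dtype")
        import imageio.v3 as iio

        iio.imwrite(path, data)
    elif ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    elif ext == ".nii" or path.name.lower().endswith(".nii.gz"):
        import nibabel as nib

        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    else:
        raise ValueError(f"unsupported output extension: {path.suffix!r}")
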