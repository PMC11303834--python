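"""Readers and writers for volumes, label maps, curves, and tables.

Supported volume formats are multi-page TIFF (``.tif``/``.tiff``) and
NIfTI-1 (``.nii``/``.nii.gz``).  The voxel size travels in the file header:
TIFF uses ImageJ-style resolution tags (µm per pixel), NIfTI uses the zoom
fields with the spatial unit set to micrometres.  Reading a file that lacks
a voxel size and was given no override is an error — downstream
measurements are calibrated, so a silent default would be wrong.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .volume import ImageVolume, LabelMap, LandmarkCurve

__all__ = [
    "read_volume",
    "write_volume",
    "write_array",
    "read_labelmap",
    "write_labelmap",
    "read_curve",
    "write_curve",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def _read_tiff(path: Path, voxel_size_um: float | None):
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        size = None
        if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
            # ImageJ convention: spacing = z-step, XResolution = px per unit
            size = float(tf.imagej_metadata["spacing"])
        else:
            page = tf.pages[0]
            tag = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            # ResolutionUnit 1 means "no absolute unit": not a calibration
            if tag is not None and unit is not None and unit.value != 1:
                num, den = tag.value
                if num:
                    size = den / num
    if voxel_size_um is not None:
        size = float(voxel_size_um)
    if size is None or size <= 0:
        raise ValueError(
            f"{path}: no voxel size in TIFF tags and no override given"
        )
    return np.atleast_3d(data), size


_NIFTI_UNIT_TO_UM = {"micron": 1.0, "mm": 1e3, "meter": 1e6, "unknown": None}


def _read_nifti(path: Path, voxel_size_um: float | None):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI volume")
    # NIfTI stores (x, y, z); normalize to (z, y, x)
    data = np.ascontiguousarray(data.T)
    zooms = img.header.get_zooms()[:3]
    if voxel_size_um is not None:
        return data, float(voxel_size_um)
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(
            f"{path}: anisotropic voxels {zooms}; resample first or pass an "
            "explicit voxel-size override"
        )
    unit = img.header.get_xyzt_units()[0]
    scale = _NIFTI_UNIT_TO_UM.get(unit)
    if scale is None:
        raise ValueError(
            f"{path}: spatial unit is '{unit}'; pass a voxel-size override"
        )
    return data, float(zooms[0]) * scale


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> ImageVolume:
    """Read a 3D volume from multi-page TIFF or NIfTI-1.

    Parameters
    ----------
    path
        Input file.  The format is chosen by suffix.
    voxel_size_um
        Optional override for the voxel size recorded in the header.
    """
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        data, size = _read_tiff(path, voxel_size_um)
    elif _is_nifti(path):
        data, size = _read_nifti(path, voxel_size_um)
    else:
        raise ValueError(
            f"{path}: unknown format '{path.suffix}'; supported: "
            ".tif/.tiff (multi-page TIFF), .nii/.nii.gz (NIfTI-1)"
        )
    return ImageVolume(data=data, voxel_size_um=size)


def write_volume(volume: ImageVolume | LabelMap, path: str | Path) -> Path:
    """Write a volume or label map; the voxel size goes in the header."""
    return write_array(volume.data, float(volume.voxel_size_um), path)


def write_array(data: np.ndarray, voxel_size_um: float, path: str | Path) -> Path:
    """Write a bare 3D array (NaN allowed, e.g. helix-angle maps)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data, size = np.asarray(data), float(voxel_size_um)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / size, 1.0 / size),
            metadata={"spacing": size, "unit": "um", "axes": "ZYX"},
        )
    elif _is_nifti(path):
        affine = np.diag([size, size, size, 1.0])
        img = nib.Nifti1Image(np.asarray(data).T, affine)
        img.header.set_zooms((size, size, size))
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, str(path))
    else:
        raise ValueError(f"{path}: unsupported output format '{path.suffix}'")
    return path


def read_labelmap(path: str | Path, voxel_size_um: float | None = None) -> LabelMap:
    vol = read_volume(path, voxel_size_um)
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise ValueError(f"{path}: label map contains non-integer values")
        data = rounded.astype(np.int32)
    return LabelMap(data=data, voxel_size_um=vol.voxel_size_um)


def write_labelmap(labelmap: LabelMap, path: str | Path) -> Path:
    data = labelmap.data
    if data.max(initial=0) < 256 and data.min(initial=0) >= 0:
        labelmap = LabelMap(data.astype(np.uint8), labelmap.voxel_size_um)
    return write_volume(labelmap, path)


def write_curve(curve: LandmarkCurve, path: str | Path) -> Path:
    """Write a landmark curve as CSV with columns angle_deg, x_um, y_um, z_um."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    angles = (
        curve.angles_deg
        if curve.angles_deg is not None
        else np.full(len(curve), np.nan)
    )
    df = pd.DataFrame(
        {
            "angle_deg": angles,
            "x_um": curve.points_um[:, 2],
            "y_um": curve.points_um[:, 1],
            "z_um": curve.points_um[:, 0],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_curve(path: str | Path) -> LandmarkCurve:
    df = pd.read_csv(path)
    for col in ("x_um", "y_um", "z_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    pts = np.column_stack([df["z_um"], df["y_um"], df["x_um"]])
    angles = df["angle_deg"].to_numpy() if "angle_deg" in df.columns else None
    if angles is not None and np.all(np.isnan(angles)):
        angles = None
    return LandmarkCurve(points_um=pts, angles_deg=angles)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
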