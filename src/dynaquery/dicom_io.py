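"""DICOM ingestion: pixel data plus position/orientation metadata.

Builds the 22-component raw metadata vector consumed by the preprocessing
pipeline: patient position (x, y, z), proper Euler angles (φ, θ, ψ) derived
from the image-orientation direction cosines, the two 3-component
orientation vectors themselves, the relative slice-location scalar, and —
when a scout (localizer) scan is supplied — its position and orientation.
Missing tags degrade gracefully: the affected components are zero-filled and
a warning is emitted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pydicom
from scipy.spatial.transform import Rotation

from .data_pools import Sample

METADATA_DIM = 22


def _orientation_tags(ds: pydicom.Dataset, origin: str) -> tuple[np.ndarray, np.ndarray, float]:
    """Extract (position(3), orientation(6), slice_location) with zero-fill."""
    position = np.zeros(3)
    orientation = np.zeros(6)
    slice_loc = 0.0
    if "ImagePositionPatient" in ds:
        position = np.asarray([float(v) for v in ds.ImagePositionPatient])
    else:
        warnings.warn(f"{origin}: ImagePositionPatient missing, zero-filled", stacklevel=3)
    if "ImageOrientationPatient" in ds:
        orientation = np.asarray([float(v) for v in ds.ImageOrientationPatient])
    else:
        warnings.warn(f"{origin}: ImageOrientationPatient missing, zero-filled", stacklevel=3)
    if "SliceLocation" in ds:
        slice_loc = float(ds.SliceLocation)
    else:
        warnings.warn(f"{origin}: SliceLocation missing, zero-filled", stacklevel=3)
    return position, orientation, slice_loc


def euler_from_orientation(orientation: np.ndarray) -> np.ndarray:
    """Proper (z-x-z) Euler angles of the scan plane's rotation matrix, built
    from the row/column direction cosines and their normal.  Returns zeros
    for a degenerate (e.g. zero-filled) orientation."""
    row, col = orientation[:3], orientation[3:]
    if np.linalg.norm(row) < 1e-9 or np.linalg.norm(col) < 1e-9:
        return np.zeros(3)
    row = row / np.linalg.norm(row)
    col = col / np.linalg.norm(col)
    normal = np.cross(row, col)
    matrix = np.column_stack([row, col, normal])
    try:
        with warnings.catch_warnings():
            # axis-aligned planes hit the ZXZ degeneracy; the convention of
            # putting the whole rotation in the first angle is fine here
            warnings.filterwarnings("ignore", message="Gimbal lock")
            return Rotation.from_matrix(matrix).as_euler("ZXZ")
    except ValueError:
        warnings.warn("non-orthonormal image orientation; Euler angles zero-filled", stacklevel=2)
        return np.zeros(3)


def read_dicom_sample(path: str | Path, scout_path: str | Path | None = None) -> Sample:
    """Read one DICOM file (and optionally its scout scan) into a Sample.

    Raises on unreadable files or missing pixel data; missing metadata tags
    are zero-filled with a warning.  With no scout file, the six scout
    components are zeros (flagged by a warning).
    """
    path = Path(path)
    ds = pydicom.dcmread(path)
    if "PixelData" not in ds:
        raise ValueError(f"{path}: DICOM file has no pixel data")
    image = np.asarray(ds.pixel_array, dtype=float)

    position, orientation, slice_loc = _orientation_tags(ds, path.name)
    euler = euler_from_orientation(orientation)

    if scout_path is not None:
        scout = pydicom.dcmread(Path(scout_path))
        scout_pos, scout_orient, _ = _orientation_tags(scout, Path(scout_path).name)
    else:
        warnings.warn(f"{path.name}: no scout scan supplied, scout metadata zero-filled",
                      stacklevel=2)
        scout_pos, scout_orient = np.zeros(3), np.zeros(6)

    metadata = np.concatenate([position, euler, orientation, [slice_loc], scout_pos, scout_orient])
    assert metadata.shape == (METADATA_DIM,)
    sample_id = str(getattr(ds, "SOPInstanceUID", path.stem))
    return Sample(sample_id=sample_id, image=image, metadata_raw=metadata)
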