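"""On-disk I/O for volumes (NIfTI-1), tractograms (TCK/TRK) and labeled
matrices (CSV).

Coordinate contract: voxel indices are 0-based with voxel-center
coordinates; voxel (0,0,0) maps to the world point ``affine @ (0,0,0,1)``.
TRK's voxel-space conventions are converted at read/write so that all
in-memory streamlines are world-coordinate.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import TckFile, TrkFile
from nibabel.streamlines import Tractogram as NibTractogram
from nibabel.streamlines.trk import Field

from .types import LabeledMatrix, Tractogram, VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_tractogram",
    "write_tractogram",
    "read_matrix",
    "write_matrix",
]


def read_volume(path) -> VolumeGrid:
    """Read a 3D NIfTI-1 file into a :class:`VolumeGrid`."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got ndim={data.ndim}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: image contains non-finite values")
    unit_code = img.header.get_xyzt_units()[0]
    unit = {"mm": "mm", "micron": "um"}.get(unit_code, "voxel")
    return VolumeGrid(values=data, affine=np.asarray(img.affine), space_unit=unit)


def write_volume(vol: VolumeGrid, path) -> str:
    """Write a :class:`VolumeGrid` as NIfTI-1; integer grids keep their dtype."""
    path = os.fspath(path)
    data = vol.values
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    img = nib.Nifti1Image(data, vol.affine)
    if vol.space_unit in ("mm", "um"):
        img.header.set_xyzt_units({"mm": "mm", "um": "micron"}[vol.space_unit])
    nib.save(img, path)
    return path


def _trk_header(t: Tractogram) -> dict:
    shape = t.grid_shape if t.grid_shape is not None else (1, 1, 1)
    affine = t.reference_affine
    return {
        Field.VOXEL_TO_RASMM: affine.astype(np.float32),
        Field.VOXEL_SIZES: np.linalg.norm(affine[:3, :3], axis=0).astype(np.float32),
        Field.DIMENSIONS: np.asarray(shape, dtype=np.int16),
        Field.VOXEL_ORDER: b"RAS",
    }


def read_tractogram(path) -> Tractogram:
    """Read a TCK or TRK file; streamlines come back in world coordinates."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".tck", ".trk"):
        raise ValueError(f"unsupported tractogram format {ext!r} (use .tck or .trk)")
    if not os.path.exists(path):
        raise FileNotFoundError(f"tractogram file not found: {path}")
    tf = nib.streamlines.load(path)  # nibabel returns rasmm (world) coordinates
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    affine = np.asarray(tf.tractogram.affine_to_rasmm)
    if ext == ".trk":
        affine = np.asarray(tf.header[Field.VOXEL_TO_RASMM], dtype=float)
    return Tractogram(
        streamlines=streamlines, reference_affine=affine, provenance="synthetic"
    ) if streamlines else _empty_tractogram(affine)


def _empty_tractogram(affine: np.ndarray) -> Tractogram:
    return Tractogram(streamlines=[], reference_affine=affine)


def write_tractogram(t: Tractogram, path) -> str:
    """Write a :class:`Tractogram` to TCK or TRK (chosen by extension)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".tck", ".trk"):
        raise ValueError(f"unsupported tractogram format {ext!r} (use .tck or .trk)")
    # in-memory streamlines are already world (rasmm) coordinates
    nt = NibTractogram([np.asarray(s, dtype=np.float32) for s in t.streamlines],
                       affine_to_rasmm=np.eye(4))
    if ext == ".tck":
        TckFile(nt).save(path)
    else:
        TrkFile(nt, header=_trk_header(t)).save(path)
    return path


def read_matrix(path) -> LabeledMatrix:
    """Read a labeled CSV matrix (first row = column labels, first column = rows)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"matrix file not found: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate column labels")
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed CSV ({e})") from e
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{path}: matrix contains negative values")
    normalization = "raw"
    # a balanced matrix is recognizable by its marginals; the tag is advisory
    # and rewritten by sinkhorn_balance, so raw is the safe default on read
    return LabeledMatrix(
        values=values,
        row_labels=[str(x) for x in df.index],
        col_labels=[str(x) for x in df.columns],
        normalization=normalization,
    )


def write_matrix(m: LabeledMatrix, path) -> str:
    """Write a labeled matrix as CSV."""
    path = os.fspath(path)
    df = pd.DataFrame(m.values, index=m.row_labels, columns=m.col_labels)
    df.to_csv(path)
    return path
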