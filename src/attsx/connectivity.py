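"""Connectivity matrices from tracer volumes and tractograms, and
Sinkhorn-Knopp balancing.

Two routes produce raw matrices:

* tracer route — per-injection volumes are L2-normalized (removing
  absolute intensity differences between injections), summed voxel-wise
  within each cortical injection group into a composite "sum image",
  and the mean signal over each target parcel mask gives the raw
  connection strength;
* streamline route — a streamline connects two parcels if it traverses
  both, i.e. at least one of its points falls (nearest-voxel) inside
  each parcel's mask; entries are traversal counts.

Sinkhorn-Knopp then rescales rows and columns toward uniform marginals
so matrices from different modalities (or species) become directly
comparable.  For a square matrix this is the classical doubly-stochastic
form (all marginals 1); for an r x c rectangular matrix rows are scaled
to 1 and columns to r/c, which preserves the total mass r and reduces to
the square case when r == c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import LabeledMatrix, ParcelAtlas, Tractogram, VolumeGrid

__all__ = [
    "InjectionRecord",
    "l2_normalize",
    "group_sum_images",
    "tracer_connectivity",
    "streamline_connectivity",
    "sinkhorn_balance",
]


@dataclass
class InjectionRecord:
    """One tracer injection: its load volume and the cortical parcel it seeds."""

    volume: VolumeGrid
    parcel: str
    subject_id: str = ""


def l2_normalize(volume: VolumeGrid) -> VolumeGrid:
    """Divide a volume by its Euclidean (L2) norm."""
    norm = float(np.sqrt(np.sum(volume.values.astype(float) ** 2)))
    if norm == 0:
        raise ValueError("cannot L2-normalize an all-zero volume")
    return VolumeGrid(volume.values / norm, volume.affine, volume.space_unit)


def group_sum_images(records: list) -> dict:
    """Voxel-wise sum of L2-normalized volumes per cortical injection group."""
    sums: dict = {}
    shape = None
    for rec in records:
        if shape is None:
            shape = rec.volume.shape
        elif rec.volume.shape != shape:
            raise ValueError(
                f"volume shape mismatch: {rec.volume.shape} vs {shape}"
            )
        normed = l2_normalize(rec.volume)
        if rec.parcel in sums:
            sums[rec.parcel] = VolumeGrid(
                sums[rec.parcel].values + normed.values, normed.affine, normed.space_unit
            )
        else:
            sums[rec.parcel] = normed
    return sums


def tracer_connectivity(
    sums: dict, atlas: ParcelAtlas, targets: list
) -> LabeledMatrix:
    """Mean sum-image signal within each target parcel mask.

    Rows are injection groups (in the order of ``sums``), columns the
    requested targets.  Cortical targets yield an association matrix; a
    row's own parcel, if present among the targets, is zeroed to exclude
    self-connection.
    """
    rows = list(sums)
    values = np.zeros((len(rows), len(targets)))
    masks = {}
    for t in targets:
        m = atlas.mask(t)  # raises KeyError for unknown parcels
        if not m.any():
            raise ValueError(f"target parcel {t!r} has an empty mask")
        masks[t] = m
    for i, parcel in enumerate(rows):
        img = sums[parcel].values
        for j, t in enumerate(targets):
            if t == parcel:
                continue  # association matrices exclude the self edge
            values[i, j] = float(img[masks[t]].mean())
    return LabeledMatrix(values, rows, list(targets), normalization="raw")


def streamline_connectivity(
    t: Tractogram, atlas: ParcelAtlas, row_names: list, col_names: list
) -> LabeledMatrix:
    """Count streamlines traversing each (row, col) parcel pair.

    A streamline traverses a parcel iff at least one of its points,
    mapped through the atlas affine and rounded to the nearest voxel,
    carries that label; points outside the grid traverse nothing.  A
    streamline visiting several parcels contributes to every pair it
    links.
    """
    grid = atlas.labels
    shape = grid.values.shape
    name_of = {label: name for label, (name, _) in atlas.table.items()}
    row_idx = {n: i for i, n in enumerate(row_names)}
    col_idx = {n: j for j, n in enumerate(col_names)}
    values = np.zeros((len(row_names), len(col_names)))
    inv = np.linalg.inv(grid.affine)
    for sl in t.streamlines:
        vox = np.rint(np.asarray(sl) @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        inside = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
        if not inside.any():
            continue
        vox = vox[inside]
        labels = np.unique(grid.values[vox[:, 0], vox[:, 1], vox[:, 2]])
        names = {name_of[l] for l in labels if l != 0}
        for a in names:
            for b in names:
                if a != b and a in row_idx and b in col_idx:
                    values[row_idx[a], col_idx[b]] += 1
    # symmetric double-count guard: for square matrices each unordered
    # pair was visited twice (a,b) and (b,a) — that is the intended
    # symmetric convention; rectangular row/col families are disjoint.
    return LabeledMatrix(values, list(row_names), list(col_names), normalization="raw")


def sinkhorn_balance(
    m: LabeledMatrix, tol: float = 1e-10, max_iter: int = 10000
) -> LabeledMatrix:
    """Sinkhorn-Knopp alternating row/column scaling.

    Square matrices converge to doubly-stochastic form (all marginals 1);
    r x c rectangular matrices to row sums 1 and column sums r/c.  The
    result is diagonally equivalent to the input (D1 M D2), so relative
    entry ratios within each row are preserved up to column scaling.
    Zero rows/columns are rejected: scaling cannot repair absent
    connectivity and padding would fabricate it.
    """
    A = m.values.astype(float).copy()
    r, c = A.shape
    if np.any(A.sum(axis=1) == 0):
        raise ValueError("matrix has an all-zero row; Sinkhorn balancing undefined")
    if np.any(A.sum(axis=0) == 0):
        raise ValueError("matrix has an all-zero column; Sinkhorn balancing undefined")
    row_target = 1.0
    col_target = r / c
    for _ in range(max_iter):
        A *= (row_target / A.sum(axis=1))[:, None]
        A *= (col_target / A.sum(axis=0))[None, :]
        if (
            np.abs(A.sum(axis=1) - row_target).max() <= tol
            and np.abs(A.sum(axis=0) - col_target).max() <= tol
        ):
            return LabeledMatrix(A, list(m.row_labels), list(m.col_labels), "sinkhorn")
    imbalance = max(
        np.abs(A.sum(axis=1) - row_target).max(),
        np.abs(A.sum(axis=0) - col_target).max(),
    )
    raise RuntimeError(
        f"Sinkhorn-Knopp did not converge in {max_iter} iterations "
        f"(marginal imbalance {imbalance:.3e})"
    )
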