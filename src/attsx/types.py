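"""Core in-memory containers shared across the pipeline.

All spatial objects carry an explicit voxel-index -> world-coordinate
affine (4x4, voxel-center convention, 0-based indices).  Streamlines are
always stored in world coordinates; format-specific voxel conventions
(notably TRK's) are absorbed at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeGrid",
    "Tractogram",
    "LabeledMatrix",
    "ParcelAtlas",
    "CORTICAL_PARCELS",
    "SUBCORTICAL_PARCELS",
]

#: The seven prefrontal injection-group parcels.
CORTICAL_PARCELS = ("OFC", "dlPFC", "vlPFC", "dmPFC", "dACC", "vACC", "premotor")

#: The six subcortical target parcels.
SUBCORTICAL_PARCELS = ("STN", "SN", "RN", "MD", "VL", "VTA")


@dataclass
class VolumeGrid:
    """A 3D scalar or integer grid with a voxel->world affine.

    Houses both tracer-load volumes (the axonal "conductivity" sigma)
    and integer parcel-label volumes.
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_unit: str = "voxel"  # voxel | mm | um

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        if any(s < 2 for s in self.values.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Length of one voxel along each axis, from the affine columns."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (ijk @ self.affine[:3, :3].T) + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (xyz @ inv[:3, :3].T) + inv[:3, 3]


@dataclass
class Tractogram:
    """A set of 3D polylines in world coordinates."""

    streamlines: list  # list of (n_i, 3) float arrays, n_i >= 2
    reference_affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    provenance: str = "synthetic"  # atts | dmri | synthetic
    grid_shape: tuple | None = None  # reference grid dims, needed for TRK headers

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for i, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError(f"streamline {i} is not an (n,3) array")
            if s.shape[0] < 2:
                raise ValueError(f"streamline {i} has fewer than 2 points")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
        self.reference_affine = np.asarray(self.reference_affine, dtype=float)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class LabeledMatrix:
    """Nonnegative connectivity matrix with parcel-name labels.

    ``normalization`` records whether the values are raw measurements
    or a Sinkhorn-balanced profile.
    """

    values: np.ndarray
    row_labels: list
    col_labels: list
    normalization: str = "raw"  # raw | sinkhorn

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_labels = list(self.row_labels)
        self.col_labels = list(self.col_labels)
        if self.values.ndim != 2:
            raise ValueError("matrix values must be 2D")
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("matrix contains negative values")
        if self.normalization not in ("raw", "sinkhorn"):
            raise ValueError(f"unknown normalization tag {self.normalization!r}")

    def loc(self, row: str, col: str) -> float:
        return float(self.values[self.row_labels.index(row), self.col_labels.index(col)])

    def copy(self) -> "LabeledMatrix":
        return LabeledMatrix(
            self.values.copy(), list(self.row_labels), list(self.col_labels), self.normalization
        )


@dataclass
class ParcelAtlas:
    """Integer label grid plus a label table with cortical/subcortical roles."""

    labels: VolumeGrid
    table: dict  # label id -> (name, role), role in {"cortical", "subcortical"}

    def __post_init__(self) -> None:
        if not np.issubdtype(self.labels.values.dtype, np.integer):
            raise ValueError("atlas label grid must be integer-typed")
        present = set(np.unique(self.labels.values)) - {0}
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"grid labels missing from table: {sorted(missing)}")
        names = [name for name, _ in self.table.values()]
        if len(set(names)) != len(names):
            raise ValueError("parcel names must be unique")
        for label, (name, role) in self.table.items():
            if role not in ("cortical", "subcortical"):
                raise ValueError(f"parcel {name!r}: unknown role {role!r}")

    @property
    def names(self) -> list:
        return [name for name, _ in self.table.values()]

    def names_by_role(self, role: str) -> list:
        return [name for name, r in self.table.values() if r == role]

    def id_of(self, name: str) -> int:
        for label, (nm, _) in self.table.items():
            if nm == name:
                return label
        raise KeyError(f"unknown parcel name {name!r}")

    def mask(self, name: str) -> np.ndarray:
        return self.labels.values == self.id_of(name)
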