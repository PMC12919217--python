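"""Synthetic inputs with known ground truth.

Every generator here returns the latent truth (centerlines, planted
counts, effect edge, branch weights) alongside the data, so recovery
tests downstream are self-contained.  All generators are deterministic
given their seed.

The phantoms emulate the statistical structure the analysis assumes,
not anatomy: tracer volumes are noisy Gaussian tubes around known
centerlines from a point injection; the toy atlas places the seven
prefrontal parcels (OFC, dlPFC, vlPFC, dmPFC, dACC, vACC, premotor) as
blocks in an outer cortical shell and the six subcortical targets (STN,
SN, RN, MD, VL, VTA) in the core, the VTA as a radius-2 sphere;
tractograms realize an exact planted parcel-pair count matrix; cohorts
are per-subject connectivity matrices with i.i.d. Gaussian edge noise
and an optional single-edge group effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .connectivity import InjectionRecord
from .types import (
    CORTICAL_PARCELS,
    SUBCORTICAL_PARCELS,
    LabeledMatrix,
    ParcelAtlas,
    Tractogram,
    VolumeGrid,
)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_tube_phantom",
    "make_toy_atlas",
    "make_planted_tractogram",
    "make_cohort",
    "make_injection_cohort",
    "TABLE_INJECTION_COUNTS",
]

#: Default per-parcel injection counts of the marmoset tracer collection.
TABLE_INJECTION_COUNTS = {
    "OFC": 6,
    "dlPFC": 29,
    "vlPFC": 2,
    "dmPFC": 3,
    "dACC": 3,
    "vACC": 3,
    "premotor": 5,
}


@dataclass
class PhantomSpec:
    """Recipe for a tube/branch tracer phantom.

    sigma = background + sum_k weight_k * peak * exp(-d_k^2 / (2 radius^2))
            + N(0, noise_sd), clipped at 0,

    where d_k is the distance to centerline k.  The Gaussian tube profile
    keeps sigma smooth, avoiding discretization artifacts in the PDE.
    """

    shape: tuple = (48, 48, 48)
    centerlines: list = field(default_factory=list)  # list of (n,3) voxel-coord polylines
    tube_radius: float = 1.5
    peak_intensity: float = 1.0
    branch_weights: list | None = None
    background: float = 0.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tube_radius <= 0 or self.peak_intensity <= 0:
            raise ValueError("tube_radius and peak_intensity must be > 0")
        if self.branch_weights is None:
            self.branch_weights = [1.0] * len(self.centerlines)
        if len(self.branch_weights) != len(self.centerlines):
            raise ValueError("one branch weight per centerline required")
        if any(w <= 0 for w in self.branch_weights):
            raise ValueError("branch weights must be strictly positive")
        dims = np.asarray(self.shape)
        for k, cl in enumerate(self.centerlines):
            cl = np.asarray(cl, dtype=float)
            if np.any(cl < 0) or np.any(cl > dims - 1):
                raise ValueError(f"centerline {k} exits the grid {self.shape}")


@dataclass
class CohortSpec:
    """Recipe for a two-group per-subject connectivity cohort.

    Both groups draw baseline + N(0, noise_sd^2) per entry (clipped at
    0); the second group additionally receives ``effect_delta`` at
    ``effect_edge``.  n_per_group defaults to 12 subjects.
    """

    baseline_matrix: LabeledMatrix = None  # type: ignore[assignment]
    effect_edge: tuple = ("vlPFC", "STN")
    effect_delta: float = 0.0
    noise_sd: float = 0.02
    n_per_group: int = 12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        r, c = self.effect_edge
        if r not in self.baseline_matrix.row_labels or c not in self.baseline_matrix.col_labels:
            raise ValueError(f"effect edge {self.effect_edge} not in baseline matrix")


def _densify(polyline: np.ndarray, spacing: float = 0.25) -> np.ndarray:
    """Resample a polyline at roughly uniform arc-length spacing."""
    pts = np.asarray(polyline, dtype=float)
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        length = np.linalg.norm(seg)
        n = max(int(np.ceil(length / spacing)), 1)
        for t in np.linspace(0, 1, n + 1)[1:]:
            out.append(a + t * seg)
    return np.asarray(out)


def make_tube_phantom(spec: PhantomSpec):
    """Build a tracer phantom; returns (sigma volume, injection voxel, centerlines)."""
    rng = np.random.default_rng(spec.rng_seed)
    grid = np.indices(spec.shape).reshape(3, -1).T.astype(float)
    sigma = np.full(int(np.prod(spec.shape)), float(spec.background))
    for cl, w in zip(spec.centerlines, spec.branch_weights):
        tree = cKDTree(_densify(np.asarray(cl, dtype=float)))
        d, _ = tree.query(grid, workers=-1)
        sigma += w * spec.peak_intensity * np.exp(-(d**2) / (2 * spec.tube_radius**2))
    if spec.noise_sd > 0:
        sigma += rng.normal(0.0, spec.noise_sd, size=sigma.shape)
    sigma = np.clip(sigma, 0.0, None).reshape(spec.shape)
    if spec.centerlines:
        injection = tuple(int(round(x)) for x in np.asarray(spec.centerlines[0])[0])
    else:
        injection = tuple(s // 2 for s in spec.shape)
    return VolumeGrid(sigma), injection, [np.asarray(c, float) for c in spec.centerlines]


# geometry of the toy atlas: cortical blocks at grid corners, subcortical
# blocks offset from the grid center along the axes, VTA a radius-2 sphere
_CORNER_OF = {
    "OFC": (0, 0, 0),
    "dlPFC": (1, 0, 0),
    "vlPFC": (0, 1, 0),
    "dmPFC": (1, 1, 0),
    "dACC": (0, 0, 1),
    "vACC": (1, 0, 1),
    "premotor": (0, 1, 1),
}
_CORE_OFFSET = {
    "STN": (-7, 0, 0),
    "SN": (7, 0, 0),
    "RN": (0, -7, 0),
    "MD": (0, 7, 0),
    "VL": (0, 0, -7),
    "VTA": (0, 0, 7),
}


def make_toy_atlas(shape: tuple = (48, 48, 48)) -> ParcelAtlas:
    """13-parcel toy atlas: 7 cortical shell blocks + 6 subcortical core blocks.

    Cortical parcels are 7x7x7 blocks at seven corners of the grid
    (margin 5); subcortical parcels are 5x5x5 blocks at +-7 voxels from
    the grid center along each axis, except the VTA, a radius-2 sphere.
    All parcels are pairwise disjoint and label 0 is background.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 42:
        raise ValueError(f"shape {shape} too small for the toy atlas (need >= 42 per axis)")
    labels = np.zeros(shape, dtype=np.int32)
    table: dict = {}
    dims = np.asarray(shape)
    for i, name in enumerate(CORTICAL_PARCELS, start=1):
        corner = _CORNER_OF[name]
        sl = []
        for ax in range(3):
            if corner[ax] == 0:
                sl.append(slice(5, 12))
            else:
                sl.append(slice(dims[ax] - 12, dims[ax] - 5))
        labels[tuple(sl)] = i
        table[i] = (name, "cortical")
    center = dims // 2
    ii, jj, kk = np.indices(shape)
    for i, name in enumerate(SUBCORTICAL_PARCELS, start=8):
        pos = center + np.asarray(_CORE_OFFSET[name])
        if name == "VTA":
            # sphere with 2-voxel radius, mirroring the MNI-sphere VTA definition
            d2 = (ii - pos[0]) ** 2 + (jj - pos[1]) ** 2 + (kk - pos[2]) ** 2
            labels[d2 <= 4] = i
        else:
            sl = tuple(slice(int(p) - 2, int(p) + 3) for p in pos)
            labels[sl] = i
        table[i] = (name, "subcortical")
    return ParcelAtlas(VolumeGrid(labels), table)


def _route(
    rng: np.random.Generator,
    atlas: ParcelAtlas,
    id_a: int,
    id_b: int,
    max_tries: int = 200,
) -> np.ndarray:
    """Find a polyline visiting parcels a and b and no other parcel.

    Endpoints are random voxels inside each parcel; the path is a
    quadratic Bezier through a jittered midpoint, validated against the
    label grid and re-drawn on failure.
    """
    grid = atlas.labels.values
    dims = np.asarray(grid.shape)
    vox_a = np.argwhere(grid == id_a)
    vox_b = np.argwhere(grid == id_b)
    for trial in range(max_tries):
        p0 = vox_a[rng.integers(len(vox_a))].astype(float)
        p2 = vox_b[rng.integers(len(vox_b))].astype(float)
        mid = 0.5 * (p0 + p2)
        if trial > 0:
            mid = mid + rng.uniform(-6, 6, size=3)
        mid = np.clip(mid, 1, dims - 2)
        t = np.linspace(0, 1, 121)[:, None]
        path = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * mid + t**2 * p2
        path = np.clip(path, 0, dims - 1)
        vox = np.rint(path).astype(int)
        hit = set(np.unique(grid[vox[:, 0], vox[:, 1], vox[:, 2]]))
        if hit <= {0, id_a, id_b} and id_a in hit and id_b in hit:
            return path
    raise RuntimeError(
        f"could not route a streamline between parcels {id_a} and {id_b}"
    )


def make_planted_tractogram(
    atlas: ParcelAtlas, counts: LabeledMatrix, rng_seed: int = 0
) -> Tractogram:
    """Realize an integer parcel-pair count matrix as a tractogram.

    For each pair (a, b), exactly counts[a, b] streamlines visit parcel
    a and parcel b and no other labeled parcel, so streamline counting
    recovers ``counts`` exactly.
    """
    rng = np.random.default_rng(rng_seed)
    if not np.allclose(counts.values, np.rint(counts.values)):
        raise ValueError("planted counts must be integers")
    aff = atlas.labels.affine
    streamlines = []
    for i, a in enumerate(counts.row_labels):
        for j, b in enumerate(counts.col_labels):
            n = int(round(counts.values[i, j]))
            if n == 0 or a == b:
                continue
            id_a, id_b = atlas.id_of(a), atlas.id_of(b)
            for _ in range(n):
                path = _route(rng, atlas, id_a, id_b)
                world = path @ aff[:3, :3].T + aff[:3, 3]
                streamlines.append(world)
    return Tractogram(
        streamlines, reference_affine=aff, provenance="synthetic",
        grid_shape=atlas.labels.shape,
    )


def make_cohort(spec: CohortSpec) -> list:
    """Draw a two-group cohort of per-subject connectivity matrices.

    Returns a list of (subject_id, group, LabeledMatrix) with groups
    "HC" and "OCD"; the OCD group carries the planted effect.
    """
    rng = np.random.default_rng(spec.rng_seed)
    base = spec.baseline_matrix
    ei = base.row_labels.index(spec.effect_edge[0])
    ej = base.col_labels.index(spec.effect_edge[1])
    out = []
    for group, delta in (("HC", 0.0), ("OCD", spec.effect_delta)):
        for s in range(spec.n_per_group):
            noise = rng.normal(0.0, spec.noise_sd, size=base.values.shape)
            vals = base.values + noise
            vals[ei, ej] += delta
            vals = np.clip(vals, 0.0, None)
            out.append(
                (
                    f"{group}-{s:02d}",
                    group,
                    LabeledMatrix(vals, list(base.row_labels), list(base.col_labels),
                                  base.normalization),
                )
            )
    return out


def _route_branch(
    rng: np.random.Generator,
    src: np.ndarray,
    target: str,
    center: np.ndarray,
    shape: tuple,
    mask_trees: dict,
    clearance: float = 4.0,
    max_tries: int = 12,
) -> np.ndarray:
    """Centerline from a cortical source to a subcortical target that
    keeps ``clearance`` voxels away from every other subcortical mask.

    A straight corridor from a cortical block to a far-side target can
    graze an intervening target mask and contaminate its mean-signal
    readout, so the mid-waypoint is pushed outward (away from the core
    center) with increasing strength until the densified polyline clears
    every non-target mask; the best route found is kept otherwise.
    The terminal segment extends 3 voxels beyond the target center so
    the tube covers the target mask evenly.
    """
    dims = np.asarray(shape, dtype=float)
    tgt = (center + np.asarray(_CORE_OFFSET[target])).astype(float)
    others = [t for name, t in mask_trees.items() if name != target]
    best, best_clear = None, -np.inf
    for trial in range(max_tries):
        mid0 = 0.5 * (src + tgt)
        outward = mid0 - center
        norm = np.linalg.norm(outward)
        outward = outward / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        push = 2.0 * trial * outward
        mid = np.clip(mid0 + push + rng.uniform(-2, 2, 3), 1, dims - 2)
        direction = tgt - mid
        direction /= np.linalg.norm(direction)
        end = np.clip(tgt + 3.0 * direction, 0, dims - 1)
        line = np.array([src, mid, tgt, end])
        pts = _densify(line, spacing=0.5)
        clear = min(t.query(pts, workers=-1)[0].min() for t in others)
        if clear >= clearance:
            return line
        if clear > best_clear:
            best, best_clear = line, clear
    return best


#: Branch-weight ladder: each injection's subcortical targets get a random
#: permutation (per cortical parcel) of these weights.  The factor-2 spacing
#: dominates the mask-geometry differences between cube and sphere targets,
#: so the planted ordering is recoverable from raw mean signals.
_WEIGHT_LADDER = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])


def make_injection_cohort(
    atlas: ParcelAtlas,
    counts_per_parcel: dict | None = None,
    rng_seed: int = 0,
    tube_radius: float = 1.0,
    noise_sd: float = 0.01,
):
    """Generate one tube-phantom tracer volume per injection.

    Each injection is seeded at a random voxel of its cortical parcel
    and branches to every subcortical target, the branches Gaussian
    tubes weighted by the parcel's latent weight vector (shared by all
    injections of that parcel and returned as ground truth).

    Returns (records, truth) where records is a list of
    :class:`InjectionRecord` and truth maps cortical parcel ->
    {subcortical name: weight}.
    """
    if counts_per_parcel is None:
        counts_per_parcel = dict(TABLE_INJECTION_COUNTS)
    rng = np.random.default_rng(rng_seed)
    shape = atlas.labels.shape
    cortical = atlas.names_by_role("cortical")
    sub_names = atlas.names_by_role("subcortical")
    for parcel, n in counts_per_parcel.items():
        if parcel not in cortical:
            raise KeyError(f"unknown cortical parcel {parcel!r}")
        if n < 0:
            raise ValueError("injection counts must be >= 0")
    grid = atlas.labels.values
    center = np.asarray(shape) // 2
    # one KD-tree per target mask, for branch-route clearance checks
    mask_trees = {
        name: cKDTree(np.argwhere(grid == atlas.id_of(name))) for name in sub_names
    }
    truth: dict = {}
    records: list = []
    for parcel in cortical:
        n_inj = counts_per_parcel.get(parcel, 0)
        if n_inj == 0:
            continue
        weights = _WEIGHT_LADDER[rng.permutation(len(sub_names))[: len(sub_names)]]
        truth[parcel] = dict(zip(sub_names, (float(w) for w in weights)))
        vox_src = np.argwhere(grid == atlas.id_of(parcel))
        for k in range(n_inj):
            src = vox_src[rng.integers(len(vox_src))].astype(float)
            centerlines = [
                _route_branch(rng, src, name, center, shape, mask_trees)
                for name in sub_names
            ]
            spec = PhantomSpec(
                shape=shape,
                centerlines=centerlines,
                tube_radius=tube_radius,
                peak_intensity=1.0,
                branch_weights=[truth[parcel][n] for n in sub_names],
                background=0.0,
                noise_sd=noise_sd,
                rng_seed=int(rng.integers(2**31 - 1)),
            )
            vol, _, _ = make_tube_phantom(spec)
            records.append(InjectionRecord(volume=vol, parcel=parcel,
                                           subject_id=f"{parcel}-{k:02d}"))
    return records, truth
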