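"""Screened-Poisson flux fields from orientation-free tracer maps.

Anterograde tracer load maps record how much axonal signal each voxel
carries but not which way the axons run.  Treating the tracer load
sigma(r) as an electrical conductivity and the injection site as a unit
current source, the potential phi solves the screened Poisson problem

    (-div(sigma_eff grad) + alpha) phi = delta_{injection},

with zero-flux (Neumann) boundaries.  The screening term alpha*phi is a
small leakage current drawn uniformly from the volume; it makes the
operator strictly positive definite and gives phi an exponential decay
length sqrt(sigma/alpha).  The flux j = sigma_eff * grad(phi), oriented
away from the injection, is a proxy for the mean axonal direction and is
what the streamline tracker integrates.

The operator is discretized on the voxel grid as a conservative 7-point
stencil with harmonic-mean face conductivities (finite-volume form), so
that the discrete divergence theorem holds exactly: for the whole grid,
alpha * sum(phi) = total injected current = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .types import VolumeGrid

__all__ = [
    "ScreenedPoissonConfig",
    "PotentialField",
    "FluxField",
    "ScreenedPoissonOperator",
    "assemble_operator",
    "solve_potential",
    "compute_flux",
]


@dataclass
class ScreenedPoissonConfig:
    """Tunable parameters of the screened-Poisson solve.

    alpha
        Leakage coefficient (1/voxel^2 units).  Sets the decay length of
        the potential, sqrt(sigma_mean/alpha).  If None, it is chosen at
        solve time so the decay length is ~10 voxels.
    sigma_floor
        Small conductivity added everywhere so the operator stays
        irreducible where tracer is absent.  If None, 1e-4 * max(sigma).
    rel_tol
        Solver relative-residual tolerance.
    max_iter
        Iteration cap for the Krylov solver.
    """

    alpha: float | None = None
    sigma_floor: float | None = None
    rel_tol: float = 1e-8
    max_iter: int = 20000

    def __post_init__(self) -> None:
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.sigma_floor is not None and self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be > 0")
        if not (0 < self.rel_tol < 1):
            raise ValueError("rel_tol must lie in (0, 1)")

    def resolve(self, sigma: np.ndarray) -> "ScreenedPoissonConfig":
        """Fill the data-dependent defaults for a given conductivity grid."""
        smax = float(np.max(sigma))
        floor = self.sigma_floor if self.sigma_floor is not None else 1e-4 * max(smax, 1.0)
        sigma_eff_mean = float(np.mean(sigma)) + floor
        alpha = self.alpha if self.alpha is not None else sigma_eff_mean / 10.0**2
        return ScreenedPoissonConfig(
            alpha=alpha, sigma_floor=floor, rel_tol=self.rel_tol, max_iter=self.max_iter
        )


@dataclass
class PotentialField:
    """Solved potential phi with the configuration and source that produced it."""

    values: np.ndarray
    config: ScreenedPoissonConfig
    injection: tuple
    residual: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential contains non-finite values")


@dataclass
class FluxField:
    """Per-voxel 3-vector flux, oriented away from the injection.

    components has shape (nx, ny, nz, 3); the normal component on each
    boundary face is zero by the Neumann condition.
    """

    components: np.ndarray
    injection: tuple | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 4 or self.components.shape[-1] != 3:
            raise ValueError("flux components must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.components)):
            raise ValueError("flux contains non-finite values")

    @property
    def grid_shape(self) -> tuple:
        return self.components.shape[:3]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.components, axis=-1)


class ScreenedPoissonOperator(LinearOperator):
    """Matrix-free SPD operator L = -div(sigma_eff grad) + alpha I.

    7-point stencil, harmonic-mean face conductivities, Neumann
    boundaries.  Applied to a constant c it returns alpha*c everywhere.
    """

    def __init__(self, sigma: VolumeGrid, config: ScreenedPoissonConfig):
        vals = np.asarray(sigma.values, dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("sigma must be nonnegative and finite")
        self.config = config.resolve(vals)
        self.shape3 = vals.shape
        sigma_eff = vals + self.config.sigma_floor
        # harmonic mean across each interior face, one array per axis
        self.face_w = []
        for ax in range(3):
            a = np.moveaxis(sigma_eff, ax, 0)
            w = 2.0 * a[:-1] * a[1:] / (a[:-1] + a[1:])
            self.face_w.append(np.moveaxis(w, 0, ax))
        n = int(np.prod(self.shape3))
        super().__init__(dtype=np.float64, shape=(n, n))
        # diagonal (for Jacobi preconditioning)
        diag = np.full(self.shape3, self.config.alpha)
        for ax, w in enumerate(self.face_w):
            pad_lo = [(0, 0)] * 3
            pad_lo[ax] = (1, 0)
            pad_hi = [(0, 0)] * 3
            pad_hi[ax] = (0, 1)
            diag += np.pad(w, pad_lo) + np.pad(w, pad_hi)
        self.diagonal = diag

    def apply_grid(self, phi: np.ndarray) -> np.ndarray:
        out = self.config.alpha * phi
        for ax, w in enumerate(self.face_w):
            p = np.moveaxis(phi, ax, 0)
            wv = np.moveaxis(w, ax, 0)
            flux = wv * (p[1:] - p[:-1])  # flux across interior faces
            o = np.moveaxis(out, ax, 0)
            o[:-1] -= flux
            o[1:] += flux
        return out

    def _matvec(self, x: np.ndarray) -> np.ndarray:
        return self.apply_grid(x.reshape(self.shape3)).ravel()


def assemble_operator(sigma: VolumeGrid, config: ScreenedPoissonConfig | None = None) -> ScreenedPoissonOperator:
    """Build the matrix-free screened-Poisson operator for a tracer grid."""
    return ScreenedPoissonOperator(sigma, config or ScreenedPoissonConfig())


def solve_potential(
    sigma: VolumeGrid,
    injection: tuple,
    config: ScreenedPoissonConfig | None = None,
) -> PotentialField:
    """Solve L phi = delta_{injection} (unit source at one voxel).

    Conjugate gradients with Jacobi preconditioning; the operator is SPD
    so CG is the natural Krylov choice.  Raises on non-convergence.
    """
    op = assemble_operator(sigma, config)
    injection = tuple(int(i) for i in injection)
    if len(injection) != 3 or any(
        not (0 <= injection[ax] < op.shape3[ax]) for ax in range(3)
    ):
        raise ValueError(f"injection {injection} outside grid {op.shape3}")
    b = np.zeros(op.shape3)
    b[injection] = 1.0
    b_flat = b.ravel()
    inv_diag = 1.0 / op.diagonal.ravel()
    M = LinearOperator(op.shape, matvec=lambda x: inv_diag * x, dtype=np.float64)
    cfg = op.config
    x, info = cg(op, b_flat, rtol=cfg.rel_tol, atol=0.0, maxiter=cfg.max_iter, M=M)
    residual = float(np.linalg.norm(op @ x - b_flat) / np.linalg.norm(b_flat))
    if info != 0 or residual > cfg.rel_tol * 10:
        raise RuntimeError(
            f"screened-Poisson solve did not converge in {cfg.max_iter} iterations "
            f"(achieved relative residual {residual:.3e})"
        )
    return PotentialField(
        values=x.reshape(op.shape3), config=cfg, injection=injection, residual=residual
    )


def compute_flux(sigma: VolumeGrid, phi: PotentialField) -> FluxField:
    """Flux j = sigma_eff * grad(phi), oriented away from the injection.

    The gradient is central-difference in the interior and one-sided at
    the boundary, after which the boundary-normal component is forced to
    zero (the Neumann condition).  phi peaks at the source, so -grad(phi)
    points away from it.
    """
    vals = np.asarray(sigma.values, dtype=float)
    if vals.shape != phi.values.shape:
        raise ValueError(f"sigma shape {vals.shape} != phi shape {phi.values.shape}")
    cfg = phi.config.resolve(vals)
    sigma_eff = vals + cfg.sigma_floor
    grads = np.gradient(phi.values, edge_order=1)
    comps = np.stack([-sigma_eff * g for g in grads], axis=-1)
    # zero the boundary-normal component on each face
    comps[0, :, :, 0] = 0.0
    comps[-1, :, :, 0] = 0.0
    comps[:, 0, :, 1] = 0.0
    comps[:, -1, :, 1] = 0.0
    comps[:, :, 0, 2] = 0.0
    comps[:, :, -1, 2] = 0.0
    return FluxField(components=comps, injection=phi.injection)
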