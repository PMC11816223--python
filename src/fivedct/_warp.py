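"""Shared warping primitives: trilinear sampling and fixed-point inversion.

All volumes are indexed ``[x, y, z]`` with z the craniocaudal axis.  Voxel
fields of 3-vectors have shape ``(nx, ny, nz, 3)`` and are expressed in mm in
the world frame; positions handed to the samplers are in *index* coordinates
(world = origin + index * voxel_size, axis-aligned grids only).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

AIR_HU = -1000.0


def grid_points(shape: tuple[int, int, int]) -> np.ndarray:
    """Index coordinates of every voxel, shape (nx, ny, nz, 3), float64."""
    axes = [np.arange(n, dtype=float) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def sample_scalar(field: np.ndarray, pts: np.ndarray, cval: float = 0.0,
                  mode: str = "constant") -> np.ndarray:
    """Trilinear sample of a scalar grid at index-coordinate points (..., 3)."""
    coords = [pts[..., k] for k in range(3)]
    return map_coordinates(field, coords, order=1, mode=mode, cval=cval,
                           prefilter=False)


def sample_vector(field: np.ndarray, pts: np.ndarray, cval: float = 0.0,
                  mode: str = "constant") -> np.ndarray:
    """Trilinear sample of a (nx, ny, nz, 3) vector field; returns (..., 3)."""
    return np.stack([sample_scalar(field[..., k], pts, cval, mode) for k in range(3)],
                    axis=-1)


def invert_model_map(
    alpha: np.ndarray,
    beta: np.ndarray,
    A_out,
    Adot_out,
    voxel_size: np.ndarray,
    const: np.ndarray | None = None,
    points: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
    tol: float = 0.05,
    max_iter: int = 40,
    omega: float = 0.5,
) -> tuple[np.ndarray, float, int]:
    """Invert the motion map ``phi(x0) = x0 + alpha(x0)*A + beta(x0)*Adot + c(x0)``.

    Finds, for every output voxel x, the source position psi(x) such that
    ``phi(psi) = x``, by under-relaxed fixed-point iteration
    ``psi <- (1 - omega) psi + omega (x - u(psi))`` (the damping suppresses
    period-2 oscillation where the field gradient approaches one).  The
    amplitude/rate pair belongs to the *output* slice (its acquisition time),
    so ``A_out``/``Adot_out`` may be scalars (a phase image) or length-nz
    arrays (a helical scan with one tag per slice).

    Returns (psi in index coordinates, achieved max update in mm, iterations).
    """
    voxel = np.asarray(voxel_size, dtype=float)
    if points is None:
        if shape is None:
            shape = alpha.shape[:3]
        points = grid_points(shape)
    nz = points.shape[2]
    a = np.broadcast_to(np.asarray(A_out, dtype=float), (nz,)) if np.ndim(A_out) else np.full(nz, float(A_out))
    b = np.broadcast_to(np.asarray(Adot_out, dtype=float), (nz,)) if np.ndim(Adot_out) else np.full(nz, float(Adot_out))
    a = a.reshape(1, 1, nz, 1)
    b = b.reshape(1, 1, nz, 1)

    psi = points.copy()
    achieved = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        u = sample_vector(alpha, psi) * a + sample_vector(beta, psi) * b
        if const is not None:
            u = u + sample_vector(const, psi)
        step = (points - u / voxel) - psi
        achieved = float(np.max(np.abs(step * voxel)))
        psi = psi + omega * step
        if achieved < tol:
            break
    return psi, achieved, it


def pull_volume(volume: np.ndarray, psi: np.ndarray, fill: float = AIR_HU) -> np.ndarray:
    """Resample ``volume`` at source positions psi (index coords)."""
    return sample_scalar(np.asarray(volume, dtype=float), psi, cval=fill)


def invert_displacement_field(
    u_mm: np.ndarray,
    voxel_size: np.ndarray,
    tol: float = 0.05,
    max_iter: int = 40,
    omega: float = 0.5,
) -> tuple[np.ndarray, float, int]:
    """Fixed-point inverse of a displacement field on its own grid.

    Given u with ``phi(x) = x + u(x)`` (mm, world frame), returns v with
    ``phi^{-1}(y) = y + v(y)`` such that ``u(y + v(y)) + v(y) ~ 0``.
    The update is under-relaxed by ``omega`` to damp oscillation where the
    field gradient approaches one.  Returns (v in mm, achieved max
    composition residual in mm, iterations).
    """
    voxel = np.asarray(voxel_size, dtype=float)
    pts = grid_points(u_mm.shape[:3])
    v = -u_mm.astype(float)
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # nearest extension: preimages just outside the grid see the edge field
        u_at = sample_vector(u_mm, pts + v / voxel, mode="nearest")
        residual = float(np.max(np.abs(u_at + v)))
        if residual < tol:
            break
        v = v - omega * (v + u_at)
    return v, residual, it
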