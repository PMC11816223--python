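"""Phase-image reconstruction from the fitted motion model.

A phase image at breathing state (A, Adot) is the reference volume deformed
by the model field: the forward map ``phi(x0) = x0 + u(x0)`` is inverted by
fixed-point iteration and the reference is pulled back through the inverse,
so intensities are always the reference scan's.  The same machinery, driven
slice-by-slice with each slice's acquired amplitude and rate, regenerates
the original helical scans for the workflow's self-check ("original scan
reconstruction").  Voxel-wise maxima over the 8 phase images give the MIP;
over all N acquired scans, the MEGA-MIP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _warp
from .errors import GeometryError, SyncError
from .model import MotionModel, predict_displacement
from .registration import DVF
from .surrogate import PhaseSpec

AIR_HU = -1000.0


@dataclass
class PhaseImageSet:
    """The eight model-generated percentile-amplitude volumes."""

    volumes: dict[str, np.ndarray]  # keyed by phase label, reference grid
    affine: np.ndarray
    phase_spec: PhaseSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.volumes) != 8:
            raise ValueError(f"phase set needs 8 volumes, got {len(self.volumes)}")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise GeometryError("phase volumes do not share one grid")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.volumes[label]

    def as_list(self) -> list[np.ndarray]:
        return [self.volumes[e.label] for e in self.phase_spec]


def invert_field(dvf: DVF, voxel_size, tol: float = 0.05, max_iter: int = 40) -> DVF:
    """Fixed-point inverse of a displacement field.

    Iterates ``v <- -u(x + v)`` until the composition residual
    ``max |u(x + v) + v|`` drops below ``tol`` mm.  Non-convergence emits a
    warning and reports the achieved residual instead of raising.
    """
    v, residual, iters = _warp.invert_displacement_field(
        dvf.disp, np.asarray(voxel_size, float), tol=tol, max_iter=max_iter
    )
    if residual >= tol:
        warnings.warn(
            f"field inversion stopped at residual {residual:.3f} mm "
            f"after {iters} iterations (tolerance {tol} mm)",
            stacklevel=2,
        )
    return DVF(disp=v, source=dvf.target, target=dvf.source, affine=dvf.affine,
               meta={"inverse_of": (dvf.source, dvf.target),
                     "achieved_residual_mm": residual, "iterations": iters})


def reconstruct_phase(
    model: MotionModel,
    A: float,
    Adot: float,
    reference_volume: np.ndarray,
    tol: float = 0.05,
) -> np.ndarray:
    """Deform the reference volume to breathing state (A, Adot)."""
    fwd = predict_displacement(model, A, Adot)
    inv = invert_field(fwd, model.voxel_size, tol=tol)
    pts = _warp.grid_points(model.shape) + inv.disp / model.voxel_size
    return _warp.pull_volume(np.asarray(reference_volume, dtype=float), pts)


def reconstruct_phase_set(
    model: MotionModel,
    spec: PhaseSpec,
    reference_volume: np.ndarray,
    tol: float = 0.05,
) -> PhaseImageSet:
    """All eight phase images from the phase spec."""
    volumes = {
        e.label: reconstruct_phase(model, e.A, e.Adot, reference_volume, tol=tol)
        for e in spec
    }
    return PhaseImageSet(volumes=volumes, affine=model.affine, phase_spec=spec,
                         meta={"n_obs": model.n_obs})


def reconstruct_original_scan(
    model: MotionModel,
    scan,
    tags: dict[int, tuple[np.ndarray, np.ndarray]],
    reference_volume: np.ndarray,
    tol: float = 0.05,
) -> np.ndarray:
    """Regenerate an acquired helical scan from the reference image.

    Each output slice is the reference deformed at that slice's (A, Adot);
    the per-slice states enter the fixed-point inversion directly, so the
    assembled volume is consistent with the slice-by-slice acquisition.
    """
    if scan.index not in tags:
        raise SyncError(f"no slice tags for scan {scan.index}")
    A, Adot = tags[scan.index]
    if A is None or len(A) != scan.n_slices:
        raise SyncError(f"tags for scan {scan.index} do not cover its slices")
    # fold the per-voxel reference state into a constant offset field
    const = -(model.alpha * model.A_ref[None, None, :, None]
              + model.beta * model.Adot_ref[None, None, :, None])
    psi, achieved, iters = _warp.invert_model_map(
        model.alpha, model.beta, np.asarray(A, float), np.asarray(Adot, float),
        model.voxel_size, const=const, shape=model.shape, tol=tol,
    )
    if achieved >= tol:
        warnings.warn(
            f"scan {scan.index} reconstruction inversion stopped at "
            f"{achieved:.3f} mm after {iters} iterations",
            stacklevel=2,
        )
    return _warp.pull_volume(np.asarray(reference_volume, dtype=float), psi)


def max_intensity_projection(volumes: list[np.ndarray]) -> np.ndarray:
    """Voxel-wise maximum across volumes on a common grid.

    Applied to the 8 phase images this is the MIP used for ITV contouring;
    applied to all acquired scans it is the MEGA-MIP.
    """
    if len(volumes) == 0:
        raise GeometryError("need at least one volume")
    shapes = {np.asarray(v).shape for v in volumes}
    if len(shapes) != 1:
        raise GeometryError(f"volumes on different grids: {shapes}")
    return np.maximum.reduce([np.asarray(v) for v in volumes])
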