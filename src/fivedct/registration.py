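"""Deformation-field abstraction between the reference and target scans.

The workflow treats deformable image registration (DIR) as a replaceable
component: phantom sessions get exact analytic fields from the ground-truth
motion parameters, while clinical sessions plug in any external DIR tool via
a command-template adapter.  Both produce the same internal `DVF` object —
a pull-from-reference displacement in mm, world frame, on the reference grid.

Green/magenta QA overlays (reference in green, deformed target in magenta;
aligned structures render gray) are provided for visual DIR review.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _warp
from .errors import RegistrationFailedError
from .session import ScanRecord

DEFAULT_WINDOW = (-1000.0, 300.0)  # HU-like display window


@dataclass
class DVF:
    """Displacement field mapping reference positions to target positions."""

    disp: np.ndarray  # (nx, ny, nz, 3), mm, world frame
    source: int  # reference scan index
    target: int
    affine: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValueError("displacement grid must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[:3]


def interp_slice_tags(tags: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-slice tag looked up at (possibly fractional, clipped) slice index.

    This is the single lookup convention shared by ground-truth field
    generation and model fitting: the amplitude a tissue element was imaged
    at belongs to the target-scan slice at its deformed z position.
    """
    nz = tags.shape[0]
    return np.interp(z, np.arange(nz), tags)


def ground_truth_dvf(
    phantom,
    reference: ScanRecord,
    target: ScanRecord,
    tol: float = 1e-12,
    max_iter: int = 50,
) -> DVF:
    """Analytic displacement field of a simulated scan pair.

    At each reference voxel the displacement is
    ``alpha_true * (A_t - A_r) + beta_true * (Adot_t - Adot_r)``, where the
    target tag is read at the deformed z position (solved by fixed-point
    iteration on the z component, which converges because within-scan
    amplitude variation per slice is small).
    """
    if phantom is None or not hasattr(phantom, "alpha_true"):
        raise RegistrationFailedError("ground-truth fields need a phantom session")
    if reference.index == target.index:
        return DVF(disp=np.zeros(phantom.grid_shape + (3,)),
                   source=reference.index, target=target.index,
                   affine=reference.affine)
    nz = phantom.grid_shape[2]
    vz = phantom.voxel_size[2]
    z_idx = np.arange(nz, dtype=float)
    a_ref = reference.A_true[None, None, :]
    b_ref = reference.Adot_true[None, None, :]
    alpha_z = phantom.alpha_true[..., 2]
    beta_z = phantom.beta_true[..., 2]

    dz = alpha_z * (target.A_true[None, None, :] - a_ref) + beta_z * (
        target.Adot_true[None, None, :] - b_ref
    )
    for _ in range(max_iter):
        zp = z_idx[None, None, :] + dz / vz
        a = interp_slice_tags(target.A_true, zp) - a_ref
        b = interp_slice_tags(target.Adot_true, zp) - b_ref
        dz_new = alpha_z * a + beta_z * b
        if np.max(np.abs(dz_new - dz)) < tol:
            dz = dz_new
            break
        dz = dz_new
    zp = z_idx[None, None, :] + dz / vz
    a = interp_slice_tags(target.A_true, zp) - a_ref
    b = interp_slice_tags(target.Adot_true, zp) - b_ref
    disp = phantom.alpha_true * a[..., None] + phantom.beta_true * b[..., None]
    return DVF(disp=disp, source=reference.index, target=target.index,
               affine=reference.affine, meta={"kind": "ground-truth"})


def ground_truth_dvfs(session) -> list[DVF]:
    """Ground-truth fields from the reference to every other scan."""
    ref = session.reference
    return [ground_truth_dvf(session.phantom, ref, s)
            for s in session.scans if not s.is_reference]


def register_external(
    reference: ScanRecord,
    target: ScanRecord,
    command_template: str,
    workdir: str | Path | None = None,
) -> DVF:
    """Run an external DIR tool and read back its displacement field.

    ``command_template`` is formatted with ``{reference}``, ``{target}`` and
    ``{output}`` NIfTI paths.  The tool must write a 4-D NIfTI displacement
    volume (nx, ny, nz, 3) or (nx, ny, nz, 1, 3) in mm, world frame,
    pull-from-reference convention.
    """
    import nibabel as nib

    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(ctx.name) if ctx else Path(workdir)
    try:
        ref_p, tgt_p, out_p = wd / "reference.nii", wd / "target.nii", wd / "dvf.nii"
        nib.save(nib.Nifti1Image(np.asarray(reference.volume, dtype=np.float32),
                                 reference.affine), ref_p)
        nib.save(nib.Nifti1Image(np.asarray(target.volume, dtype=np.float32),
                                 target.affine), tgt_p)
        cmd = command_template.format(reference=ref_p, target=tgt_p, output=out_p)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RegistrationFailedError(
                f"DIR adapter exited with {proc.returncode}",
                tool_output=proc.stdout + proc.stderr,
            )
        if not out_p.exists():
            raise RegistrationFailedError("DIR adapter wrote no output field",
                                          tool_output=proc.stdout + proc.stderr)
        try:
            data = np.asarray(nib.load(out_p).dataobj, dtype=float)
        except Exception as exc:
            raise RegistrationFailedError(f"cannot read DVF: {exc}") from exc
        if data.ndim == 5 and data.shape[3] == 1:
            data = data[:, :, :, 0, :]
        if data.ndim != 4 or data.shape[-1] != 3 or data.shape[:3] != reference.volume.shape:
            raise RegistrationFailedError(
                f"malformed displacement field of shape {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise RegistrationFailedError("displacement field contains non-finite values")
        return DVF(disp=data, source=reference.index, target=target.index,
                   affine=reference.affine, meta={"kind": "external", "command": cmd})
    finally:
        if ctx:
            ctx.cleanup()


def deform_target(target_volume: np.ndarray, dvf: DVF, voxel_size) -> np.ndarray:
    """Warp the target volume back onto the reference frame via the DVF."""
    pts = _warp.grid_points(dvf.shape) + dvf.disp / np.asarray(voxel_size, float)
    return _warp.pull_volume(np.asarray(target_volume, dtype=float), pts)


def _extract_plane(volume: np.ndarray, plane: str, index: int) -> np.ndarray:
    nx, ny, nz = volume.shape
    if plane == "coronal":
        if not 0 <= index < ny:
            raise IndexError(f"coronal slice {index} out of bounds for ny={ny}")
        sl = volume[:, index, :]
    elif plane in ("sagittal-left", "sagittal-right", "sagittal"):
        if not 0 <= index < nx:
            raise IndexError(f"sagittal slice {index} out of bounds for nx={nx}")
        sl = volume[index, :, :]
    else:
        raise ValueError(f"unknown plane {plane!r}")
    # display with the cranial direction up
    return sl.T[::-1]


def render_overlay(
    reference_volume: np.ndarray,
    deformed_target: np.ndarray,
    plane: str = "coronal",
    slice_index: int | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> np.ndarray:
    """Green/magenta alignment overlay of a single plane.

    Reference intensity drives the green channel; the deformed target drives
    red and blue (magenta).  Where the two agree the channels are equal and
    the pixel renders gray.  Returns an (H, W, 3) float image in [0, 1].
    """
    if slice_index is None:
        slice_index = (reference_volume.shape[1] // 2 if plane == "coronal"
                       else reference_volume.shape[0] // 2)
    lo, hi = window
    ref = np.clip((_extract_plane(reference_volume, plane, slice_index) - lo) / (hi - lo), 0, 1)
    tgt = np.clip((_extract_plane(deformed_target, plane, slice_index) - lo) / (hi - lo), 0, 1)
    rgb = np.empty(ref.shape + (3,))
    rgb[..., 0] = tgt
    rgb[..., 1] = ref
    rgb[..., 2] = tgt
    return rgb


def overlay_contact_sheet(session, dvfs: list[DVF], out_path: str | Path,
                          window=DEFAULT_WINDOW) -> Path:
    """One row per registered scan, three planes per row (coronal, right and
    left lung sagittal), saved as a PNG contact sheet."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ref = session.reference
    nx = ref.volume.shape[0]
    planes = [("coronal", None), ("sagittal-right", nx // 4), ("sagittal-left", 3 * nx // 4)]
    n = len(dvfs)
    fig, axes = plt.subplots(n, 3, figsize=(7.5, 2.2 * n), squeeze=False)
    by_index = {s.index: s for s in session.scans}
    for row, dvf in enumerate(dvfs):
        warped = deform_target(by_index[dvf.target].volume, dvf, ref.voxel_size)
        for col, (plane, idx) in enumerate(planes):
            img = render_overlay(ref.volume, warped, plane, idx, window)
            ax = axes[row][col]
            ax.imshow(img)
            ax.set_axis_off()
            if col == 0:
                ax.set_title(f"scan {dvf.target}", fontsize=7, loc="left")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=90)
    plt.close(fig)
    return out_path
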