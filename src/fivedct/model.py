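"""Per-voxel breathing-motion model: fit, prediction, residual diagnostics.

The model describes the position of the tissue at reference voxel X0 as

    X = X0 + alpha * A + beta * Adot

with voxel-specific 3-vector coefficients: ``alpha`` scales breathing
amplitude (mm per a.u.), ``beta`` scales breathing rate (mm per a.u./s).
Fitting is ordinary least squares per voxel and axis, with no intercept,
of DIR displacements against amplitude/rate deltas from the reference
scan's own slice tags — so predicting at the reference state returns an
exactly zero field.  The amplitude a displacement observation pairs with is
the target-scan slice tag at the voxel's *deformed* z position (the slice
the tissue was actually imaged in).

Rank-deficient voxels (e.g., no amplitude variation across scans) never
raise: the unidentifiable coefficient is set to zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError
from .registration import DVF, interp_slice_tags

# pooled-statistics percentile convention matches the surrogate module
_P95_METHOD = "linear"
_COV_TOL = 1e-10  # a.u.^2; below this a covariate carries no information


@dataclass
class MotionModel:
    """Fitted per-voxel coefficient fields on the reference grid."""

    alpha: np.ndarray  # (nx, ny, nz, 3), mm per a.u.
    beta: np.ndarray  # (nx, ny, nz, 3), mm per (a.u./s)
    A_ref: np.ndarray  # (nz,) reference-scan slice amplitudes
    Adot_ref: np.ndarray  # (nz,)
    voxel_size: np.ndarray
    affine: np.ndarray
    n_obs: int
    flag_alpha: np.ndarray = None  # True where alpha was unidentifiable
    flag_beta: np.ndarray = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.alpha.shape[:3]


@dataclass
class ResidualReport:
    """Pooled model-fit residual summary over the lung mask."""

    mean: float  # mm
    sd: float  # mm
    p95: float  # mm
    bin_edges: np.ndarray  # 1 mm bins
    counts: np.ndarray
    percent: np.ndarray  # counts as percent of pooled lung-voxel observations
    mip_coronal: np.ndarray  # per-voxel max residual, projected over y
    mip_sagittal: np.ndarray  # projected over x
    n_pooled: int
    n_mask_voxels: int

    def to_dict(self) -> dict:
        return {
            "mean_mm": self.mean,
            "sd_mm": self.sd,
            "p95_mm": self.p95,
            "bin_edges_mm": self.bin_edges.tolist(),
            "counts": self.counts.tolist(),
            "percent": self.percent.tolist(),
            "n_pooled": self.n_pooled,
            "n_mask_voxels": self.n_mask_voxels,
        }


def true_tags(session) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Simulator ground-truth per-slice (A, Adot) for every scan."""
    return {s.index: (s.A_true, s.Adot_true) for s in session.scans}


def surrogate_tags(session) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-slice (A, Adot) assigned from the processed surrogate signal."""
    return {s.index: (s.A_tag, s.Adot_tag) for s in session.scans}


def _covariates(dvf: DVF, tags_target, tags_ref, voxel_z: float):
    """Per-voxel amplitude/rate deltas for one scan's displacement field.

    z' = z + dz / voxel_z is the deformed slice position; the target tag is
    read there, the reference tag at the voxel's own slice.
    """
    A_t, Adot_t = tags_target
    A_r, Adot_r = tags_ref
    nz = dvf.shape[2]
    zp = np.arange(nz, dtype=float)[None, None, :] + dvf.disp[..., 2] / voxel_z
    a = interp_slice_tags(np.asarray(A_t, float), zp) - np.asarray(A_r, float)[None, None, :]
    b = interp_slice_tags(np.asarray(Adot_t, float), zp) - np.asarray(Adot_r, float)[None, None, :]
    return a, b


def fit_model(
    dvfs: list[DVF],
    tags: dict[int, tuple[np.ndarray, np.ndarray]],
    reference_index: int,
    voxel_size,
    affine=None,
) -> MotionModel:
    """Fit alpha and beta at every voxel by no-intercept least squares.

    Every grid voxel is fitted, inside the lungs or not.  The reference scan
    contributes a zero-displacement observation at zero covariate delta
    (which fixes the model at the reference state by construction).
    """
    if reference_index not in tags:
        raise KeyError(f"no tags for reference scan {reference_index}")
    voxel = np.asarray(voxel_size, dtype=float)
    shape = dvfs[0].shape
    ref_tags = tags[reference_index]

    Saa = np.zeros(shape)
    Sbb = np.zeros(shape)
    Sab = np.zeros(shape)
    Sua = np.zeros(shape + (3,))
    Sub = np.zeros(shape + (3,))
    for dvf in dvfs:
        if dvf.target not in tags:
            raise KeyError(f"no tags for scan {dvf.target}")
        a, b = _covariates(dvf, tags[dvf.target], ref_tags, voxel[2])
        Saa += a * a
        Sbb += b * b
        Sab += a * b
        Sua += a[..., None] * dvf.disp
        Sub += b[..., None] * dvf.disp

    det = Saa * Sbb - Sab * Sab
    full = (Saa > _COV_TOL) & (Sbb > _COV_TOL) & (det > 1e-12 * Saa * Sbb)
    only_a = ~full & (Saa > _COV_TOL) & (Sbb <= _COV_TOL)
    only_b = ~full & (Sbb > _COV_TOL) & (Saa <= _COV_TOL)
    det_safe = np.where(full, det, 1.0)
    Saa_safe = np.where(Saa > _COV_TOL, Saa, 1.0)
    Sbb_safe = np.where(Sbb > _COV_TOL, Sbb, 1.0)

    alpha = np.zeros(shape + (3,))
    beta = np.zeros(shape + (3,))
    for k in range(3):
        alpha[..., k] = np.where(
            full, (Sbb * Sua[..., k] - Sab * Sub[..., k]) / det_safe,
            np.where(only_a, Sua[..., k] / Saa_safe, 0.0),
        )
        beta[..., k] = np.where(
            full, (Saa * Sub[..., k] - Sab * Sua[..., k]) / det_safe,
            np.where(only_b, Sub[..., k] / Sbb_safe, 0.0),
        )
    return MotionModel(
        alpha=alpha,
        beta=beta,
        A_ref=np.asarray(ref_tags[0], dtype=float),
        Adot_ref=np.asarray(ref_tags[1], dtype=float),
        voxel_size=voxel,
        affine=dvfs[0].affine if affine is None else affine,
        n_obs=len(dvfs) + 1,
        flag_alpha=~(full | only_a),
        flag_beta=~(full | only_b),
        meta={"reference_index": reference_index},
    )


def predict_displacement(model: MotionModel, A: float, Adot: float = 0.0) -> DVF:
    """Model displacement field at a user-chosen amplitude and rate."""
    da = A - model.A_ref[None, None, :, None]
    db = Adot - model.Adot_ref[None, None, :, None]
    disp = model.alpha * da + model.beta * db
    return DVF(disp=disp, source=model.meta.get("reference_index", 0), target=-1,
               affine=model.affine, meta={"A": A, "Adot": Adot})


def compute_residuals(
    model: MotionModel,
    dvfs: list[DVF],
    tags: dict[int, tuple[np.ndarray, np.ndarray]],
    lung_mask: np.ndarray,
) -> ResidualReport:
    """Distances between model-predicted and DIR-observed voxel positions.

    Residuals are pooled over lung-mask voxels and all non-reference scans;
    the histogram uses 1 mm bins with frequency as percent of the pooled
    set; per-voxel maxima over scans supply the coronal and sagittal
    residual maximum-intensity projections.
    """
    mask = np.asarray(lung_mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("lung mask is empty")
    ref_tags = (model.A_ref, model.Adot_ref)
    pooled = []
    vox_max = np.zeros(model.shape)
    for dvf in dvfs:
        a, b = _covariates(dvf, tags[dvf.target], ref_tags, model.voxel_size[2])
        pred = model.alpha * a[..., None] + model.beta * b[..., None]
        r = np.linalg.norm(dvf.disp - pred, axis=-1)
        pooled.append(r[mask])
        np.maximum(vox_max, r, out=vox_max)
    pooled = np.concatenate(pooled)
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    p95 = float(np.percentile(pooled, 95, method=_P95_METHOD))
    top = max(float(np.ceil(pooled.max())), 1.0)
    edges = np.arange(0.0, top + 1.0)
    counts, _ = np.histogram(pooled, bins=edges)
    vox_max = np.where(mask, vox_max, 0.0)
    return ResidualReport(
        mean=mean, sd=sd, p95=p95,
        bin_edges=edges, counts=counts,
        percent=100.0 * counts / pooled.size,
        mip_coronal=vox_max.max(axis=1),
        mip_sagittal=vox_max.max(axis=0),
        n_pooled=int(pooled.size),
        n_mask_voxels=int(mask.sum()),
    )


def make_lung_mask(volume: np.ndarray, threshold: float = -500.0) -> np.ndarray:
    """Threshold-based lung segmentation.

    Air-like voxels (< threshold) inside the largest connected body
    component, morphologically closed, keeping the two largest components
    (the two lungs).  Adequate for the phantom and for typical thoracic CT;
    bright structures such as the spine are excluded by construction.
    """
    vol = np.asarray(volume)
    body = vol > threshold
    labels, n = ndimage.label(body)
    if n == 0:
        raise EmptyMaskError("no body component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    body_main = labels == (1 + int(np.argmax(sizes)))
    # fill per axial slice: lungs stay enclosed by the body ring even where
    # they cross the cranial/caudal volume border
    body_filled = np.empty_like(body_main)
    for z in range(body_main.shape[2]):
        body_filled[:, :, z] = ndimage.binary_fill_holes(body_main[:, :, z])
    cand = (vol < threshold) & body_filled
    cand = ndimage.binary_closing(cand, structure=ndimage.generate_binary_structure(3, 1))
    labels, n = ndimage.label(cand)
    if n == 0:
        raise EmptyMaskError("no lung-like component inside the body")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:2] + 1
    return np.isin(labels, keep)


def render_residual_mips(report: ResidualReport, out_path, vmax: float | None = None):
    """Residual MIP panel on a green-to-red color wash."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.colors as mcolors
    import matplotlib.pyplot as plt

    cmap = mcolors.LinearSegmentedColormap.from_list("g2r", ["green", "gold", "red"])
    if vmax is None:
        vmax = max(2.0, report.p95 * 1.5)
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2))
    for ax, img, name in zip(axes, (report.mip_coronal, report.mip_sagittal),
                             ("coronal", "sagittal")):
        im = ax.imshow(img.T[::-1], cmap=cmap, vmin=0, vmax=vmax)
        ax.set_title(f"{name} max residual (mm)", fontsize=9)
        ax.set_axis_off()
    fig.colorbar(im, ax=axes, shrink=0.8)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
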