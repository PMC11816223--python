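"""Disk formats: NIfTI volumes, session manifests, trace CSVs.

A session directory contains one NIfTI per scan, ``manifest.json`` with
per-scan acquisition metadata, ``trace.csv`` (t, v_raw and, for simulated
sessions, the ground-truth amplitude/rate and the scanner on/off signal) and
``abdomen.csv`` (t, height_mm).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .model import MotionModel
from .phantom import PhantomSpec
from .registration import DVF
from .session import ScanRecord, ScanSession
from .surrogate import BreathingTrace


def write_nifti(path, data: np.ndarray, affine: np.ndarray):
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_session(session: ScanSession, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"sync_offset": session.sync_offset, "scans": []}
    for s in session.scans:
        name = f"scan_{s.index:02d}.nii"
        write_nifti(out / name, s.volume, s.affine)
        manifest["scans"].append({
            "index": s.index,
            "file": name,
            "direction": s.direction,
            "slice_times": s.slice_times.tolist(),
            "is_reference": s.is_reference,
            "dose_tag": s.dose_tag,
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    trace = {"t": session.trace.t, "v_raw": session.trace.v_raw}
    if session.trace.A_true is not None:
        trace["A_true"] = session.trace.A_true
        trace["Adot_true"] = session.trace.Adot_true
    if session.scanner_on is not None:
        trace["scanner_on"] = session.scanner_on
    pd.DataFrame(trace).to_csv(out / "trace.csv", index=False)
    if session.abdomen_samples is not None:
        pd.DataFrame(session.abdomen_samples, columns=["t", "height_mm"]).to_csv(
            out / "abdomen.csv", index=False)
    if session.phantom is not None:
        _write_phantom(session.phantom, out)
    return out


def _write_phantom(phantom: PhantomSpec, out: Path):
    """Persist the simulator ground truth next to the session volumes."""
    write_nifti(out / "phantom_template.nii", phantom.template, phantom.affine)
    write_nifti(out / "phantom_alpha.nii", phantom.alpha_true, phantom.affine)
    write_nifti(out / "phantom_beta.nii", phantom.beta_true, phantom.affine)
    write_nifti(out / "phantom_masks.nii",
                np.stack([phantom.body_mask, phantom.lung_mask], axis=-1).astype(np.float32),
                phantom.affine)
    (out / "phantom.json").write_text(json.dumps({
        "grid_shape": list(phantom.grid_shape),
        "voxel_size": phantom.voxel_size.tolist(),
        "abdomen_gain": phantom.abdomen_gain,
        "abdomen_profile": phantom.abdomen_profile.tolist(),
        "apex_column": list(phantom.apex_column),
        "apex_z_index": phantom.apex_z_index,
    }, indent=2))


def _read_phantom(d: Path) -> PhantomSpec | None:
    if not (d / "phantom.json").exists():
        return None
    meta = json.loads((d / "phantom.json").read_text())
    template, affine = read_nifti(d / "phantom_template.nii")
    alpha, _ = read_nifti(d / "phantom_alpha.nii")
    beta, _ = read_nifti(d / "phantom_beta.nii")
    masks, _ = read_nifti(d / "phantom_masks.nii")
    return PhantomSpec(
        grid_shape=tuple(meta["grid_shape"]),
        voxel_size=np.asarray(meta["voxel_size"]),
        template=template, alpha_true=alpha, beta_true=beta,
        body_mask=masks[..., 0] > 0.5, lung_mask=masks[..., 1] > 0.5,
        abdomen_gain=float(meta["abdomen_gain"]),
        abdomen_profile=np.asarray(meta["abdomen_profile"]),
        apex_column=tuple(meta["apex_column"]),
        apex_z_index=int(meta["apex_z_index"]),
        affine=affine,
    )


def read_session(session_dir) -> ScanSession:
    d = Path(session_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    df = pd.read_csv(d / "trace.csv")
    trace = BreathingTrace(
        t=df["t"].to_numpy(),
        v_raw=df["v_raw"].to_numpy(),
        A_true=df["A_true"].to_numpy() if "A_true" in df else None,
        Adot_true=df["Adot_true"].to_numpy() if "Adot_true" in df else None,
    )
    scanner_on = df["scanner_on"].to_numpy() if "scanner_on" in df else None
    scans = []
    for entry in manifest["scans"]:
        vol, affine = read_nifti(d / entry["file"])
        times = np.asarray(entry["slice_times"], dtype=float)
        rec = ScanRecord(
            index=entry["index"], volume=vol, affine=affine,
            direction=entry["direction"], slice_times=times,
            is_reference=entry["is_reference"], dose_tag=entry["dose_tag"],
        )
        if trace.A_true is not None:
            rec.A_true = np.interp(times, trace.t, trace.A_true)
            rec.Adot_true = np.interp(times, trace.t, trace.Adot_true)
        scans.append(rec)
    abdomen = None
    if (d / "abdomen.csv").exists():
        abdomen = pd.read_csv(d / "abdomen.csv").to_numpy()
    return ScanSession(
        scans=scans, trace=trace, scanner_on=scanner_on,
        sync_offset=float(manifest.get("sync_offset", 0.0)),
        abdomen_samples=abdomen,
        phantom=_read_phantom(d),
    )


def write_dvf(path, dvf: DVF):
    write_nifti(path, dvf.disp, dvf.affine if dvf.affine is not None else np.eye(4))


def read_dvf(path, source: int = 0, target: int = -1) -> DVF:
    data, affine = read_nifti(path)
    if data.ndim == 5 and data.shape[3] == 1:
        data = data[:, :, :, 0, :]
    return DVF(disp=data, source=source, target=target, affine=affine)


def write_model(model: MotionModel, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nifti(out / "alpha.nii", model.alpha, model.affine)
    write_nifti(out / "beta.nii", model.beta, model.affine)
    meta = {
        "A_ref": model.A_ref.tolist(),
        "Adot_ref": model.Adot_ref.tolist(),
        "voxel_size": model.voxel_size.tolist(),
        "n_obs": model.n_obs,
        "meta": model.meta,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    return out


def read_model(model_dir) -> MotionModel:
    d = Path(model_dir)
    alpha, affine = read_nifti(d / "alpha.nii")
    beta, _ = read_nifti(d / "beta.nii")
    meta = json.loads((d / "model.json").read_text())
    return MotionModel(
        alpha=alpha, beta=beta,
        A_ref=np.asarray(meta["A_ref"]), Adot_ref=np.asarray(meta["Adot_ref"]),
        voxel_size=np.asarray(meta["voxel_size"]), affine=affine,
        n_obs=int(meta["n_obs"]),
        flag_alpha=np.zeros(alpha.shape[:3], dtype=bool),
        flag_beta=np.zeros(alpha.shape[:3], dtype=bool),
        meta=meta.get("meta", {}),
    )


def write_phase_set(phase_set, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = []
    for e in phase_set.phase_spec:
        name = f"phase_{e.label}.nii"
        write_nifti(out / name, phase_set[e.label], phase_set.affine)
        sidecar.append({"label": e.label, "file": name, "A": e.A, "Adot": e.Adot})
    (out / "phases.json").write_text(json.dumps(sidecar, indent=2))
    return out
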