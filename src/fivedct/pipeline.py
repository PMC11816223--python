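"""End-to-end orchestration of the 5DCT workflow on one session.

Steps: detect scan windows -> validate scan ranges -> harmonize grids ->
process the surrogate (drift correction, rate, breaths, phase spec) -> tag
slices -> obtain deformation fields (ground truth for phantom sessions) ->
fit the motion model -> residual diagnostics -> reconstruct the 8 phase
images, the MIP and the MEGA-MIP -> optionally assemble the QA report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import model as mm
from . import qa, reconstruct, registration, surrogate
from .session import (
    ScanSession,
    correct_direction_shifts,
    detect_scan_windows,
    tag_slices,
    validate_scan_ranges,
)


@dataclass
class WorkflowResult:
    session: ScanSession
    signal: surrogate.SurrogateSignal
    rep_breath: surrogate.RepresentativeBreath
    phase_spec: surrogate.PhaseSpec
    dvfs: list
    model: mm.MotionModel
    lung_mask: np.ndarray
    residuals: mm.ResidualReport
    phase_set: reconstruct.PhaseImageSet
    mip: np.ndarray
    mega_mip: np.ndarray
    validation_report: dict
    shifts: dict
    report_summary: dict | None = None
    extras: dict = field(default_factory=dict)


def run_workflow(
    session: ScanSession,
    dvfs: list | None = None,
    tag_source: str = "surrogate",
    report_dir: str | Path | None = None,
) -> WorkflowResult:
    """Run the full workflow on a session.

    ``tag_source`` selects the amplitude/rate signal driving the model fit
    AND the phase targets (the two must share one amplitude scale):
    ``"surrogate"`` (processed bellows signal — the clinical path) or
    ``"true"`` (simulator ground truth — the oracle path for accuracy
    studies).  ``dvfs`` defaults to ground-truth fields on phantom sessions.
    """
    windows = None
    if session.scanner_on is not None:
        windows, _ = detect_scan_windows(session.trace.t, session.scanner_on)
        if len(windows) == session.n_scans:
            # scans map to windows strictly by temporal order
            session.scan_windows = windows
    session, validation = validate_scan_ranges(session)
    if session.scan_windows is not None and validation["dropped"]:
        keep = [s.index for s in session.scans]
        session.scan_windows = [w for i, w in enumerate(session.scan_windows) if i in keep]
    session, shifts = correct_direction_shifts(session)

    surrogate_signal = surrogate.correct_drift(session.trace, session.abdomen_samples)
    surrogate_signal = surrogate.compute_rate(surrogate_signal)
    if tag_source == "true":
        if session.trace.A_true is None:
            raise ValueError("tag_source='true' needs simulator ground truth")
        signal = surrogate.SurrogateSignal(
            t=session.trace.t, A=session.trace.A_true.copy(),
            Adot=session.trace.Adot_true.copy(),
            abdomen_correlation=surrogate_signal.abdomen_correlation,
        )
    else:
        signal = surrogate_signal
    breaths = surrogate.segment_breaths(signal)
    rep = surrogate.build_representative_breath(signal, breaths)
    phase_spec = surrogate.make_phase_spec(rep)
    tag_slices(session, signal)

    if dvfs is None:
        dvfs = registration.ground_truth_dvfs(session)
    ref = session.reference
    tags = mm.true_tags(session) if tag_source == "true" else mm.surrogate_tags(session)
    motion = mm.fit_model(dvfs, tags, ref.index, ref.voxel_size, affine=ref.affine)
    lung_mask = mm.make_lung_mask(ref.volume)
    residuals = mm.compute_residuals(motion, dvfs, tags, lung_mask)

    phase_set = reconstruct.reconstruct_phase_set(motion, phase_spec, ref.volume)
    mip = reconstruct.max_intensity_projection(phase_set.as_list())
    mega_mip = reconstruct.max_intensity_projection(
        [np.asarray(s.volume, dtype=float) for s in session.scans]
    )

    result = WorkflowResult(
        session=session, signal=signal, rep_breath=rep, phase_spec=phase_spec,
        dvfs=dvfs, model=motion, lung_mask=lung_mask, residuals=residuals,
        phase_set=phase_set, mip=mip, mega_mip=mega_mip,
        validation_report=validation, shifts=shifts,
    )
    result.extras["scan_windows"] = windows
    if report_dir is not None:
        result.report_summary = build_qa_report(result, report_dir)
    return result


def build_qa_report(result: WorkflowResult, out_dir) -> dict:
    """Render all QA panels and assemble the four-section report."""
    from . import plots
    from .model import render_residual_mips
    from .registration import overlay_contact_sheet

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session, signal = result.session, result.signal
    breaths = surrogate.segment_breaths(signal)

    windows = result.extras.get("scan_windows") or []
    acquisition = {
        "scan_start_stop": plots.scan_windows_panel(
            session.trace.t, session.scanner_on, windows, out / "scan_windows.png")
        if session.scanner_on is not None else None,
        "scan_ranges": {
            "modal_slices": result.validation_report["modal_slices"],
            "dropped": result.validation_report["dropped"],
        },
        "corrected_shifts": result.shifts,
        "bellows_abdomen_correlation": signal.abdomen_correlation,
    }
    breathing = {
        "respiratory_trace": plots.trace_panel(signal, out / "trace.png"),
        "amplitude_histogram": plots.amplitude_histogram(signal, out / "amp_hist.png"),
        "waveform_segmentation": plots.segmentation_panel(
            signal, breaths, out / "segmentation.png"),
        "representative_breath": plots.representative_breath_panel(
            result.rep_breath, signal, out / "rep_breath.png"),
    }
    registration_section = {
        "dir_overlays": str(overlay_contact_sheet(
            session, result.dvfs, out / "dir_overlays.png")),
    }
    res = result.residuals
    # original-scan-reconstruction overlay for the scan with the largest tag span
    worst = max((s for s in session.scans if not s.is_reference),
                key=lambda s: np.ptp(s.A_tag if s.A_tag is not None else s.A_true))
    tags = mm.surrogate_tags(session) if worst.A_tag is not None else mm.true_tags(session)
    recon = reconstruct.reconstruct_original_scan(
        result.model, worst, tags, session.reference.volume)
    osr_img = registration.render_overlay(np.asarray(worst.volume, float), recon)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(osr_img)
    ax.set_axis_off()
    ax.set_title(f"original scan reconstruction, scan {worst.index}", fontsize=8)
    fig.savefig(out / "osr_overlay.png", dpi=100)
    plt.close(fig)

    modeling = {
        "model_summary": {
            "n_scans": session.n_scans,
            "reference_scan": session.reference.index,
            "residual_mean_mm": res.mean,
            "residual_sd_mm": res.sd,
            "residual_p95_mm": res.p95,
        },
        "residual_histogram": plots.residual_histogram_panel(
            res, out / "residual_hist.png"),
        "residual_mips": str(render_residual_mips(res, out / "residual_mips.png")),
        "original_scan_reconstructions": str(out / "osr_overlay.png"),
    }
    return qa.assemble_report(
        out, acquisition=acquisition, breathing=breathing,
        registration=registration_section, modeling=modeling,
    )
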