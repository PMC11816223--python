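"""QA-report figure panels (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np


def _save(fig, out_path) -> str:
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return str(out_path)


def trace_panel(signal, out_path) -> str:
    """Amplitude trace annotated with the 5th, 85th and 95th percentiles."""
    fig, ax = plt.subplots(figsize=(8, 2.6))
    ax.plot(signal.t, signal.A, lw=0.6, color="steelblue")
    for key, color in (("P5", "green"), ("P85", "orange"), ("P95", "red")):
        ax.axhline(signal.percentiles[key], color=color, ls="--", lw=0.8, label=key)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("amplitude (a.u.)")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    return _save(fig, out_path)


def amplitude_histogram(signal, out_path, bins: int = 40) -> str:
    """Fraction of time spent in each amplitude bin."""
    fig, ax = plt.subplots(figsize=(4, 2.6))
    ax.hist(signal.A, bins=bins, weights=np.full(signal.A.size, 100.0 / signal.A.size),
            color="steelblue")
    ax.set_xlabel("amplitude (a.u.)")
    ax.set_ylabel("% of time")
    fig.tight_layout()
    return _save(fig, out_path)


def segmentation_panel(signal, breaths, out_path) -> str:
    """Trace with every detected exhalation point annotated."""
    fig, ax = plt.subplots(figsize=(8, 2.6))
    ax.plot(signal.t, signal.A, lw=0.6, color="steelblue")
    starts = sorted({a for a, _ in breaths} | {b for _, b in breaths})
    ax.plot(signal.t[starts], signal.A[starts], "v", color="crimson", ms=4,
            label="exhalation points")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("amplitude (a.u.)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return _save(fig, out_path)


def representative_breath_panel(rep, signal, out_path) -> str:
    """Representative breath alone and in the context of the whole trace."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 2.6),
                                   gridspec_kw={"width_ratios": [1, 3]})
    ax1.plot(rep.phase * rep.period, rep.A, color="darkorange")
    ax1.set_xlabel("time in breath (s)")
    ax1.set_ylabel("amplitude (a.u.)")
    ax1.set_title("representative breath", fontsize=8)
    ax2.plot(signal.t, signal.A, lw=0.5, color="steelblue", alpha=0.7)
    t0 = signal.t[0] + 0.45 * (signal.t[-1] - signal.t[0])
    ax2.plot(t0 + rep.phase * rep.period, rep.A, color="darkorange", lw=1.5)
    for key in ("P5", "P95"):
        ax2.axhline(signal.percentiles[key], color="gray", ls=":", lw=0.7)
    ax2.set_xlabel("time (s)")
    fig.tight_layout()
    return _save(fig, out_path)


def scan_windows_panel(t, scanner_on, windows, out_path) -> str:
    """Binary CT on/off signal with the detected scan windows."""
    fig, ax = plt.subplots(figsize=(8, 1.8))
    ax.plot(t, scanner_on, lw=0.6, color="black")
    for a, b in windows:
        ax.axvspan(a, b, color="steelblue", alpha=0.25)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("CT on")
    fig.tight_layout()
    return _save(fig, out_path)


def residual_histogram_panel(report, out_path) -> str:
    """Model residual histogram in 1 mm bins, percent of lung voxels."""
    fig, ax = plt.subplots(figsize=(4, 2.6))
    centers = report.bin_edges[:-1] + 0.5
    ax.bar(centers, report.percent, width=0.9, color="seagreen")
    ax.set_xlabel("residual (mm)")
    ax.set_ylabel("% of lung voxels")
    fig.tight_layout()
    return _save(fig, out_path)
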