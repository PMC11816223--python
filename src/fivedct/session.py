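"""Session synchronization: scan windows, geometry harmonization, slice tags.

A 5DCT session couples N fast-helical volumes to one surrogate trace.  This
module detects scanner on/off windows in the sync signal, drops truncated
scans, resamples foot-first scans onto the reference grid (the scanner
reconstructs the two directions at sub-millimeter different couch positions),
and assigns each slice of each scan its breathing amplitude and rate at the
slice's mid-exposure time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import (
    ExcessiveNoiseError,
    GeometryError,
    OutOfRangeError,
    SyncError,
    UnderDeterminedSessionError,
    UnusableReferenceError,
)
from .surrogate import BreathingTrace, SurrogateSignal

AIR_HU = -1000.0
MAX_SHIFT_MM = 1.0  # larger direction shifts indicate a programming error


@dataclass
class ScanRecord:
    """One fast-helical volume with per-slice acquisition times."""

    index: int
    volume: np.ndarray  # (nx, ny, nz) intensities
    affine: np.ndarray  # 4x4, axis-aligned, mm
    direction: str  # 'head-first' | 'foot-first'
    slice_times: np.ndarray  # s, one per z slice (mid-exposure)
    is_reference: bool = False
    dose_tag: str = "low"
    A_true: np.ndarray | None = None  # simulator ground truth per slice
    Adot_true: np.ndarray | None = None
    A_tag: np.ndarray | None = None  # assigned by tag_slices
    Adot_tag: np.ndarray | None = None

    @property
    def n_slices(self) -> int:
        return self.volume.shape[2]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.abs(np.diag(self.affine)[:3])


@dataclass
class ScanSession:
    """A set of scans, the surrogate trace, and synchronization metadata."""

    scans: list[ScanRecord]
    trace: BreathingTrace
    scanner_on: np.ndarray | None = None  # binary, sampled on trace.t
    sync_offset: float = 0.0  # s added to slice times before surrogate lookup
    abdomen_samples: np.ndarray | None = None  # (n, 2) of (t s, height mm)
    phantom: object | None = None  # PhantomSpec when simulated
    scan_windows: list[tuple[float, float]] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def reference(self) -> ScanRecord:
        refs = [s for s in self.scans if s.is_reference]
        if len(refs) != 1:
            raise UnusableReferenceError(f"session has {len(refs)} reference scans")
        return refs[0]

    @property
    def n_scans(self) -> int:
        return len(self.scans)


def detect_scan_windows(t: np.ndarray, signal: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """Detect scanner-on windows from a binary on/off signal.

    Levels are estimated as the medians of the samples on either side of the
    signal midpoint; edges are located by linear interpolation of the
    threshold crossing.  Returns (windows, noise_margin) where noise_margin
    is the largest deviation of any sample from its level, as a fraction of
    the level separation.  A margin >= 0.5 means the two levels overlap and
    the windows cannot be trusted.
    """
    t = np.asarray(t, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if np.ptp(signal) == 0:
        return [], 0.0
    mid = 0.5 * (signal.min() + signal.max())
    hi_cls = signal >= mid
    level_lo = float(np.median(signal[~hi_cls]))
    level_hi = float(np.median(signal[hi_cls]))
    sep = level_hi - level_lo
    dev = np.where(hi_cls, np.abs(signal - level_hi), np.abs(signal - level_lo))
    margin = float(dev.max() / sep)
    if margin >= 0.5:
        raise ExcessiveNoiseError(
            f"on/off signal noise is {margin:.0%} of the level separation"
        )
    thr = 0.5 * (level_lo + level_hi)
    above = signal > thr
    flips = np.flatnonzero(np.diff(above.astype(int)))
    edges = []
    for i in flips:
        # linear interpolation of the crossing between samples i and i+1
        f = (thr - signal[i]) / (signal[i + 1] - signal[i])
        edges.append((t[i] + f * (t[i + 1] - t[i]), above[i + 1]))
    windows = []
    start = t[0] if above[0] else None
    for time, rising in edges:
        if rising:
            start = time
        elif start is not None:
            windows.append((float(start), float(time)))
            start = None
    if start is not None and above[-1]:
        windows.append((float(start), float(t[-1])))
    return windows, margin


def validate_scan_ranges(session: ScanSession) -> tuple[ScanSession, dict]:
    """Drop scans whose slice count differs from the session mode.

    Mirrors the clinical rule that a truncated helical pass is removed from
    further analysis.  Raises if the reference itself is truncated or fewer
    than 3 scans survive.
    """
    counts = Counter(s.n_slices for s in session.scans)
    modal = counts.most_common(1)[0][0]
    kept, dropped = [], []
    for s in session.scans:
        if s.n_slices == modal:
            kept.append(s)
        else:
            if s.is_reference:
                raise UnusableReferenceError(
                    f"reference scan has {s.n_slices} slices, expected {modal}"
                )
            dropped.append(s.index)
    if len(kept) < 3:
        raise UnderDeterminedSessionError(f"only {len(kept)} usable scans remain")
    report = {"modal_slices": modal, "dropped": dropped}
    if not dropped:
        return session, report
    new = ScanSession(
        scans=kept, trace=session.trace, scanner_on=session.scanner_on,
        sync_offset=session.sync_offset, abdomen_samples=session.abdomen_samples,
        phantom=session.phantom, scan_windows=session.scan_windows,
        meta=dict(session.meta),
    )
    return new, report


def correct_direction_shifts(session: ScanSession, max_shift_mm: float = MAX_SHIFT_MM) -> tuple[ScanSession, dict]:
    """Resample all scans onto the reference grid.

    Foot-first passes are reconstructed at slightly different couch
    positions; any translation up to ``max_shift_mm`` is corrected by
    trilinear resampling.  A larger offset signals a programming error in
    the acquisition and raises.  Scans already on the reference grid are
    returned untouched (bit-identical).
    """
    ref = session.reference
    shifts = {}
    for s in session.scans:
        if not np.allclose(s.affine[:3, :3], ref.affine[:3, :3]):
            raise GeometryError(f"scan {s.index}: non-translational grid mismatch")
        off = s.affine[:3, 3] - ref.affine[:3, 3]
        if np.max(np.abs(off)) > max_shift_mm:
            raise GeometryError(
                f"scan {s.index}: grid offset {off} mm exceeds {max_shift_mm} mm — "
                "likely a CT programming error"
            )
        shifts[s.index] = off.tolist()
        if np.any(off != 0):
            voxel = s.voxel_size
            idx = [np.arange(n, dtype=float) for n in s.volume.shape]
            grid = np.meshgrid(*idx, indexing="ij")
            # scan index of a reference-grid world point: i_ref - offset/voxel
            coords = [g - off[k] / voxel[k] for k, g in enumerate(grid)]
            s.volume = map_coordinates(
                s.volume.astype(float), coords, order=1,
                mode="constant", cval=AIR_HU, prefilter=False,
            ).astype(s.volume.dtype)
            s.affine = ref.affine.copy()
    session.meta["corrected_shifts"] = shifts
    return session, shifts


def tag_slices(session: ScanSession, signal: SurrogateSignal) -> pd.DataFrame:
    """Assign every slice of every scan its (A, Adot) from the surrogate.

    Values are linearly interpolated at ``slice_time + sync_offset``; tags
    are stored on each record and returned as a tidy table.
    """
    if session.scan_windows is not None and len(session.scan_windows) != session.n_scans:
        raise SyncError(
            f"{len(session.scan_windows)} scan windows for {session.n_scans} scans"
        )
    rows = []
    for s in session.scans:
        times = s.slice_times + session.sync_offset
        if times.min() < signal.t[0] or times.max() > signal.t[-1]:
            raise OutOfRangeError(f"scan {s.index} slice times fall outside the trace")
        A, Adot = signal.interp(times)
        s.A_tag, s.Adot_tag = A, Adot
        for z in range(s.n_slices):
            rows.append((s.index, z, times[z], A[z], Adot[z]))
    return pd.DataFrame(rows, columns=["scan", "slice", "t", "A", "Adot"])
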