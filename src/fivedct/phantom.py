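"""Synthetic deforming-thorax sessions with known ground truth.

The phantom is a minimal thorax in Hounsfield-like units: an elliptical soft
tissue body (air outside at -1000 HU), two low-intensity lung compartments,
a bright diaphragm dome under each lung, vessel-like bright spheres in the
lungs, a bright zero-motion spine, and an anterior abdominal surface whose
height tracks breathing amplitude (used by the drift-correction stage).

Motion follows the per-voxel linear model: a voxel at rest position x0 sits at
``x0 + alpha(x0) * A(t) + beta(x0) * Adot(t)`` at breathing amplitude A and
rate Adot.  ``alpha`` peaks at the diaphragm and decays cranially; ``beta`` is
a smaller field producing hysteresis; both vanish smoothly at the body surface
and inside the spine.

A session is 25 fast-helical scans acquired slice by slice with alternating
craniocaudal direction while a bellows trace with linear thermal drift and
noise is recorded; the first scan is the high-dose reference.  True per-slice
amplitudes and rates are retained everywhere so every downstream stage has an
exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _warp
from .errors import InvalidSpecError, OutOfRangeError, UnderDeterminedSessionError
from .session import ScanRecord, ScanSession
from .surrogate import BreathingTrace

AIR, LUNG, TISSUE, DIAPHRAGM, VESSEL, BONE = -1000.0, -800.0, 40.0, 60.0, 100.0, 700.0


@dataclass
class WaveformSpec:
    """Breathing waveform parameters.

    Breaths are concatenated raised-cosine cycles with per-breath period and
    depth drawn from normal distributions, so `breath_period_sd` /
    `amplitude_sd` dial breathing irregularity from perfectly regular to very
    irregular.  The raw bellows value adds gain, offset, linear thermal drift
    and white noise on top of the true amplitude.
    """

    duration: float = 140.0  # s
    sample_rate: float = 50.0  # Hz
    breath_period_mean: float = 4.0  # s
    breath_period_sd: float = 0.4  # s
    amplitude_mean: float = 1.0  # a.u.
    amplitude_sd: float = 0.1  # a.u.
    drift_slope: float = 0.005  # a.u./s
    noise_sd: float = 0.01  # a.u.
    gain: float = 1.0
    offset: float = 0.2  # a.u.
    seed: int = 0

    def validate(self):
        if self.duration <= 0 or self.sample_rate <= 0:
            raise InvalidSpecError("duration and sample_rate must be positive")
        if self.breath_period_mean <= 0:
            raise InvalidSpecError("breath period must be positive")


@dataclass
class PhantomSpec:
    """A deforming thorax with ground-truth motion fields."""

    grid_shape: tuple[int, int, int]
    voxel_size: np.ndarray  # mm per axis
    template: np.ndarray  # HU-like intensities at A = 0
    alpha_true: np.ndarray  # (nx, ny, nz, 3) mm per a.u.
    beta_true: np.ndarray  # (nx, ny, nz, 3) mm per (a.u./s)
    body_mask: np.ndarray
    lung_mask: np.ndarray
    abdomen_gain: float  # mm of anterior surface rise per a.u.
    abdomen_profile: np.ndarray  # per-slice surface gain, mm per a.u.
    apex_column: tuple[int, int]  # (ix, iy) through the right diaphragm dome
    apex_z_index: int  # dome apex slice at A = 0
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.affine is None:
            aff = np.eye(4)
            aff[:3, :3] = np.diag(self.voxel_size)
            self.affine = aff

    @property
    def apex_alpha_z(self) -> float:
        ix, iy = self.apex_column
        return float(self.alpha_true[ix, iy, self.apex_z_index, 2])


def make_default_phantom(
    grid_shape: tuple[int, int, int] = (64, 64, 48),
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 2.5),
    alpha_peak: float = 10.0,  # mm per a.u., craniocaudal, at the diaphragm
    beta_peak: float = 2.0,  # mm per (a.u./s)
    abdomen_gain: float = 8.0,  # mm per a.u.
) -> PhantomSpec:
    """Build the standard phantom; geometry scales with the field of view."""
    nx, ny, nz = grid_shape
    voxel = np.asarray(voxel_size, dtype=float)
    extent = np.array(grid_shape) * voxel  # mm
    x = (np.arange(nx) + 0.5) * voxel[0]
    y = (np.arange(ny) + 0.5) * voxel[1]
    z = (np.arange(nz) + 0.5) * voxel[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    cx, cy = extent[0] / 2, extent[1] / 2

    # body: elliptical cylinder of soft tissue
    rx, ry = 0.42 * extent[0], 0.35 * extent[1]
    r2_body = ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2
    body = r2_body <= 1.0
    vol = np.full(grid_shape, AIR)
    vol[body] = TISSUE

    # lungs: two ellipsoids, bottoms carved by diaphragm domes
    lung_mask = np.zeros(grid_shape, dtype=bool)
    apex_info = {}
    for side, sgn in (("right", -1), ("left", +1)):
        lx = cx + sgn * 0.18 * extent[0]
        ly = cy - 0.04 * extent[1]
        lz = 0.62 * extent[2]
        ax_, ay_, az_ = 0.14 * extent[0], 0.24 * extent[1], 0.34 * extent[2]
        inside = (((X - lx) / ax_) ** 2 + ((Y - ly) / ay_) ** 2
                  + ((Z - lz) / az_) ** 2) <= 1.0
        # dome: anterior-posterior paraboloid rising to an apex at the lung center
        z_base = 0.30 * extent[2] if side == "right" else 0.26 * extent[2]
        h = 0.16 * extent[2]
        bump = np.clip(1.0 - ((X - lx) / ax_) ** 2 - ((Y - ly) / ay_) ** 2, 0.0, None)
        z_dome = z_base + h * bump
        lung = inside & (Z > z_dome)
        lung_mask |= lung
        if side == "right":
            ix = int(np.argmin(np.abs(x - lx)))
            iy = int(np.argmin(np.abs(y - ly)))
            apex_z = z_base + h * np.clip(
                1.0 - ((x[ix] - lx) / ax_) ** 2 - ((y[iy] - ly) / ay_) ** 2, 0, None
            )
            apex_info = {"column": (ix, iy), "z_index": int(round(apex_z / voxel[2] - 0.5))}
        # bright dome shell just below the lung floor
        dome_shell = inside & (Z <= z_dome) & (Z > z_dome - 0.06 * extent[2])
        vol[dome_shell] = DIAPHRAGM
    vol[lung_mask] = LUNG

    # vessel-like spheres inside the lungs
    rng_v = np.random.default_rng(12345)  # fixed anatomy, not a study condition
    candidates = np.argwhere(lung_mask)
    for k in range(6):
        ci = candidates[rng_v.integers(len(candidates))]
        cxyz = (ci + 0.5) * voxel
        d2 = ((X - cxyz[0]) ** 2 + (Y - cxyz[1]) ** 2 + (Z - cxyz[2]) ** 2)
        vol[(d2 <= (0.02 * extent[0] + 4.0) ** 2) & lung_mask] = VESSEL

    # spine: posterior bright cylinder, zero motion
    sx, sy, sr = cx, cy + 0.27 * extent[1], 0.05 * extent[0]
    d_spine = np.sqrt((X - sx) ** 2 + (Y - sy) ** 2)
    spine = (d_spine <= sr) & body
    vol[spine] = BONE

    # motion weight: smooth, peaks at the diaphragm, vanishes at the body
    # surface and within/near the spine
    z_dia = 0.38 * extent[2]
    g_z = np.exp(-(((Z - z_dia) / (0.33 * extent[2])) ** 2))
    e_xy = np.clip(1.0 - r2_body, 0.0, None)
    w_spine = np.clip((d_spine - 1.4 * sr) / (2.0 * sr), 0.0, 1.0)
    # smoothstep taper to zero at the craniocaudal volume edges keeps the
    # motion map contractive for the fixed-point inversion
    ramp = np.clip(np.minimum(Z, extent[2] - Z) / (0.12 * extent[2]), 0.0, 1.0)
    w_edge = ramp * ramp * (3.0 - 2.0 * ramp)
    w = g_z * e_xy * w_spine * w_edge * body
    w /= w.max()

    alpha_dir = np.array([0.06, 0.12, 1.0]) * alpha_peak
    beta_dir = np.array([0.1, 0.3, 1.0]) * beta_peak
    alpha_true = w[..., None] * alpha_dir
    beta_true = w[..., None] * beta_dir

    profile = np.full(nz, abdomen_gain)
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        voxel_size=voxel,
        template=vol,
        alpha_true=alpha_true,
        beta_true=beta_true,
        body_mask=body,
        lung_mask=lung_mask,
        abdomen_gain=abdomen_gain,
        abdomen_profile=profile,
        apex_column=apex_info["column"],
        apex_z_index=apex_info["z_index"],
    )


def diaphragm_apex_index(volume: np.ndarray, phantom: PhantomSpec,
                         threshold: float = -370.0) -> float:
    """Sub-voxel z index of the right diaphragm dome apex in a volume.

    Walks the stored apex column from the lung region downward and linearly
    interpolates the tissue/lung intensity crossing.  Used by geometry checks:
    the apex displaces by ``alpha_z(apex) * dA`` between breathing states.
    """
    ix, iy = phantom.apex_column
    col = np.asarray(volume, dtype=float)[ix, iy, :]
    z_top = int(0.62 * col.size)  # below the lung center, above any dome position
    idx = np.nonzero(col[:z_top] > threshold)[0]
    if idx.size == 0:
        raise ValueError("no diaphragm surface found in the apex column")
    z0 = int(idx.max())
    if z0 + 1 >= col.size or col[z0 + 1] >= threshold:
        return float(z0)
    return z0 + (col[z0] - threshold) / (col[z0] - col[z0 + 1])


def generate_waveform(spec: WaveformSpec) -> BreathingTrace:
    """Simulate a bellows trace with ground-truth amplitude and rate.

    Amplitude is a chain of raised-cosine breaths (zero amplitude and rate at
    every breath boundary, so the concatenation is C1); the raw bellows value
    is ``gain * A + drift_slope * t + offset + noise``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    periods, amps = [], []
    total = 0.0
    while total < spec.duration + 2 * spec.breath_period_mean:
        T = rng.normal(spec.breath_period_mean, spec.breath_period_sd)
        T = max(T, 0.25 * spec.breath_period_mean, 0.5)
        a = rng.normal(spec.amplitude_mean, spec.amplitude_sd)
        a = max(a, 0.05 * spec.amplitude_mean)
        periods.append(T)
        amps.append(a)
        total += T
    periods = np.array(periods)
    amps = np.array(amps)
    edges = np.concatenate([[0.0], np.cumsum(periods)])

    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(periods) - 1)
    tau = t - edges[idx]
    T_i = periods[idx]
    a_i = amps[idx]
    A = a_i * 0.5 * (1.0 - np.cos(2 * np.pi * tau / T_i))
    Adot = a_i * (np.pi / T_i) * np.sin(2 * np.pi * tau / T_i)
    v_raw = (spec.gain * A + spec.drift_slope * t + spec.offset
             + spec.noise_sd * rng.standard_normal(n))
    return BreathingTrace(t=t, v_raw=v_raw, A_true=A, Adot_true=Adot)


def _slice_times(nz: int, start_time: float, direction: str, slice_interval: float) -> np.ndarray:
    """Mid-exposure acquisition time of each z slice."""
    order = np.arange(nz) if direction == "head-first" else np.arange(nz)[::-1]
    return start_time + (order + 0.5) * slice_interval


def simulate_helical_scan(
    phantom: PhantomSpec,
    trace: BreathingTrace,
    scan_index: int,
    start_time: float,
    direction: str = "head-first",
    slice_interval: float = 0.08,
    grid_offset_mm: np.ndarray | None = None,
    interp_tol: float = 0.05,
) -> ScanRecord:
    """Acquire one fast-helical scan of the breathing phantom.

    Each output slice z is the phantom deformed at that slice's acquisition
    time (its true amplitude and rate), sampled by fixed-point inversion of
    the motion map and trilinear pull-back.  ``grid_offset_mm`` models the
    sub-millimeter couch-position difference of foot-first reconstructions.
    """
    if direction not in ("head-first", "foot-first"):
        raise InvalidSpecError(f"unknown direction {direction!r}")
    nz = phantom.grid_shape[2]
    times = _slice_times(nz, start_time, direction, slice_interval)
    if times.min() < trace.t[0] or times.max() > trace.t[-1]:
        raise OutOfRangeError("scan time span extends past the trace")
    A = np.interp(times, trace.t, trace.A_true)
    Adot = np.interp(times, trace.t, trace.Adot_true)

    points = _warp.grid_points(phantom.grid_shape)
    affine = phantom.affine.copy()
    if grid_offset_mm is not None:
        off = np.asarray(grid_offset_mm, dtype=float)
        points = points + off / phantom.voxel_size
        affine[:3, 3] = affine[:3, 3] + off
    psi, _, _ = _warp.invert_model_map(
        phantom.alpha_true, phantom.beta_true, A, Adot,
        phantom.voxel_size, points=points, tol=interp_tol,
    )
    volume = _warp.pull_volume(phantom.template, psi).astype(np.float32)
    return ScanRecord(
        index=scan_index,
        volume=volume,
        affine=affine,
        direction=direction,
        slice_times=times,
        is_reference=False,
        dose_tag="low",
        A_true=A,
        Adot_true=Adot,
    )


def simulate_session(
    phantom: PhantomSpec,
    spec: WaveformSpec | None = None,
    n_scans: int = 25,
    reference_index: int = 0,
    scan_duration: float = 4.0,  # s per helical pass
    gap: float = 0.8,  # s between passes
    session_start: float = 5.0,  # s into the trace
    foot_first_offset_mm: float = 0.4,
    abdomen_sample_interval: float = 2.0,  # s
    abdomen_noise_mm: float = 0.1,
) -> ScanSession:
    """Simulate a full acquisition: scans, bellows trace, scanner on/off signal.

    Scans alternate head-first / foot-first; scan ``reference_index`` is
    tagged as the high-dose reference (a metadata distinction only).  The
    default 25 passes at 4 s + 0.8 s gap span ~2 minutes.
    """
    if n_scans < 3:
        raise UnderDeterminedSessionError(
            "a session needs >= 3 scans to identify the two model coefficients"
        )
    if spec is None:
        spec = WaveformSpec()
    needed = session_start + n_scans * (scan_duration + gap) + 2.0
    if spec.duration < needed:
        spec = WaveformSpec(**{**spec.__dict__, "duration": needed})
    trace = generate_waveform(spec)
    rng = np.random.default_rng(spec.seed + 1)

    nz = phantom.grid_shape[2]
    slice_interval = scan_duration / nz
    scans = []
    for k in range(n_scans):
        direction = "head-first" if k % 2 == 0 else "foot-first"
        offset = None
        if direction == "foot-first" and foot_first_offset_mm:
            offset = np.array([0.0, 0.0, foot_first_offset_mm])
        rec = simulate_helical_scan(
            phantom, trace, k,
            start_time=session_start + k * (scan_duration + gap),
            direction=direction, slice_interval=slice_interval,
            grid_offset_mm=offset,
        )
        if k == reference_index:
            rec.is_reference = True
            rec.dose_tag = "high"
        scans.append(rec)

    # binary scanner on/off signal sampled on the trace clock
    on = np.zeros_like(trace.t)
    for rec in scans:
        t0 = rec.slice_times.min() - slice_interval / 2
        t1 = rec.slice_times.max() + slice_interval / 2
        on[(trace.t >= t0) & (trace.t <= t1)] = 1.0

    # abdominal surface height samples: h = h0 + gain * A_true + noise
    ts = np.arange(trace.t[0], trace.t[-1], abdomen_sample_interval)
    heights = (10.0 + phantom.abdomen_gain * np.interp(ts, trace.t, trace.A_true)
               + abdomen_noise_mm * rng.standard_normal(ts.size))
    abdomen = np.column_stack([ts, heights])

    return ScanSession(
        scans=scans,
        trace=trace,
        scanner_on=on,
        sync_offset=0.0,
        abdomen_samples=abdomen,
        phantom=phantom,
    )
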