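"""Respiratory-surrogate processing.

Converts a raw abdominal-bellows pressure trace into the two respiratory
covariates of the 5D motion model — breathing amplitude ``A`` and breathing
rate ``Adot = dA/dt`` — and derives the per-session phase targets:

1. linear thermal drift is removed by maximizing the correlation between the
   corrected amplitude and independently measured anterior abdominal surface
   heights;
2. the rate is a smoothed (Savitzky-Golay) derivative of the amplitude;
3. amplitudes outside the [5th, 95th] percentile range are trimmed as
   outliers;
4. individual breaths are segmented at exhalation minima and collapsed into a
   representative breath (per-phase median, rescaled to the trimmed range);
5. eight phase targets are read off the representative breath at amplitude
   fractions 0, 25, 50, 75, 100 % of (P95 - P5) on the exhalation branch and
   75, 50, 25 % on the inhalation branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    DegenerateCorrelationError,
    InsufficientBreathsError,
    InsufficientDataError,
    NoBreathsDetectedError,
)

PHASE_LABELS = ("0ex", "25ex", "50ex", "75ex", "100", "75in", "50in", "25in")
PHASE_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25)

# percentile convention used everywhere in the package
PERCENTILE_METHOD = "linear"


@dataclass
class BreathingTrace:
    """Uniformly sampled raw bellows trace; optional simulation ground truth."""

    t: np.ndarray  # s, strictly increasing, constant step
    v_raw: np.ndarray  # bellows value, arbitrary units
    A_true: np.ndarray | None = None  # simulator ground truth, a.u.
    Adot_true: np.ndarray | None = None  # simulator ground truth, a.u./s

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v_raw = np.asarray(self.v_raw, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise InsufficientDataError("trace needs at least two samples")
        dt = np.diff(self.t)
        if not np.all(dt > 0):
            raise ValueError("trace times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace must be uniformly sampled")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.v_raw))):
            raise ValueError("trace contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt


@dataclass
class SurrogateSignal:
    """Drift-corrected breathing amplitude and rate with percentile anchors."""

    t: np.ndarray  # s
    A: np.ndarray  # a.u.
    Adot: np.ndarray | None = None  # a.u./s
    drift_intercept: float = 0.0  # d0, a.u.
    drift_slope: float = 0.0  # d1, a.u./s
    abdomen_correlation: float | None = None
    percentiles: dict = field(default_factory=dict)  # {'P5','P85','P95'}

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if not self.percentiles:
            p5, p85, p95 = np.percentile(
                self.A, [5, 85, 95], method=PERCENTILE_METHOD
            )
            self.percentiles = {"P5": float(p5), "P85": float(p85), "P95": float(p95)}

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def interp(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolate (A, Adot) at arbitrary times inside the trace."""
        times = np.asarray(times, dtype=float)
        a = np.interp(times, self.t, self.A)
        adot = np.interp(times, self.t, self.Adot) if self.Adot is not None else np.zeros_like(a)
        return a, adot


@dataclass
class RepresentativeBreath:
    """One summary breath: end-exhale -> peak inhale -> end-exhale.

    ``phase`` is normalized to [0, 1]; the rising branch (Adot >= 0) is
    inhalation, the falling branch (Adot <= 0) exhalation.  Amplitude is
    rescaled so min = P5 and max = P95 of the trimmed trace.
    """

    phase: np.ndarray
    A: np.ndarray
    Adot: np.ndarray
    branch: np.ndarray  # 'inhalation' | 'exhalation' per sample
    period: float  # s, median breath period
    P5: float
    P95: float

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.A))

    def to_dict(self) -> dict:
        return {
            "phase": self.phase.tolist(),
            "A": self.A.tolist(),
            "Adot": self.Adot.tolist(),
            "branch": self.branch.tolist(),
            "period": self.period,
            "P5": self.P5,
            "P95": self.P95,
        }


@dataclass
class PhaseEntry:
    label: str
    fraction: float  # of (P95 - P5)
    A: float  # a.u.
    Adot: float  # a.u./s


@dataclass
class PhaseSpec:
    """The eight phase targets, ordered 0ex..100..25in."""

    entries: list[PhaseEntry]

    def __post_init__(self):
        if len(self.entries) != 8:
            raise ValueError("phase spec must have exactly 8 entries")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def to_json(self) -> str:
        return json.dumps(
            [
                {"label": e.label, "fraction": e.fraction, "A": e.A, "Adot": e.Adot}
                for e in self.entries
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhaseSpec":
        return cls([PhaseEntry(**d) for d in json.loads(text)])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        raise DegenerateCorrelationError("correlation undefined for constant input")
    return float((x * y).sum() / denom)


def correct_drift(
    trace: BreathingTrace,
    abdomen_samples: np.ndarray,
    slope_bound: float | None = None,
    n_grid: int = 201,
) -> SurrogateSignal:
    """Remove linear bellows drift using abdominal surface heights.

    The corrected amplitude is ``A(t) = v_raw(t) - (d0 + d1 t)`` where the
    slope ``d1`` maximizes the Pearson correlation between A at the abdomen
    sample times and the measured surface heights.  The correlation is
    invariant to ``d0``; it is set so that A has zero temporal mean and
    reported for completeness.

    Parameters
    ----------
    abdomen_samples : (n, 2) array of (time s, height mm), n >= 3, spanning
        the trace.
    slope_bound : half-width of the search interval for d1 in a.u./s; by
        default the total signal excursion divided by the trace duration.

    Returns
    -------
    SurrogateSignal with drift parameters and achieved correlation.
    """
    samples = np.asarray(abdomen_samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 3:
        raise InsufficientDataError("need at least 3 abdomen samples")
    ts, hs = samples[:, 0], samples[:, 1]
    if np.ptp(hs) == 0:
        raise DegenerateCorrelationError("abdomen heights are constant")
    v_at = np.interp(ts, trace.t, trace.v_raw)

    if slope_bound is None:
        duration = trace.t[-1] - trace.t[0]
        slope_bound = max(np.ptp(trace.v_raw) / duration, 1e-12)

    def neg_corr(d1: float) -> float:
        return -_pearson(v_at - d1 * ts, hs)

    # coarse grid then golden-section refinement; the objective is smooth in d1
    grid = np.linspace(-slope_bound, slope_bound, n_grid)
    vals = np.array([neg_corr(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(neg_corr, bounds=(lo, hi), method="bounded",
                          options={"xatol": slope_bound * 1e-8})
    d1 = float(res.x)
    if neg_corr(d1) > vals[i]:  # keep the grid optimum if refinement regressed
        d1 = float(grid[i])

    A = trace.v_raw - d1 * trace.t
    d0 = float(A.mean())
    A = A - d0
    corr = _pearson(np.interp(ts, trace.t, A), hs)
    return SurrogateSignal(
        t=trace.t.copy(),
        A=A,
        drift_intercept=d0,
        drift_slope=d1,
        abdomen_correlation=corr,
    )


def compute_rate(
    signal: SurrogateSignal, window_s: float = 0.5, polyorder: int = 3
) -> SurrogateSignal:
    """Fill ``Adot`` with a Savitzky-Golay smoothed derivative of A.

    The window is ``window_s`` seconds (odd number of samples, >= polyorder+2);
    endpoints use the filter's one-sided polynomial extrapolation.
    """
    n = signal.A.size
    win = int(round(window_s / signal.dt))
    win = max(win | 1, polyorder + 2 + ((polyorder + 2) % 2 == 0))
    if win % 2 == 0:
        win += 1
    if n < win:
        raise InsufficientDataError(
            f"trace ({n} samples) shorter than smoothing window ({win})"
        )
    adot = savgol_filter(signal.A, win, polyorder, deriv=1, delta=signal.dt,
                         mode="interp")
    signal.Adot = adot
    return signal


def trim_outliers(signal: SurrogateSignal) -> tuple[np.ndarray, float, float]:
    """Keep samples with A in the closed interval [P5, P95].

    Returns (boolean keep-mask, P5, P95).  Idempotent: trimming the retained
    samples again changes nothing because the anchors come from the full
    signal and are stored on it.
    """
    if signal.A.size < 100:
        raise InsufficientDataError("need at least 100 samples to trim outliers")
    p5 = signal.percentiles["P5"]
    p95 = signal.percentiles["P95"]
    keep = (signal.A >= p5) & (signal.A <= p95)
    return keep, p5, p95


def segment_breaths(
    signal: SurrogateSignal,
    min_breath_duration: float = 1.5,
    prominence_fraction: float = 0.2,
) -> list[tuple[int, int]]:
    """Segment the trace into breaths bounded by exhalation minima.

    Minima must be separated by at least ``min_breath_duration`` seconds and
    have prominence of at least ``prominence_fraction * (P95 - P5)``, which
    suppresses spurious minima inside breath-holds.

    Returns a list of (start_index, end_index) sample-index intervals, one
    per complete breath.
    """
    n = signal.A.size
    if n * signal.dt < min_breath_duration:
        raise NoBreathsDetectedError("trace shorter than one minimum breath")
    span = signal.percentiles["P95"] - signal.percentiles["P5"]
    distance = max(int(round(min_breath_duration / signal.dt)), 1)
    minima, _ = find_peaks(
        -signal.A, distance=distance, prominence=prominence_fraction * max(span, 1e-12)
    )
    if minima.size < 2:
        raise NoBreathsDetectedError("no exhalation minima found")
    return [(int(a), int(b)) for a, b in zip(minima[:-1], minima[1:])]


def build_representative_breath(
    signal: SurrogateSignal,
    breaths: list[tuple[int, int]],
    n_phase: int = 101,
    deriv_window: float = 0.1,
) -> RepresentativeBreath:
    """Collapse segmented breaths into one representative breath.

    Each breath is resampled onto a common normalized phase axis, the
    per-phase median is taken (robust to outlier breaths), and the result is
    rescaled so its minimum is P5 and its maximum P95 of the full signal.
    The rate curve is the smoothed derivative with time scaled by the median
    breath period; the single sample of peak amplitude belongs to the
    inhalation branch by convention.
    """
    if len(breaths) < 3:
        raise InsufficientBreathsError(f"need >= 3 breaths, got {len(breaths)}")
    phase = np.linspace(0.0, 1.0, n_phase)
    resampled = np.empty((len(breaths), n_phase))
    periods = []
    for k, (a, b) in enumerate(breaths):
        seg = signal.A[a : b + 1]
        tau = np.linspace(0.0, 1.0, seg.size)
        resampled[k] = np.interp(phase, tau, seg)
        periods.append((b - a) * signal.dt)
    med = np.median(resampled, axis=0)
    p5 = signal.percentiles["P5"]
    p95 = signal.percentiles["P95"]
    span = med.max() - med.min()
    if span == 0:
        raise InsufficientBreathsError("degenerate (flat) median breath")
    A = (med - med.min()) / span * (p95 - p5) + p5
    period = float(np.median(periods))

    dt_phase = period / (n_phase - 1)
    win = max(int(round(deriv_window / dt_phase)) | 1, 5)
    win = min(win if win % 2 else win + 1, n_phase - 1 if (n_phase - 1) % 2 else n_phase - 2)
    adot = savgol_filter(A, win, 3, deriv=1, delta=dt_phase, mode="interp")

    peak = int(np.argmax(A))
    branch = np.array(
        ["inhalation"] * (peak + 1) + ["exhalation"] * (n_phase - peak - 1)
    )
    return RepresentativeBreath(
        phase=phase, A=A, Adot=adot, branch=branch, period=period, P5=p5, P95=p95
    )


def make_phase_spec(rep: RepresentativeBreath) -> PhaseSpec:
    """Define the eight phase targets from the representative breath.

    Amplitude for fraction f is ``P5 + f * (P95 - P5)``.  The rate for an
    exhalation entry is read from the exhalation branch at that amplitude
    (clipped to <= 0), inhalation entries from the inhalation branch
    (clipped to >= 0); the end-exhale and peak-inhale entries are turning
    points and get rate 0.
    """
    p5, p95 = rep.P5, rep.P95
    peak = rep.peak_index
    # inhalation branch: amplitude rises phase 0 -> peak
    a_in, r_in = rep.A[: peak + 1], rep.Adot[: peak + 1]
    # exhalation branch: amplitude falls peak -> end; reverse so A is increasing
    a_ex, r_ex = rep.A[peak:][::-1], rep.Adot[peak:][::-1]

    entries = []
    for label, f in zip(PHASE_LABELS, PHASE_FRACTIONS):
        amp = p5 + f * (p95 - p5)
        if label in ("0ex", "100"):
            rate = 0.0
        elif label.endswith("ex"):
            rate = min(float(np.interp(amp, a_ex, r_ex)), 0.0)
        else:
            rate = max(float(np.interp(amp, a_in, r_in)), 0.0)
        entries.append(PhaseEntry(label=label, fraction=f, A=float(amp), Adot=rate))
    return PhaseSpec(entries)


def process_trace(
    trace: BreathingTrace,
    abdomen_samples: np.ndarray,
    rate_window_s: float = 1.0,
) -> tuple[SurrogateSignal, RepresentativeBreath, PhaseSpec]:
    """Convenience pipeline: drift correction -> rate -> breaths -> phase spec."""
    signal = correct_drift(trace, abdomen_samples)
    signal = compute_rate(signal, window_s=rate_window_s)
    breaths = segment_breaths(signal)
    rep = build_representative_breath(signal, breaths)
    return signal, rep, make_phase_spec(rep)
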