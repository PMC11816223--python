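"""Surrogate processing: drift correction, rate, trimming, breaths, phases."""

import numpy as np
import pytest

from fivedct.errors import (
    DegenerateCorrelationError,
    InsufficientBreathsError,
    InsufficientDataError,
    NoBreathsDetectedError,
)
from fivedct.phantom import WaveformSpec, generate_waveform
from fivedct.surrogate import (
    PHASE_FRACTIONS,
    PHASE_LABELS,
    SurrogateSignal,
    build_representative_breath,
    compute_rate,
    correct_drift,
    make_phase_spec,
    segment_breaths,
    trim_outliers,
)


def _abdomen_from_trace(trace, gain=8.0, every=100):
    ts = trace.t[::every]
    return np.column_stack([ts, 10.0 + gain * trace.A_true[::every]])


class TestCorrectDrift:
    def test_injected_drift_recovered_within_10pct(self):
        slope = 0.02
        trace = generate_waveform(WaveformSpec(drift_slope=slope, seed=3))
        sig = correct_drift(trace, _abdomen_from_trace(trace))
        assert abs(sig.drift_slope - slope) <= 0.1 * slope
        assert sig.abdomen_correlation > 0.99

    def test_grid_search_oracle_agrees(self):
        """An exhaustive grid over candidate slopes finds the same optimum."""
        trace = generate_waveform(WaveformSpec(drift_slope=0.015, seed=5))
        abdomen = _abdomen_from_trace(trace)
        sig = correct_drift(trace, abdomen)
        ts, hs = abdomen[:, 0], abdomen[:, 1]
        v_at = np.interp(ts, trace.t, trace.v_raw)
        grid = np.linspace(-0.05, 0.05, 5001)
        corrs = [np.corrcoef(v_at - g * ts, hs)[0, 1] for g in grid]
        best = grid[int(np.argmax(corrs))]
        assert abs(sig.drift_slope - best) < 2e-4

    def test_zero_drift_is_a_noop_up_to_constant(self):
        trace = generate_waveform(WaveformSpec(drift_slope=0.0, noise_sd=0.0, seed=2))
        sig = correct_drift(trace, _abdomen_from_trace(trace))
        assert abs(sig.drift_slope) < 1e-4
        shifted = sig.A - (trace.v_raw - trace.v_raw.mean())
        assert np.allclose(shifted, shifted[0], atol=1e-2)

    def test_constant_abdomen_heights_raise(self):
        trace = generate_waveform(WaveformSpec(seed=1))
        samples = np.column_stack([trace.t[::100], np.full(trace.t[::100].size, 5.0)])
        with pytest.raises(DegenerateCorrelationError):
            correct_drift(trace, samples)

    def test_too_few_samples_raise(self):
        trace = generate_waveform(WaveformSpec(seed=1))
        with pytest.raises(InsufficientDataError):
            correct_drift(trace, np.array([[0.0, 1.0], [1.0, 2.0]]))


class TestComputeRate:
    def test_constant_signal_has_zero_rate(self):
        t = np.arange(0, 30, 0.02)
        sig = compute_rate(SurrogateSignal(t=t, A=np.full(t.size, 3.0)))
        assert np.allclose(sig.Adot, 0.0, atol=1e-12)

    def test_sinusoid_matches_analytic_derivative(self):
        t = np.arange(0, 60, 0.01)
        sig = compute_rate(SurrogateSignal(t=t, A=np.sin(2 * np.pi * t / 4)))
        expected = (2 * np.pi / 4) * np.cos(2 * np.pi * t / 4)
        peak = np.abs(expected).max()
        assert np.max(np.abs(sig.Adot - expected)) < 0.01 * peak

    def test_time_reversal_negates_rate(self):
        t = np.arange(0, 20, 0.02)
        A = np.sin(t) + 0.3 * np.sin(2.7 * t)
        fwd = compute_rate(SurrogateSignal(t=t, A=A))
        rev = compute_rate(SurrogateSignal(t=t, A=A[::-1]))
        assert np.allclose(rev.Adot, -fwd.Adot[::-1], atol=1e-9)

    def test_short_trace_raises(self):
        t = np.arange(0, 0.2, 0.01)
        with pytest.raises(InsufficientDataError):
            compute_rate(SurrogateSignal(t=t, A=np.sin(t)), window_s=1.0)


class TestTrimOutliers:
    def test_uniform_samples_percentiles_and_fraction(self):
        t = np.arange(1001) * 0.1
        A = np.linspace(0, 1, 1001)
        sig = SurrogateSignal(t=t, A=A)
        keep, p5, p95 = trim_outliers(sig)
        assert p5 == pytest.approx(0.05)
        assert p95 == pytest.approx(0.95)
        assert abs(keep.mean() - 0.90) <= 1.5 / 1001

    def test_degenerate_distribution_keeps_everything(self):
        t = np.arange(200) * 0.1
        sig = SurrogateSignal(t=t, A=np.full(200, 2.0))
        keep, p5, p95 = trim_outliers(sig)
        assert p5 == p95 == 2.0
        assert keep.all()

    def test_single_spike_excluded(self):
        rng = np.random.default_rng(0)
        A = rng.normal(0, 1, 10_000)
        A[5000] = 50.0
        sig = SurrogateSignal(t=np.arange(10_000) * 0.02, A=A)
        keep, _, p95 = trim_outliers(sig)
        # sorting oracle for the 95th percentile
        srt = np.sort(A)
        k = 0.95 * (A.size - 1)
        oracle = srt[int(k)] + (k - int(k)) * (srt[int(k) + 1] - srt[int(k)])
        assert p95 == pytest.approx(oracle)
        assert not keep[5000]

    def test_idempotent_with_anchored_percentiles(self):
        rng = np.random.default_rng(1)
        sig = SurrogateSignal(t=np.arange(500) * 0.1, A=rng.normal(0, 1, 500))
        keep, p5, p95 = trim_outliers(sig)
        again = (sig.A[keep] >= p5) & (sig.A[keep] <= p95)
        assert again.all()


class TestSegmentBreaths:
    def test_sinusoid_breath_count(self):
        t = np.arange(0, 60, 0.01)
        sig = SurrogateSignal(t=t, A=np.sin(2 * np.pi * t / 4))
        breaths = segment_breaths(sig)
        assert len(breaths) in (14, 15)

    def test_monotone_ramp_raises(self):
        t = np.arange(0, 30, 0.01)
        sig = SurrogateSignal(t=t, A=0.1 * t)
        with pytest.raises(NoBreathsDetectedError):
            segment_breaths(sig)

    def test_breath_hold_produces_no_spurious_minima(self):
        dt = 0.01
        part = np.sin(2 * np.pi * np.arange(0, 20, dt) / 4)
        rng = np.random.default_rng(4)
        hold = 0.002 * rng.standard_normal(int(10 / dt))  # 10 s quiet exhale
        A = np.concatenate([part, hold, part])
        sig = SurrogateSignal(t=np.arange(A.size) * dt, A=A)
        breaths = segment_breaths(sig)
        bounds = sorted({i for ab in breaths for i in ab})
        hold_lo, hold_hi = part.size + 200, part.size + hold.size - 200
        inside_hold = [b for b in bounds if hold_lo < b < hold_hi]
        assert inside_hold == []


class TestRepresentativeBreath:
    def _signal(self, n_breaths=10, period=4.0, dt=0.01, outlier=None):
        t = np.arange(0, n_breaths * period, dt)
        A = 0.5 * (1 - np.cos(2 * np.pi * t / period))
        if outlier is not None:
            k, scale = outlier
            sel = (t >= k * period) & (t < (k + 1) * period)
            A[sel] *= scale
        return compute_rate(SurrogateSignal(t=t, A=A))

    def test_regular_breathing_spans_trimmed_range(self):
        sig = self._signal()
        rep = build_representative_breath(sig, segment_breaths(sig))
        assert rep.A.min() == pytest.approx(sig.percentiles["P5"])
        assert rep.A.max() == pytest.approx(sig.percentiles["P95"])
        assert np.sum(np.diff(np.sign(np.diff(rep.A))) != 0) <= 2  # single hump

    def test_median_is_robust_to_one_deep_breath(self):
        clean = self._signal()
        rep_clean = build_representative_breath(clean, segment_breaths(clean))
        dirty = self._signal(outlier=(4, 1.8))
        rep_dirty = build_representative_breath(dirty, segment_breaths(dirty))
        # compare shapes normalized to their own trimmed span
        norm = lambda r: (r.A - r.A.min()) / (r.A.max() - r.A.min())
        assert np.max(np.abs(norm(rep_clean) - norm(rep_dirty))) < 0.05

    def test_too_few_breaths_raise(self):
        sig = self._signal(n_breaths=3)  # only one complete min-to-min interval
        with pytest.raises(InsufficientBreathsError):
            build_representative_breath(sig, segment_breaths(sig))


class TestPhaseSpec:
    def _rep(self):
        sig = TestRepresentativeBreath()._signal()
        return build_representative_breath(sig, segment_breaths(sig))

    def test_eight_entries_with_canonical_fractions(self):
        spec = make_phase_spec(self._rep())
        assert tuple(e.label for e in spec) == PHASE_LABELS
        assert tuple(e.fraction for e in spec) == PHASE_FRACTIONS

    def test_amplitudes_are_linear_in_fraction(self):
        rep = self._rep()
        rep.P5, rep.P95 = 0.0, 2.0
        rep.A = (rep.A - rep.A.min()) / (rep.A.max() - rep.A.min()) * 2.0
        spec = make_phase_spec(rep)
        assert [e.A for e in spec] == pytest.approx([0, 0.5, 1.0, 1.5, 2.0, 1.5, 1.0, 0.5])

    def test_branch_rate_signs(self):
        spec = make_phase_spec(self._rep())
        by = {e.label: e for e in spec}
        assert by["25ex"].A == by["25in"].A
        assert by["25ex"].Adot <= 0.0 <= by["25in"].Adot
        assert by["0ex"].Adot == 0.0 and by["100"].Adot == 0.0

    def test_amplitude_ordering_over_the_cycle(self):
        amps = [e.A for e in make_phase_spec(self._rep())]
        assert np.all(np.diff(amps[:5]) >= 0)
        assert np.all(np.diff(amps[4:]) <= 0)


class TestTrimProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_retained_fraction_and_anchor_order(self, seed):
        rng = np.random.default_rng(seed)
        sig = SurrogateSignal(t=np.arange(300) * 0.1,
                              A=rng.normal(0, 1 + seed % 3, 300))
        keep, p5, p95 = trim_outliers(sig)
        assert p5 <= sig.percentiles["P85"] <= p95
        assert 0.85 <= keep.mean() <= 0.95
        assert sig.A[keep].min() >= p5 and sig.A[keep].max() <= p95


def test_noiseless_trace_correlates_with_truth():
    trace = generate_waveform(WaveformSpec(noise_sd=0.0, seed=6))
    sig = correct_drift(trace, _abdomen_from_trace(trace))
    assert np.corrcoef(sig.A, trace.A_true)[0, 1] > 0.999
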