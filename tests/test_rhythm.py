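"""Correlation statistics, burst detection and alternation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tailbeat.errors import (
    DegenerateSignalError,
    InsufficientEventsError,
    NotRhythmicError,
    ParameterError,
)
from tailbeat.rhythm import (
    BurstSequence,
    alternation_index,
    analyze_trace,
    autocorrelation,
    contralateral_phase,
    cross_correlation,
    detect_bursts,
    locomotor_period,
)
from tailbeat.trace import BilateralTrace, make_time_grid

from conftest import circular_diff, sine_pair

RATE = 500.0


def sine(freq_hz, n=5000, rate=RATE):
    return np.sin(2 * np.pi * freq_hz * make_time_grid(n, rate))


class TestAutocorrelation:
    def test_zero_lag_is_one(self):
        acf = autocorrelation(sine(10), RATE, 0.5)
        assert acf.values[acf.lags == 0][0] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_in_lag(self):
        acf = autocorrelation(sine(10) + 0.3 * sine(17), RATE, 0.4)
        np.testing.assert_allclose(acf.values, acf.values[::-1], atol=1e-12)

    def test_sine_first_local_maximum_at_period(self):
        acf = autocorrelation(sine(10), RATE, 0.5)
        pos = acf.lags > 0
        v = acf.values[pos]
        local_max = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]))[0] + 1
        first = acf.lags[pos][local_max[0]]
        assert abs(first - 0.100) <= 1.0 / RATE

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            autocorrelation(np.full(2000, 3.7), RATE, 0.5)

    def test_white_noise_stays_below_band(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=5000)
        acf = autocorrelation(x, RATE, 0.5)
        nonzero = acf.lags != 0
        # white noise: all non-zero-lag values within the 95% band (allow the
        # expected handful of grazing exceedances out of ~500 lags)
        frac_out = np.mean(np.abs(acf.values[nonzero]) > acf.noise_band)
        assert frac_out < 0.10

    def test_too_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            autocorrelation(sine(10, n=100), RATE, 0.5)


class TestLocomotorPeriod:
    @pytest.mark.parametrize("freq,expected", [(10.0, 0.1), (12.24, 1 / 12.24)])
    def test_sine_period(self, freq, expected):
        acf = autocorrelation(sine(freq), RATE, 0.5)
        assert locomotor_period(acf) == pytest.approx(expected, rel=0.005)

    def test_noisy_sine_matches_fft_oracle(self):
        rng = np.random.default_rng(7)
        x = sine(12.0) + rng.normal(0, 1 / 3, 5000)   # SNR ~ 3 on SD scale
        acf = autocorrelation(x, RATE, 0.5)
        period = locomotor_period(acf)
        # FFT dominant-frequency oracle
        spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
        freqs = np.fft.rfftfreq(len(x), 1 / RATE)
        f_fft = freqs[np.argmax(spec)]
        assert abs(period - 1 / f_fft) <= 0.5 / RATE

    def test_white_noise_not_rhythmic(self):
        rng = np.random.default_rng(3)
        acf = autocorrelation(rng.normal(size=5000), RATE, 0.5)
        with pytest.raises(NotRhythmicError):
            locomotor_period(acf)


class TestCrossCorrelation:
    def test_identical_channels_peak_one_at_zero(self):
        x = sine(10) + 0.1 * sine(23)
        xcf = cross_correlation(x, x, RATE, 0.5)
        k = np.argmax(xcf.values)
        assert xcf.lags[k] == 0.0
        assert xcf.values[k] == pytest.approx(1.0, abs=1e-12)

    def test_delayed_copy_peak_at_delay(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=6000)
        delay = 37
        y = np.roll(x, delay)   # y lags x by `delay` samples
        xcf = cross_correlation(x, y, RATE, 0.5)
        k = np.argmax(xcf.values)
        assert abs(xcf.lags[k] - delay / RATE) <= 1.0 / RATE

    def test_independent_noise_below_surrogate_band(self):
        from tailbeat.rhythm import surrogate_xcorr_maxima

        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(2, 4000))
        xcf = cross_correlation(a, b, RATE, 0.25)
        window = (xcf.lags > 0) & (xcf.lags <= 0.1)
        observed = np.max(np.abs(xcf.values[window]))
        surr = surrogate_xcorr_maxima(a, b, RATE, 0.25, 0.1,
                                      n_surrogates=99, seed=2)
        assert observed <= np.percentile(surr, 95) * 1.05

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            cross_correlation(np.zeros(4000), sine(10, n=4000), RATE, 0.5)


class TestContralateralPhase:
    @pytest.mark.parametrize("delay,expected", [
        (0.0, 0.0), (0.5, 0.5), (0.46, 0.54),
    ])
    def test_constructed_delays(self, delay, expected):
        tr = sine_pair(12.0, delay)
        ph = contralateral_phase(tr, seed=0)
        assert circular_diff(ph.phase, expected) <= (1 / RATE) * 12.0 + 1e-3

    def test_phase_matches_hilbert_oracle_on_noisy_sines(self):
        from scipy.signal import hilbert

        tr = sine_pair(14.0, 0.43, noise_sd=0.2, seed=21)
        ph = contralateral_phase(tr, seed=0)
        dphi = np.angle(np.mean(np.exp(1j * (
            np.angle(hilbert(tr.left - tr.left.mean()))
            - np.angle(hilbert(tr.right - tr.right.mean()))
        ))))
        oracle = (-dphi / (2 * np.pi)) % 1.0
        assert circular_diff(ph.phase, oracle) <= 0.03

    def test_not_rhythmic_left_raises(self):
        rng = np.random.default_rng(1)
        t = make_time_grid(4000, RATE)
        tr = BilateralTrace(t=t, left=rng.normal(size=4000),
                            right=sine(12, n=4000), rate_hz=RATE)
        with pytest.raises(NotRhythmicError):
            contralateral_phase(tr, seed=0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        freq=st.floats(10.0, 25.0),
        delay=st.floats(0.05, 0.95),
        extra=st.floats(0.02, 0.3),
    )
    def test_phase_equivariance_under_extra_delay(self, freq, delay, extra):
        """Delaying the right channel by delta shifts phi by -delta/T mod 1."""
        base = contralateral_phase(sine_pair(freq, delay), seed=0)
        shifted = contralateral_phase(sine_pair(freq, delay + extra), seed=0)
        expected = (base.phase - extra) % 1.0
        tol = freq / RATE + 5e-3
        assert circular_diff(shifted.phase, expected) <= tol

    def test_amplitude_offset_invariance(self):
        tr = sine_pair(12.0, 0.46)
        scaled = BilateralTrace(t=tr.t, left=tr.left,
                                right=3.2 * tr.right + 7.0, rate_hz=RATE)
        p1 = contralateral_phase(tr, seed=0)
        p2 = contralateral_phase(scaled, seed=0)
        assert circular_diff(p1.phase, p2.phase) <= 1e-9
        assert p1.period_s == pytest.approx(p2.period_s, abs=1e-12)

    def test_channel_swap_mirrors_phase(self):
        tr = sine_pair(12.0, 0.46)
        p1 = contralateral_phase(tr, seed=0)
        p2 = contralateral_phase(tr.swapped(), seed=0)
        assert circular_diff(p2.phase, (1 - p1.phase) % 1.0) <= 12.0 / RATE + 1e-3


class TestBursts:
    def test_flat_signal_no_bursts(self):
        assert len(detect_bursts(np.zeros(2000), RATE)) == 0

    def test_three_rect_pulses(self):
        x = np.zeros(3000)
        starts = [400, 1400, 2400]
        for s in starts:
            x[s:s + 100] = 1.0
        onsets = detect_bursts(x, RATE, period_hint_s=2.0)
        assert len(onsets) == 3
        for onset, s in zip(onsets, starts):
            assert abs(onset - s / RATE) <= 1.5 / RATE

    def test_intact_burst_count_matches_zero_crossing_oracle(self, intact_trace):
        x = intact_trace.left
        acf = autocorrelation(x, RATE, 0.5)
        period = locomotor_period(acf)
        onsets = detect_bursts(x, RATE, period_hint_s=period)
        xm = x - x.mean()
        cycles = int(np.sum((xm[:-1] < 0) & (xm[1:] >= 0)))
        assert abs(len(onsets) - cycles) <= 0.1 * cycles


class TestAlternation:
    def test_strict_alternation(self):
        seq = BurstSequence([(i * 0.1, "LR"[i % 2]) for i in range(6)])
        assert alternation_index(seq) == 1.0

    def test_run_pattern(self):
        # uncoupled-style runs: only the single L->R switch alternates
        sides = ["L", "L", "L", "R", "R", "R"]
        seq = BurstSequence([(i * 0.1, s) for i, s in enumerate(sides)])
        assert alternation_index(seq) == pytest.approx(0.2)

    def test_random_sides_near_half(self):
        rng = np.random.default_rng(42)
        sides = rng.choice(["L", "R"], size=10_000)
        seq = BurstSequence([(i * 0.01, s) for i, s in enumerate(sides)])
        assert alternation_index(seq) == pytest.approx(0.5, abs=0.02)

    def test_too_few_events(self):
        with pytest.raises(InsufficientEventsError):
            alternation_index(BurstSequence([(0.0, "L")]))


class TestAnalyzeTrace:
    def test_intact_summary(self, intact_trace):
        s = analyze_trace(intact_trace, seed=4)
        assert s.period_defined and s.phase_defined
        assert s.alternation_index > 0.9
        assert s.frequency_hz * s.period_s == pytest.approx(1.0, abs=1e-9)

    def test_strychnine_summary(self, strychnine_trace):
        s = analyze_trace(strychnine_trace, seed=4)
        assert s.period_defined
        assert not s.phase_defined and s.phase is None
        assert 11.2 <= s.frequency_hz <= 13.3
        assert s.notes   # reason logged

    def test_single_sample_trace_rejected(self):
        with pytest.raises(ParameterError):
            BilateralTrace(t=np.array([0.0]), left=np.array([1.0]),
                           right=np.array([1.0]), rate_hz=RATE)

    def test_arrhythmic_input_does_not_raise(self):
        rng = np.random.default_rng(0)
        t = make_time_grid(2000, RATE)
        tr = BilateralTrace(t=t, left=rng.normal(size=2000),
                            right=rng.normal(size=2000), rate_hz=RATE)
        s = analyze_trace(tr, seed=0)
        assert not s.period_defined and not s.phase_defined
        assert s.notes
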