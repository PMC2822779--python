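"""Rhythm statistics: locomotor period, contralateral phase, burst alternation.

The locomotor period is read from the autocorrelation of the left-side trace
(lag of its first significant positive-lag maximum).  The contralateral phase
is the normalized offset between that autocorrelation peak and the peak of the
left/right cross-correlation:

    phi = ((T - tau_x) / T) mod 1

where ``T`` is the period and ``tau_x`` the cross-correlation peak lag searched
in ``(0, T]``.  The cross-correlation convention is ``C(tau)`` correlating
``left(t)`` with ``right(t + tau)``, so positive ``tau`` means the right side
lags the left.  Perfect antiphase gives ``phi = 0.5``; in-phase gives 0.

A phase is only reported when the cross-correlation peak beats a circular-shift
surrogate ensemble: shifting one channel by a random circular offset preserves
each side's rhythmicity while destroying any genuine coupling, so the surrogate
maxima describe the peak height expected from two uncoupled rhythms.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateSignalError,
    InsufficientEventsError,
    NotRhythmicError,
    ParameterError,
)
from .trace import BilateralTrace

__all__ = [
    "CorrelationFunction",
    "RhythmSummary",
    "BurstSequence",
    "PhaseResult",
    "autocorrelation",
    "cross_correlation",
    "locomotor_period",
    "contralateral_phase",
    "detect_bursts",
    "alternation_index",
    "analyze_trace",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class CorrelationFunction:
    """A lag-domain correlation curve, symmetric about lag zero.

    ``values`` are correlation coefficients (biased, mean-subtracted,
    variance-normalized estimator), so an autocorrelation is exactly 1 at
    lag 0 and ``|values| <= 1`` up to rounding.
    """

    lags: np.ndarray          # seconds, strictly increasing, symmetric about 0
    values: np.ndarray
    kind: str                 # "auto" | "cross"
    rate_hz: float
    n_samples: int            # length of the underlying signal(s)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("auto", "cross"):
            raise ParameterError("kind: must be 'auto' or 'cross'")
        if len(self.lags) != len(self.values):
            raise ParameterError("lags/values: length mismatch")
        if np.any(np.diff(self.lags) <= 0):
            raise ParameterError("lags: must be strictly increasing")

    @property
    def noise_band(self) -> float:
        """95% white-noise band for correlation coefficients, 1.96/sqrt(N)."""
        return 1.96 / np.sqrt(self.n_samples)


@dataclass
class BurstSequence:
    """Ordered, timestamped burst labels, e.g. L/R/L/R during swimming."""

    events: list[tuple[float, str]]

    def __post_init__(self) -> None:
        for _, side in self.events:
            if side not in ("L", "R"):
                raise ParameterError(f"side: must be 'L' or 'R', got {side!r}")
        times = [t for t, _ in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ParameterError("events: times must be non-decreasing")

    @classmethod
    def from_onsets(
        cls, left_onsets: np.ndarray, right_onsets: np.ndarray
    ) -> "BurstSequence":
        events = [(float(t), "L") for t in left_onsets] + [
            (float(t), "R") for t in right_onsets
        ]
        events.sort(key=lambda e: e[0])
        return cls(events)

    def sides(self) -> str:
        return "".join(side for _, side in self.events)


@dataclass
class PhaseResult:
    """Contralateral phase statistic plus its surrogate significance.

    ``phase`` is always the computed statistic ``((T - tau_x)/T) mod 1``;
    ``phase_defined`` says whether the cross-correlation peak beat the
    circular-shift surrogates, i.e. whether the phase should be *reported*
    (summaries expose the phase only when defined).  The distinction matters
    for deterministic periodic signals, where the phase statistic is exact
    but a single trace cannot prove genuine coupling over coincidence.
    """

    phase: float
    phase_defined: bool
    p_value: float
    xcorr_peak_value: float
    period_s: float


@dataclass
class RhythmSummary:
    """Per-trace rhythm report: period, frequency, phase, burst alternation."""

    condition: str = ""
    period_s: float | None = None
    frequency_hz: float | None = None
    period_defined: bool = False
    phase: float | None = None
    phase_defined: bool = False
    xcorr_peak_value: float | None = None
    xcorr_significance: float | None = None
    alternation_index: float | None = None
    n_bursts_left: int = 0
    n_bursts_right: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "period_s": self.period_s,
            "frequency_hz": self.frequency_hz,
            "period_defined": self.period_defined,
            "phase": self.phase,
            "phase_defined": self.phase_defined,
            "xcorr_peak_value": self.xcorr_peak_value,
            "xcorr_significance": self.xcorr_significance,
            "alternation_index": self.alternation_index,
            "n_bursts_left": self.n_bursts_left,
            "n_bursts_right": self.n_bursts_right,
            "notes": list(self.notes),
        }


# ---------------------------------------------------------------------------
# correlation estimators
# ---------------------------------------------------------------------------
def _check_signal(x: np.ndarray, rate_hz: float, max_lag_s: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ParameterError("signal contains non-finite values")
    if rate_hz <= 0:
        raise ParameterError("rate_hz: must be positive")
    if max_lag_s <= 0:
        raise ParameterError("max_lag_s: must be positive")
    if len(x) < 2 * max_lag_s * rate_hz:
        raise ParameterError(
            f"signal too short: need >= {2 * max_lag_s * rate_hz:.0f} samples "
            f"for max_lag_s={max_lag_s}, got {len(x)}"
        )
    return x


def autocorrelation(
    x: np.ndarray, rate_hz: float, max_lag_s: float = 0.5
) -> CorrelationFunction:
    """Biased, mean-subtracted autocorrelation, normalized to 1 at lag zero.

    Raises :class:`DegenerateSignalError` on a constant signal.
    """
    x = _check_signal(x, rate_hz, max_lag_s)
    xc = x - x.mean()
    if np.allclose(xc, 0.0):
        raise DegenerateSignalError("constant signal: autocorrelation undefined")
    n = len(x)
    max_k = int(round(max_lag_s * rate_hz))
    full = sps.correlate(xc, xc, mode="full", method="fft")
    mid = n - 1
    c = full[mid - max_k : mid + max_k + 1] / full[mid]
    lags = np.arange(-max_k, max_k + 1) / rate_hz
    return CorrelationFunction(lags=lags, values=c, kind="auto",
                               rate_hz=rate_hz, n_samples=n)


def cross_correlation(
    left: np.ndarray,
    right: np.ndarray,
    rate_hz: float,
    max_lag_s: float = 0.5,
) -> CorrelationFunction:
    """Normalized cross-correlation: ``C(tau)`` correlates ``left(t)`` with
    ``right(t + tau)`` (positive ``tau`` = right lags left).

    Biased estimator (divide by N) normalized by the product of the two SDs,
    so values are correlation coefficients.
    """
    left = _check_signal(left, rate_hz, max_lag_s)
    right = _check_signal(right, rate_hz, max_lag_s)
    if len(left) != len(right):
        raise ParameterError("left/right: lengths differ")
    lc = left - left.mean()
    rc = right - right.mean()
    denom = np.sqrt(np.sum(lc * lc) * np.sum(rc * rc))
    if denom == 0.0 or np.allclose(lc, 0.0) or np.allclose(rc, 0.0):
        raise DegenerateSignalError("zero-variance input: cross-correlation undefined")
    n = len(left)
    max_k = int(round(max_lag_s * rate_hz))
    full = sps.correlate(rc, lc, mode="full", method="fft")
    mid = n - 1
    c = full[mid - max_k : mid + max_k + 1] / denom
    lags = np.arange(-max_k, max_k + 1) / rate_hz
    return CorrelationFunction(lags=lags, values=c, kind="cross",
                               rate_hz=rate_hz, n_samples=n)


# ---------------------------------------------------------------------------
# peak handling
# ---------------------------------------------------------------------------
def _parabolic_refine(values: np.ndarray, k: int) -> tuple[float, float]:
    """3-point parabolic interpolation around index ``k``.

    Returns (fractional index, interpolated value); falls back to the sample
    itself at array edges or a degenerate curvature.
    """
    if k <= 0 or k >= len(values) - 1:
        return float(k), float(values[k])
    a, b, c = values[k - 1], values[k], values[k + 1]
    denom = a - 2 * b + c
    if denom >= 0 or abs(denom) < 1e-300:
        return float(k), float(b)
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = b - 0.25 * (a - c) * delta
    return k + delta, float(value)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateau ties break toward the smaller index."""
    v = values
    idx = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]))[0] + 1
    return idx


def locomotor_period(acf: CorrelationFunction) -> float:
    """Locomotor period: lag of the first significant positive-lag maximum of
    the autocorrelation, refined by 3-point parabolic interpolation.

    A maximum counts only after the autocorrelation has passed through a local
    minimum (so the shoulder of the zero-lag peak is never picked), and must
    exceed the white-noise significance band.  Because the peak is searched
    over all positive lags, the band is Bonferroni-corrected for the number
    of lags inspected (``z_{1-0.025/M}/sqrt(N)``); the pointwise 95% band
    would flag spurious maxima on every white-noise trace.

    Raises :class:`NotRhythmicError` if no such maximum exists.
    """
    if acf.kind != "auto":
        raise ParameterError("locomotor_period expects an autocorrelation")
    pos = acf.lags > 0
    v = acf.values[pos]
    lags = acf.lags[pos]
    maxima = _local_maxima(v)
    minima = _local_maxima(-v)
    first_min = minima[0] if len(minima) else None
    from scipy import stats as _stats
    band = float(_stats.norm.ppf(1 - 0.025 / max(len(v), 1))
                 / np.sqrt(acf.n_samples))
    for k in maxima:
        if first_min is not None and k < first_min:
            continue
        if v[k] <= band:
            continue
        # refine on the positive-lag segment
        frac_idx, _ = _parabolic_refine(v, int(k))
        dt = 1.0 / acf.rate_hz
        period = lags[0] + frac_idx * dt
        if period <= 0:
            continue
        return float(period)
    raise NotRhythmicError(
        "no significant positive-lag autocorrelation maximum "
        f"(95% band = {band:.4f})"
    )


def _windowed_xcorr_peak(
    xcf: CorrelationFunction, period_s: float
) -> tuple[float, float]:
    """Peak of the cross-correlation in the window ``(0, T]``.

    Returns (tau_x in s, peak value).  The search window extends half a sample
    past ``T`` so a peak sitting exactly at the period lag is not lost to
    rounding.
    """
    dt = 1.0 / xcf.rate_hz
    in_window = (xcf.lags > 0) & (xcf.lags <= period_s + 0.5 * dt)
    if not np.any(in_window):
        raise NotRhythmicError("cross-correlation window (0, T] is empty")
    idx = np.nonzero(in_window)[0]
    k_best = idx[np.argmax(xcf.values[idx])]
    frac_idx, value = _parabolic_refine(xcf.values, int(k_best))
    tau_x = xcf.lags[0] + frac_idx * dt
    return float(tau_x), float(value)


# ---------------------------------------------------------------------------
# surrogate significance
# ---------------------------------------------------------------------------
def surrogate_xcorr_maxima(
    left: np.ndarray,
    right: np.ndarray,
    rate_hz: float,
    max_lag_s: float,
    period_s: float,
    n_surrogates: int = 199,
    seed: int | None = 0,
) -> np.ndarray:
    """Max |cross-correlation| in ``(0, T]`` for circular-shift surrogates.

    Each surrogate circularly shifts the right channel by a random offset,
    preserving both autocorrelations but destroying genuine left-right
    coupling.
    """
    rng = np.random.default_rng(seed)
    n = len(right)
    maxima = np.empty(n_surrogates)
    for i in range(n_surrogates):
        shift = int(rng.integers(1, n))
        surr = np.roll(right, shift)
        xcf = cross_correlation(left, surr, rate_hz, max_lag_s)
        dt = 1.0 / rate_hz
        in_window = (xcf.lags > 0) & (xcf.lags <= period_s + 0.5 * dt)
        maxima[i] = np.max(np.abs(xcf.values[in_window]))
    return maxima


def contralateral_phase(
    trace: BilateralTrace,
    max_lag_s: float = 0.5,
    n_surrogates: int = 199,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> PhaseResult:
    """Contralateral phase of a bilateral trace with surrogate significance.

    With ``T`` the left-side locomotor period (= lag of the first positive-lag
    autocorrelation maximum) and ``tau_x`` the cross-correlation peak in
    ``(0, T]``: ``phi = ((T - tau_x)/T) mod 1``.  ``phase_defined`` is True
    only when the observed peak exceeds the 95th percentile of circular-shift
    surrogate maxima (at the given ``alpha``); the phase statistic itself is
    always computed.

    Raises :class:`NotRhythmicError` if the left side has no significant
    autocorrelation peak.
    """
    acf = autocorrelation(trace.left, trace.rate_hz, max_lag_s)
    period_s = locomotor_period(acf)   # raises NotRhythmicError if arrhythmic
    xcf = cross_correlation(trace.left, trace.right, trace.rate_hz, max_lag_s)
    tau_x, peak = _windowed_xcorr_peak(xcf, period_s)
    surr = surrogate_xcorr_maxima(
        trace.left, trace.right, trace.rate_hz, max_lag_s, period_s,
        n_surrogates=n_surrogates, seed=seed,
    )
    p_value = (1 + int(np.sum(surr >= peak))) / (len(surr) + 1)
    defined = p_value <= alpha
    phase = float(((period_s - tau_x) / period_s) % 1.0)
    return PhaseResult(
        phase=phase,
        phase_defined=defined,
        p_value=float(p_value),
        xcorr_peak_value=peak,
        period_s=period_s,
    )


# ---------------------------------------------------------------------------
# bursts & alternation
# ---------------------------------------------------------------------------
def detect_bursts(
    x: np.ndarray,
    rate_hz: float,
    period_hint_s: float | None = None,
    smooth_s: float = 0.010,
    height_frac: float = 0.10,
) -> np.ndarray:
    """Burst onset times from amplitude-envelope peak detection.

    The envelope is the half-wave rectified signal relative to a local
    baseline (moving average over two periods, or the global mean if no
    period is known), smoothed with a causal 10 ms boxcar.  Burst peaks are
    envelope maxima above ``height_frac`` of its 95th percentile, separated
    by at least ``0.6 * T``; each onset is found by walking the peak back to
    where the envelope first rose above that height.  ``T`` is
    ``period_hint_s``, else the autocorrelation period if one exists, else
    50 ms.  A flat signal yields an empty array.

    Anchoring onsets at envelope peaks rather than raw threshold crossings
    keeps weak cycles (the rhythm's amplitude fluctuates) from being dropped.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ParameterError("signal contains non-finite values")
    if len(x) < 2:
        return np.array([])
    if period_hint_s is None:
        try:
            max_lag = min(0.5, 0.45 * len(x) / rate_hz)
            period_hint_s = locomotor_period(
                autocorrelation(x, rate_hz, max_lag))
        except (NotRhythmicError, DegenerateSignalError, ParameterError):
            period_hint_s = None
    if period_hint_s is not None:
        w_base = max(1, int(round(2.0 * period_hint_s * rate_hz)))
        baseline = np.convolve(x, np.ones(w_base) / w_base, mode="same")
    else:
        baseline = x.mean()
    env = np.maximum(x - baseline, 0.0)
    w = max(1, int(round(smooth_s * rate_hz)))
    if w > 1:
        env = np.convolve(env, np.ones(w) / w, mode="full")[: len(env)]
    height = height_frac * np.percentile(env, 95)
    if height <= 0:
        return np.array([])
    min_sep_s = 0.6 * period_hint_s if period_hint_s else 0.050
    peaks, _ = sps.find_peaks(
        env, height=height, distance=max(1, int(round(min_sep_s * rate_hz))))
    onsets: list[int] = []
    for pk in peaks:
        k = int(pk)
        while k > 0 and env[k - 1] > height:
            k -= 1
        if not onsets or k > onsets[-1]:
            onsets.append(k)
    return np.asarray(onsets, dtype=float) / rate_hz


def alternation_index(seq: BurstSequence) -> float:
    """Fraction of consecutive burst pairs whose sides differ.

    1.0 is strict L/R alternation; uncoupled sides that fire in runs
    (L/L/L/R/R/R) score lower.  Raises :class:`InsufficientEventsError` with
    fewer than two events.
    """
    sides = seq.sides()
    if len(sides) < 2:
        raise InsufficientEventsError(
            f"need >= 2 burst events, got {len(sides)}")
    switches = sum(a != b for a, b in zip(sides, sides[1:]))
    return switches / (len(sides) - 1)


# ---------------------------------------------------------------------------
# per-trace report
# ---------------------------------------------------------------------------
def analyze_trace(
    trace: BilateralTrace,
    max_lag_s: float = 0.5,
    n_surrogates: int = 199,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> RhythmSummary:
    """Full per-trace rhythm report.

    Never raises on a non-rhythmic or uncoupled trace: the corresponding
    ``*_defined`` flags are False and the reason is appended to ``notes``.
    Malformed traces still raise a validation error.
    """
    trace.validate()
    out = RhythmSummary(condition=trace.condition)
    max_lag_s = min(max_lag_s, 0.45 * len(trace) / trace.rate_hz)
    period_s = None
    try:
        acf = autocorrelation(trace.left, trace.rate_hz, max_lag_s)
        period_s = locomotor_period(acf)
        out.period_s = period_s
        out.frequency_hz = 1.0 / period_s
        out.period_defined = True
    except (DegenerateSignalError, NotRhythmicError) as err:
        out.notes.append(f"period undefined: {err}")
    if period_s is not None:
        try:
            ph = contralateral_phase(
                trace, max_lag_s=max_lag_s, n_surrogates=n_surrogates,
                alpha=alpha, seed=seed,
            )
            out.phase = ph.phase if ph.phase_defined else None
            out.phase_defined = ph.phase_defined
            out.xcorr_peak_value = ph.xcorr_peak_value
            out.xcorr_significance = ph.p_value
            if not ph.phase_defined:
                out.notes.append(
                    "phase undefined: cross-correlation peak not significant "
                    f"(p = {ph.p_value:.3f})"
                )
        except (DegenerateSignalError, NotRhythmicError) as err:
            out.notes.append(f"phase undefined: {err}")
    left_on = detect_bursts(trace.left, trace.rate_hz, period_hint_s=period_s)
    right_on = detect_bursts(trace.right, trace.rate_hz, period_hint_s=period_s)
    out.n_bursts_left = len(left_on)
    out.n_bursts_right = len(right_on)
    if len(left_on) + len(right_on) >= 2:
        seq = BurstSequence.from_onsets(left_on, right_on)
        out.alternation_index = alternation_index(seq)
    else:
        out.notes.append("alternation undefined: fewer than 2 burst events")
    return out
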