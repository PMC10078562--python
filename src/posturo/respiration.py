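"""Respiration-signal preprocessing and breathing-rate estimation.

Pipeline: the raw transducer trace (2000 Hz) is resampled to 100 Hz,
band-pass filtered with a linear-phase FIR (passband 0.5-1 Hz, 8000 taps,
group delay compensated), and the breathing rate in a balance window is
60 over the mean interval between detected positive peaks.  Peak
detection uses a hysteresis threshold relative to the within-window
peak-to-peak range, so the rate estimate is invariant to amplitude
scaling; intervals outside the physiological 6-20 breaths/min band are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .core import DataError, DegenerateInputError, RespSignal


@dataclass(frozen=True)
class FilterSettings:
    """Linear-phase FIR band-pass design.

    ``q_metadata`` is vendor metadata carried for provenance; it does not
    enter the design, which is fully determined by the cutoffs, the tap
    count and the design rate.
    """

    low_cut: float = 0.5  # Hz
    high_cut: float = 1.0  # Hz
    n_coefficients: int = 8000
    design_rate: float = 100.0  # Hz
    q_metadata: float = 0.70700

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut < self.design_rate / 2:
            raise ValueError("need 0 < low_cut < high_cut < design_rate/2")
        if self.n_coefficients < 2:
            raise ValueError("n_coefficients must be >= 2")


@dataclass(frozen=True)
class RateDetectorSettings:
    """Peak-detector settings for breathing-rate estimation."""

    baseline_window_ms: float = 25.0
    noise_rejection: float = 0.05  # fraction of peak-to-peak range
    min_rate: float = 6.0  # breaths/min
    max_rate: float = 20.0  # breaths/min

    def __post_init__(self) -> None:
        if not 0 < self.noise_rejection < 1:
            raise ValueError("noise_rejection must be in (0, 1)")
        if not 0 < self.min_rate < self.max_rate:
            raise ValueError("need 0 < min_rate < max_rate")


class UndefinedRateError(DegenerateInputError):
    """Fewer than two physiologically plausible breaths were detected."""


def resample_signal(signal: RespSignal, target_rate: float) -> RespSignal:
    """Anti-aliased resampling to a lower rate (polyphase).

    Duration is preserved to within one output sample.  Upsampling is not
    supported.
    """
    if target_rate > signal.sampling_rate:
        raise ValueError("upsampling is not supported")
    if target_rate == signal.sampling_rate:
        return signal
    from fractions import Fraction

    frac = Fraction(target_rate / signal.sampling_rate).limit_denominator(10_000)
    out = sps.resample_poly(signal.samples, frac.numerator, frac.denominator,
                            padtype="line")
    n_expected = int(round(len(signal.samples) * target_rate / signal.sampling_rate))
    out = out[:n_expected]
    return replace(signal, samples=out, sampling_rate=float(target_rate))


def design_fir_bandpass(settings: FilterSettings) -> np.ndarray:
    """FIR band-pass taps (Hamming window design, linear phase)."""
    numtaps = settings.n_coefficients
    if numtaps % 2 == 0:
        numtaps += 1  # odd length: integer group delay, type-I response
    return sps.firwin(
        numtaps,
        [settings.low_cut, settings.high_cut],
        pass_zero=False,
        fs=settings.design_rate,
    )


def fir_bandpass(signal: RespSignal, settings: FilterSettings) -> RespSignal:
    """Apply the band-pass filter with group-delay compensation.

    Output is time-aligned with the input and has the same length; the
    edge regions (half the filter length at each end) taper toward zero.
    """
    if signal.sampling_rate != settings.design_rate:
        raise DataError(
            f"signal at {signal.sampling_rate} Hz but filter designed for "
            f"{settings.design_rate} Hz; resample first"
        )
    taps = design_fir_bandpass(settings)
    if len(signal.samples) < 2:
        raise DataError("signal shorter than minimum filterable length")
    delay = (len(taps) - 1) // 2
    padded = np.concatenate([signal.samples, np.zeros(delay)])
    out = sps.lfilter(taps, 1.0, padded)[delay:]
    return replace(signal, samples=out)


def preprocess(
    signal: RespSignal,
    target_rate: float = 100.0,
    settings: FilterSettings | None = None,
) -> RespSignal:
    """Resample to the design rate and band-pass filter."""
    if settings is None:
        settings = FilterSettings(design_rate=target_rate)
    return fir_bandpass(resample_signal(signal, target_rate), settings)


def _detect_peaks(samples: np.ndarray, rate: float, settings: RateDetectorSettings) -> np.ndarray:
    """Positive-peak indices using a range-relative hysteresis threshold.

    The baseline is a running mean over ``baseline_window_ms``; a peak is
    accepted only if it rises above baseline by more than
    ``noise_rejection`` times the peak-to-peak range of the window.
    """
    ptp = float(np.ptp(samples))
    if ptp == 0:
        return np.array([], dtype=int)
    n_base = max(1, int(round(settings.baseline_window_ms / 1000.0 * rate)))
    kernel = np.ones(n_base) / n_base
    smoothed = np.convolve(samples, kernel, mode="same")
    # prominence relative to the window range acts as the hysteresis band:
    # a peak must rise noise_rejection x range above its surrounding troughs
    peaks, _ = sps.find_peaks(smoothed, prominence=settings.noise_rejection * ptp)
    return peaks


def estimate_breathing_rate(
    signal: RespSignal,
    settings: RateDetectorSettings | None = None,
    window: tuple[float, float] | None = None,
) -> float:
    """Breathing rate (breaths/min) within one balance window.

    Inter-peak intervals shorter than ``60 / max_rate`` s or longer than
    ``60 / min_rate`` s are discarded; the rate is ``60`` over the mean
    retained interval.  Raises :class:`UndefinedRateError` when fewer than
    two plausible peaks remain — an undefined rate is an error, never
    reported as zero.
    """
    if settings is None:
        settings = RateDetectorSettings()
    if window is None:
        window = (0.0, signal.duration)
    start, end = window
    if not (0 <= start < end <= signal.duration + 1e-9):
        raise DataError(f"window {window} outside record of {signal.duration:.3f} s")
    rate = signal.sampling_rate
    seg = signal.samples[int(round(start * rate)) : int(round(end * rate))]
    if len(seg) < 2:
        raise DataError("window contains fewer than 2 samples")
    peaks = _detect_peaks(seg, rate, settings)
    if len(peaks) < 2:
        raise UndefinedRateError("fewer than 2 suprathreshold peaks in window")
    intervals = np.diff(peaks) / rate
    lo, hi = 60.0 / settings.max_rate, 60.0 / settings.min_rate
    retained = intervals[(intervals >= lo) & (intervals <= hi)]
    if len(retained) < 1:
        raise UndefinedRateError(
            "no inter-peak interval inside the "
            f"{settings.min_rate}-{settings.max_rate} breaths/min band"
        )
    return float(60.0 / np.mean(retained))
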