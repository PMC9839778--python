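"""Period estimation for quasi-periodic cardiac signals.

The period is read from the first prominent non-zero peak of the normalized
autocorrelation of the detrended signal, refined to sub-frame precision by
parabolic interpolation. This is the single periodicity primitive used by
cycle detection (brightfield) and plane realignment (fluorescence).
"""
from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .errors import NoPeriodicityError


def parabolic_peak(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample refinement of a discrete peak at index ``i``.

    Fits a parabola through (i-1, i, i+1); returns (position, value). At the
    array boundary no refinement is attempted.
    """
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2.0 * b + c
    if denom == 0:
        return float(i), float(b)
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = b - 0.25 * (a - c) * delta
    return i + delta, float(value)


def autocorrelation(signal: np.ndarray) -> np.ndarray:
    """Biased, normalized autocorrelation of a detrended signal; ac[0] = 1."""
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    denom = np.dot(x, x)
    if denom <= 0:
        raise NoPeriodicityError("signal has zero variance")
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    return ac / denom


def estimate_period(
    signal: np.ndarray,
    min_period: int = 4,
    prominence: float = 0.05,
    min_height: float = 0.1,
) -> float:
    """Fundamental period (in samples) of a quasi-periodic signal.

    Parameters
    ----------
    signal
        Raw 1-D trace; a linear trend is removed before autocorrelation.
    min_period
        Smallest admissible period in samples.
    prominence, min_height
        Peak acceptance thresholds on the normalized autocorrelation.

    Raises
    ------
    NoPeriodicityError
        If the signal is constant or no acceptable autocorrelation peak exists.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 2 * min_period:
        raise NoPeriodicityError("signal too short to contain a full period")
    t = np.arange(len(x))
    # linear detrend guards against photobleaching-like drifts
    coef = np.polyfit(t, x, 1)
    x = x - np.polyval(coef, t)
    if np.std(x) == 0:
        raise NoPeriodicityError("signal has zero variance")
    ac = autocorrelation(x)
    search = ac[: max(len(ac) * 3 // 4, min_period + 2)]
    peaks, _ = find_peaks(search[min_period - 1 :], prominence=prominence, height=min_height)
    if len(peaks) == 0:
        raise NoPeriodicityError("no autocorrelation peak above the noise floor")
    lag = peaks[0] + min_period - 1
    pos, _ = parabolic_peak(search, lag)
    return float(pos)


def refine_period_fourier(signal: np.ndarray, coarse: float) -> float:
    """Refine a coarse period by maximizing the periodogram near it.

    The power of the linearly detrended signal is evaluated on a fine
    period grid within +/-15% of ``coarse`` and the maximum is refined
    parabolically. Waveform shape (harmonics) does not bias the location
    of the fundamental peak, so this stays accurate for plateaued or
    otherwise non-sinusoidal cardiac traces.
    """
    x = np.asarray(signal, dtype=float)
    t = np.arange(len(x), dtype=float)
    x = x - np.polyval(np.polyfit(t, x, 1), t)
    periods = coarse * np.linspace(0.85, 1.15, 601)
    power = np.abs(np.exp(-2j * np.pi * np.outer(1.0 / periods, t)) @ x) ** 2
    pos, _ = parabolic_peak(power, int(np.argmax(power)))
    return float(np.interp(pos, np.arange(len(periods)), periods))
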