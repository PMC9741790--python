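"""Frequency-content checks and the biological time-interval arithmetic.

During walking, the vertical and anterio-posterior ground-reaction-force
content lies below roughly 16 Hz (medio-lateral below ~24 Hz), so a change
unfolding over more than 1/16 s ≈ 0.063 s can reflect a neuromotor or
mechanical adjustment rather than noise. After resampling to a fixed number
of points per stride, an m-sample entropy template spans
m x mean_stride_time / samples_per_cycle seconds; comparing that span with
the minimal neuromotor interval is what motivates a template length of
m = 6 (0.064 s at a 1.06 s stride and 100 points per cycle).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.signal import periodogram

from gaitent.errors import ParameterError, SignalQualityError


def _round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (0.0625 -> 0.063), matching printed values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SpectrumSummary:
    """One-sided power spectral density with a cumulative-power bandwidth."""

    frequencies: np.ndarray
    power: np.ndarray
    highest_relevant_frequency: float
    cumulative_threshold: float


def power_spectrum(
    series,
    sampling_rate: float,
    cumulative_threshold: float = 0.99,
    window: str = "boxcar",
) -> SpectrumSummary:
    """Mean-removed periodogram and the frequency containing most power.

    ``highest_relevant_frequency`` is the smallest frequency below which the
    cumulative power reaches ``cumulative_threshold`` (default 99%) of the
    total — a conservative reading of "the highest frequencies present".
    The default rectangular window keeps Parseval's identity exact: the
    integrated density equals the series variance.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 16:
        raise ParameterError("series", f"need at least 16 samples, got {len(x)}")
    if not sampling_rate > 0:
        raise ParameterError("sampling_rate", "must be > 0")
    if not 0 < cumulative_threshold <= 1:
        raise ParameterError("cumulative_threshold", "must be in (0, 1]")
    if np.ptp(x) == 0.0:
        raise SignalQualityError("constant series has no defined spectrum")
    freqs, pxx = periodogram(x, fs=sampling_rate, window=window, detrend="constant")
    total = pxx.sum()
    cum = np.cumsum(pxx) / total
    idx = int(np.searchsorted(cum, cumulative_threshold))
    idx = min(idx, len(freqs) - 1)
    return SpectrumSummary(
        frequencies=freqs,
        power=pxx,
        highest_relevant_frequency=float(freqs[idx]),
        cumulative_threshold=cumulative_threshold,
    )


def min_neuromotor_interval(max_frequency: float) -> float:
    """Shortest interval (s) a process band-limited to ``max_frequency`` can
    resolve: 1 / f, rounded half-up to 3 decimals (16 Hz -> 0.063 s)."""
    if not max_frequency > 0:
        raise ParameterError("max_frequency", "must be > 0")
    return _round_half_up(1.0 / max_frequency)


def template_time_span(m: int, mean_stride_time: float, samples_per_cycle: int) -> float:
    """Seconds covered by an m-sample entropy template after stride
    resampling: m x mean_stride_time / samples_per_cycle, rounded half-up
    to 3 decimals (m=6, 1.06 s, 100 pts -> 0.064 s)."""
    if not m > 0:
        raise ParameterError("m", "must be > 0")
    if not mean_stride_time > 0:
        raise ParameterError("mean_stride_time", "must be > 0")
    if not samples_per_cycle > 0:
        raise ParameterError("samples_per_cycle", "must be > 0")
    return _round_half_up(m * mean_stride_time / samples_per_cycle)
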