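"""Stride segmentation from the resultant vertical ground reaction force.

The resultant vGRF of walking oscillates around body weight with two valleys
per stride, one per foot's single-support midstance. Valleys are phase-stable
landmarks of double-bump force profiles, so stride boundaries are detected as
local minima of a lightly smoothed vGRF; every second valley belongs to the
same leg and marks a stride start. Which parity is the reference leg is read
from the valley heights (the more-loaded leg has the shallower single-support
valley); for perfectly symmetric gait the first detected valley defines the
phase. The same boundaries are applied to COPap, COPml and vGRF downstream —
segmentation reads only the vGRF channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from gaitent.errors import SegmentationError, SignalQualityError
from gaitent.synthetic import GaitRecording


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the valley detector.

    smooth_window_s: moving-average window in seconds (default 1/20 s, i.e.
    sampling_rate/20 samples at the native rate). min_separation_frac:
    refractory rule — second-pass minimum event spacing as a fraction of the
    median first-pass spacing. prominence_frac: first-pass valley prominence
    as a fraction of the smoothed signal's range.
    """

    smooth_window_s: float = 0.05
    min_separation_frac: float = 0.4
    prominence_frac: float = 0.05


@dataclass
class StrideSegmentation:
    """Ordered stride-start sample indices and the spanned durations."""

    boundaries: np.ndarray
    stride_durations: np.ndarray
    source_rate: float

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        self.stride_durations = np.asarray(self.stride_durations, dtype=float)
        if np.any(np.diff(self.boundaries) <= 0):
            raise SegmentationError("boundaries must be strictly increasing")
        if len(self.stride_durations) != len(self.boundaries) - 1:
            raise SegmentationError("need exactly one duration per consecutive boundary pair")
        if np.any(self.stride_durations <= 0):
            raise SegmentationError("every stride duration must be > 0")

    @property
    def n_strides(self) -> int:
        return len(self.boundaries) - 1

    def cycle_slices(self) -> list[slice]:
        """Half-open per-stride windows [b_i, b_{i+1})."""
        b = self.boundaries
        return [slice(int(b[i]), int(b[i + 1])) for i in range(self.n_strides)]


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    # reflect-pad so the ends are not biased toward zero
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="reflect")
    return np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]


def segment_strides(
    recording: GaitRecording, config: SegmentationConfig | None = None
) -> StrideSegmentation:
    """Detect same-leg stride boundaries from the vGRF channel.

    Two-pass valley detection on the smoothed vGRF: a prominence-gated first
    pass estimates the event spacing, a second pass enforces a refractory
    distance of ``min_separation_frac`` x the median spacing. Every second
    valley is kept; the kept parity is the one with the higher mean valley
    level (the more-loaded leg), falling back to the first valley when the
    two parities are indistinguishable.
    """
    config = config or SegmentationConfig()
    v = np.asarray(recording.vgrf, dtype=float)
    rng_ptp = float(np.ptp(v))
    if rng_ptp == 0.0 or not np.isfinite(rng_ptp):
        raise SignalQualityError("vGRF is flat or non-finite; no gait events present")

    window = max(1, int(round(recording.sampling_rate * config.smooth_window_s)))
    vs = _smooth(v, window)
    if np.ptp(vs) == 0.0:
        raise SignalQualityError("smoothed vGRF is flat; no gait events present")

    prominence = config.prominence_frac * np.ptp(vs)
    valleys, _ = find_peaks(-vs, prominence=prominence)
    if len(valleys) >= 3:
        median_spacing = float(np.median(np.diff(valleys)))
        distance = max(1, int(round(config.min_separation_frac * median_spacing)))
        valleys, _ = find_peaks(-vs, prominence=prominence, distance=distance)
    if len(valleys) < 3:
        raise SegmentationError(
            f"only {len(valleys)} vGRF events detected; need at least 3", n_events=len(valleys)
        )

    even, odd = valleys[0::2], valleys[1::2]
    # more-loaded (reference) leg -> shallower single-support valley
    mean_even, mean_odd = float(vs[even].mean()), float(vs[odd].mean())
    tol = 1e-9 * max(1.0, abs(mean_even), abs(mean_odd))
    if mean_odd > mean_even + tol:
        boundaries = odd
    else:
        boundaries = even
    if len(boundaries) < 2:
        raise SegmentationError(
            f"only {len(boundaries)} same-leg events detected; need at least 2",
            n_events=len(boundaries),
        )

    durations = np.diff(boundaries) / recording.sampling_rate
    return StrideSegmentation(
        boundaries=boundaries, stride_durations=durations, source_rate=recording.sampling_rate
    )


def trim_first_last(
    recording: GaitRecording, segmentation: StrideSegmentation
) -> tuple[GaitRecording, StrideSegmentation]:
    """Drop the first and last detected gait cycles.

    The data window is cut to [b_1, b_{K-1}) and boundary indices are
    re-based to it, removing the acceleration/deceleration cycles at the
    recording edges. Each call removes one more cycle from each end.
    """
    if segmentation.n_strides < 3:
        raise SegmentationError(
            f"cannot trim: only {segmentation.n_strides} strides",
            n_events=len(segmentation.boundaries),
        )
    b = segmentation.boundaries
    start, stop = int(b[1]), int(b[-2])
    trimmed = GaitRecording(
        sampling_rate=recording.sampling_rate,
        copap=recording.copap[start:stop].copy(),
        copml=recording.copml[start:stop].copy(),
        vgrf=recording.vgrf[start:stop].copy(),
        true_boundaries=None,
    )
    new_b = b[1:-1] - start
    new_seg = StrideSegmentation(
        boundaries=new_b,
        stride_durations=np.diff(new_b) / segmentation.source_rate,
        source_rate=segmentation.source_rate,
    )
    return trimmed, new_seg
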