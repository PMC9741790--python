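"""The four analyzed signal forms: WHOLE, SEGM, NORM, ZERO.

WHOLE — the raw series truncated to a common length, no amplitude or
time-base change. SEGM — each gait cycle resampled to a fixed number of
points (default 100) and concatenated. NORM — SEGM additionally rescaled per
cycle so the COP excursion spans [0, 1] of the stride length (COPap) or
stride width (COPml). ZERO — SEGM translated per cycle so each cycle starts
at the coordinate (0, 0), which removes slow positional drift without
changing any within-cycle point-to-point distance.

The vGRF channel is only ever analyzed as WHOLE or SEGM; spatial
normalization and zeroing are COP-channel operations, and requesting them
for vGRF raises :class:`~gaitent.errors.VariableError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from gaitent.errors import (
    DegenerateCycleError,
    LengthError,
    ParameterError,
    SegmentationError,
    StructureError,
    VariableError,
)
from gaitent.segmentation import StrideSegmentation
from gaitent.synthetic import CHANNELS, GaitRecording

TypeTag = Literal["WHOLE", "SEGM", "NORM", "ZERO"]

#: processing regimes defined per channel; vGRF is never spatially rescaled
TYPES_BY_VARIABLE = {
    "copap": ("WHOLE", "SEGM", "NORM", "ZERO"),
    "copml": ("WHOLE", "SEGM", "NORM", "ZERO"),
    "vgrf": ("WHOLE", "SEGM"),
}


@dataclass
class ProcessedSignal:
    """A 1-D analyzed series tagged with its processing provenance."""

    values: np.ndarray
    type_tag: TypeTag
    variable: str
    samples_per_cycle: int | None = None
    n_cycles: int | None = None
    units: Literal["original", "normalized"] = "original"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.type_tag in ("SEGM", "NORM", "ZERO"):
            if self.samples_per_cycle is None or self.n_cycles is None:
                raise StructureError(f"{self.type_tag} signal requires cycle structure")
            if len(self.values) != self.samples_per_cycle * self.n_cycles:
                raise StructureError(
                    f"length {len(self.values)} != samples_per_cycle x n_cycles "
                    f"({self.samples_per_cycle} x {self.n_cycles})"
                )

    def cycles(self) -> np.ndarray:
        """View the series as an (n_cycles, samples_per_cycle) array."""
        if self.type_tag == "WHOLE":
            raise StructureError("WHOLE signal has no cycle structure")
        return self.values.reshape(self.n_cycles, self.samples_per_cycle)


def _check_variable(variable: str) -> None:
    if variable not in CHANNELS:
        raise ParameterError("variable", f"must be one of {CHANNELS}, got {variable!r}")


def make_whole(recording: GaitRecording, variable: str, n_points: int) -> ProcessedSignal:
    """WHOLE: first ``n_points`` raw samples of a channel, unchanged.

    Apply after edge-cycle trimming; truncation to a common length makes raw
    series comparable across subjects.
    """
    _check_variable(variable)
    if n_points <= 0:
        raise ParameterError("n_points", "must be >= 1 (empty output requested)")
    x = recording.channel(variable)
    if len(x) < n_points:
        raise LengthError(n_points, len(x), what=f"{variable} recording")
    return ProcessedSignal(values=x[:n_points].copy(), type_tag="WHOLE", variable=variable)


def segment_resample(
    recording: GaitRecording,
    segmentation: StrideSegmentation,
    variable: str,
    samples_per_cycle: int = 100,
    n_cycles: int | None = None,
) -> ProcessedSignal:
    """SEGM: resample each gait cycle to a fixed point count and concatenate.

    Cycles are the half-open windows [b_i, b_{i+1}); each is independently
    piecewise-linearly interpolated onto a uniform grid of
    ``samples_per_cycle`` points spanning the cycle's first through last
    sample, and the first ``n_cycles`` cycles are concatenated.
    """
    _check_variable(variable)
    if samples_per_cycle < 2:
        raise ParameterError("samples_per_cycle", "must be >= 2")
    available = segmentation.n_strides
    if n_cycles is None:
        n_cycles = available
    if n_cycles < 1 or n_cycles > available:
        raise SegmentationError(
            f"requested {n_cycles} cycles but segmentation has {available}", n_events=available
        )
    x = recording.channel(variable)
    out = np.empty(n_cycles * samples_per_cycle)
    for k, sl in enumerate(segmentation.cycle_slices()[:n_cycles]):
        cyc = x[sl]
        if len(cyc) < 2:
            raise SegmentationError(f"cycle {k} has fewer than 2 samples")
        grid = np.linspace(0.0, len(cyc) - 1.0, samples_per_cycle)
        out[k * samples_per_cycle : (k + 1) * samples_per_cycle] = np.interp(
            grid, np.arange(len(cyc)), cyc
        )
    return ProcessedSignal(
        values=out,
        type_tag="SEGM",
        variable=variable,
        samples_per_cycle=samples_per_cycle,
        n_cycles=n_cycles,
    )


def normalize_spatial(segm_signal: ProcessedSignal, variable: str | None = None) -> ProcessedSignal:
    """NORM: per-cycle affine rescale of a COP SEGM signal onto [0, 1].

    Each cycle's excursion is mapped to the unit interval — COPap to <0;1>
    of the stride length, COPml to <0;1> of the stride width, read as the
    cycle's own signal range.
    """
    variable = variable or segm_signal.variable
    _check_variable(variable)
    if variable == "vgrf":
        raise VariableError("vGRF is never spatially normalized; only WHOLE and SEGM apply")
    if segm_signal.type_tag != "SEGM":
        raise StructureError(f"normalize_spatial expects a SEGM signal, got {segm_signal.type_tag}")
    cyc = segm_signal.cycles()
    lo = cyc.min(axis=1, keepdims=True)
    hi = cyc.max(axis=1, keepdims=True)
    span = hi - lo
    degenerate = np.nonzero(span.ravel() == 0.0)[0]
    if len(degenerate):
        raise DegenerateCycleError(int(degenerate[0]))
    return ProcessedSignal(
        values=((cyc - lo) / span).ravel(),
        type_tag="NORM",
        variable=variable,
        samples_per_cycle=segm_signal.samples_per_cycle,
        n_cycles=segm_signal.n_cycles,
        units="normalized",
    )


def zero_cycles(
    segm_signal_ap: ProcessedSignal, segm_signal_ml: ProcessedSignal
) -> tuple[ProcessedSignal, ProcessedSignal]:
    """ZERO: translate each COP cycle to start at the coordinate (0, 0).

    Subtracts each cycle's first (ap, ml) coordinate from every sample of
    that cycle, as if the subject started every cycle from the same point.
    Within-cycle point-to-point vector differences are preserved exactly, so
    absolute distances between data points are not lost — only the slow
    drift of the starting position is removed.
    """
    for sig, var in ((segm_signal_ap, "copap"), (segm_signal_ml, "copml")):
        if sig.type_tag != "SEGM":
            raise StructureError(f"zero_cycles expects SEGM signals, got {sig.type_tag}")
        if sig.variable == "vgrf":
            raise VariableError("vGRF is never zeroed; only WHOLE and SEGM apply")
        if sig.variable != var:
            raise StructureError(f"expected {var} as the {var[-2:]} input, got {sig.variable}")
    if (
        segm_signal_ap.samples_per_cycle != segm_signal_ml.samples_per_cycle
        or segm_signal_ap.n_cycles != segm_signal_ml.n_cycles
    ):
        raise StructureError("ap and ml inputs must share samples_per_cycle and n_cycles")

    def _zero(sig: ProcessedSignal) -> ProcessedSignal:
        cyc = sig.cycles()
        out = cyc - cyc[:, :1]
        return ProcessedSignal(
            values=out.ravel(),
            type_tag="ZERO",
            variable=sig.variable,
            samples_per_cycle=sig.samples_per_cycle,
            n_cycles=sig.n_cycles,
            units=sig.units,
        )

    return _zero(segm_signal_ap), _zero(segm_signal_ml)
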