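"""Exception hierarchy for gaitent."""


class GaitentError(Exception):
    """Base class for all gaitent errors."""


class ParameterError(GaitentError, ValueError):
    """An invalid generator or analysis parameter; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class SignalQualityError(GaitentError, ValueError):
    """A signal is degenerate (flat, zero-range, constant) for the requested step."""


class SegmentationError(GaitentError, ValueError):
    """Stride segmentation failed; carries the number of detected events."""

    def __init__(self, message: str, n_events: int | None = None):
        self.n_events = n_events
        super().__init__(message)


class LengthError(GaitentError, ValueError):
    """A series is too short for the requested operation; reports both lengths."""

    def __init__(self, needed: int, available: int, what: str = "series"):
        self.needed = needed
        self.available = available
        super().__init__(f"{what}: need {needed} samples, have {available}")


class DegenerateCycleError(GaitentError, ValueError):
    """A gait cycle has zero within-cycle range and cannot be rescaled."""

    def __init__(self, cycle_index: int):
        self.cycle_index = cycle_index
        super().__init__(f"cycle {cycle_index} has zero within-cycle range")


class StructureError(GaitentError, ValueError):
    """Two processed signals do not share the required cycle structure."""


class VariableError(GaitentError, ValueError):
    """An operation was requested for a channel it is not defined on."""


class UndefinedEntropyError(GaitentError, ValueError):
    """Sample entropy is undefined: no template matches at m or at m+1.

    ``reason`` is ``"no_m_matches"`` (B = 0) or ``"no_m_plus_1_matches"``
    (A = 0), so callers can distinguish the two failure modes.
    """

    def __init__(self, reason: str, m: int):
        self.reason = reason
        self.m = m
        super().__init__(f"sample entropy undefined at m={m}: {reason}")


class BalanceError(GaitentError, ValueError):
    """An ANOVA table is unbalanced or incomplete; lists the offending cells."""

    def __init__(self, message: str, cells=None):
        self.cells = cells or []
        super().__init__(message)


class PairingError(GaitentError, ValueError):
    """A repeated-measures unit is missing one of its conditions."""
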