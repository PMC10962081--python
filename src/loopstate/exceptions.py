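"""Exception hierarchy shared across the pipeline stages."""


class LoopstateError(Exception):
    """Base class for all loopstate errors."""


class FormatError(LoopstateError):
    """A file does not conform to the documented schema."""


class EmptyInputError(LoopstateError):
    """An input contained no usable records."""


class ValidationError(LoopstateError):
    """A value violates a documented invariant (bad ROI, bad config...)."""


class InsufficientDataError(LoopstateError):
    """Too few observations for the requested statistic."""


class DegenerateClusterError(LoopstateError):
    """All cluster members coincide; no width is defined."""


class AnalysisError(LoopstateError):
    """An analysis stage cannot produce a defined result."""
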