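"""Exception hierarchy for the ENG analysis pipeline."""


class CuffEngError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(CuffEngError, ValueError):
    """A configuration object violates its invariants."""


class CalibrationError(CuffEngError, RuntimeError):
    """SNR gain calibration failed to converge."""


class EmptyFrameError(CuffEngError, ValueError):
    """A recording is too short to yield a single observation window."""


class DegenerateWindowError(CuffEngError, ValueError):
    """A window is too short or too degenerate for the requested statistic."""


class SchemaError(CuffEngError, ValueError):
    """Feature-matrix columns or label schemas do not match."""


class InvalidInputError(CuffEngError, ValueError):
    """Input data violates an operation precondition."""
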