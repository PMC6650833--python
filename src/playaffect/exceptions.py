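"""Exception hierarchy shared across the pipeline."""


class PlayaffectError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PlayaffectError, ValueError):
    """Malformed or out-of-range input (bad frame, bad Likert value, ...)."""


class SessionTooShortError(InvalidInputError):
    """Calibration recording too short to yield non-empty thirds after warm-up."""


class DegenerateSignalError(PlayaffectError, ValueError):
    """A channel has no variance left after detrending; no pulse can be recovered."""


class InvalidTrainingSetError(InvalidInputError):
    """Training data missing a class or empty."""


class ProtocolError(PlayaffectError, RuntimeError):
    """Evaluation protocol precondition violated (e.g. fewer than three sessions)."""


class SchemaError(InvalidInputError):
    """An input file does not match the expected column layout."""
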