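"""Exception types shared across the package."""


class P300SelectError(Exception):
    """Base class for all package errors."""


class SchemaError(P300SelectError):
    """A session bundle, montage or epoch container violates an invariant.

    The message names the violated invariant so callers can surface it.
    """


class CalibrationError(P300SelectError):
    """SWLDA calibration failed: no feature met the entry criterion.

    Mirrors real sessions in which the calibration program reports that the
    classifier could not be trained.
    """


class SelectionError(P300SelectError):
    """Electrode selection could not proceed (e.g. every candidate failed)."""
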