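"""Exception types shared across the pipeline stages."""


class SedarchError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(SedarchError, ValueError):
    """A simulation or stage configuration violates its preconditions."""


class MissingDataError(SedarchError, ValueError):
    """A required field or label is absent from an input record."""


class UltrametricityError(SedarchError, ValueError):
    """Root-to-leaf path lengths of a time tree disagree beyond tolerance.

    Carries the offending leaf labels in ``offenders``.
    """

    def __init__(self, message: str, offenders=()):
        super().__init__(message)
        self.offenders = tuple(offenders)
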