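"""Exception hierarchy.

``ValidationError`` subclasses map to CLI exit code 1, everything else
unexpected to exit code 2.
"""


class MitomorphError(Exception):
    """Base class for all package errors."""


class ValidationError(MitomorphError):
    """Bad user input: specs, configs, parameters."""


class InvalidSpecError(ValidationError):
    """A primitive or scene specification violates its invariants."""


class OverlapError(ValidationError):
    """Two phantom primitives overlap; ground truth would not be analytic."""


class OutOfBoundsError(ValidationError):
    """A phantom primitive does not fit inside the target volume."""


class MissingObjectError(ValidationError):
    """Requested object id is absent from a label image."""


class MeshIntegrityError(MitomorphError):
    """Surface mesh is not closed/consistently oriented."""

    def __init__(self, message: str, bad_edges=None):
        super().__init__(message)
        self.bad_edges = bad_edges or []


class ContainmentError(ValidationError):
    """Cristae pixels fall outside their mitochondrion mask."""


class ConfigError(ValidationError):
    """Pipeline configuration is malformed or incomplete."""

    def __init__(self, message: str, missing=None):
        super().__init__(message)
        self.missing = list(missing or [])
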