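"""Exception hierarchy shared across the package."""


class CareKGError(Exception):
    """Base class for all package errors."""


class SchemaViolationError(CareKGError):
    """A node or edge breaks the concept-layer constraints."""


class NotFoundError(CareKGError):
    """A referenced node, elder or file does not exist."""


class FormatError(CareKGError):
    """Malformed input: unknown question key, device, CSV header, ..."""


class InputError(CareKGError):
    """A numeric input falls outside the classifier's admissible range."""
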