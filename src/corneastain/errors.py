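"""Exception hierarchy."""


class CorneaStainError(Exception):
    """Base class for all package errors."""


class FormatError(CorneaStainError):
    """An input file has an unusable format (e.g. single-channel image)."""


class ROIError(CorneaStainError):
    """Region-of-interest specification is invalid or covers no pixels."""


class ValidationError(CorneaStainError):
    """Input data violates a documented contract."""
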