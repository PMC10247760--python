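"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """An input violates a documented precondition; the message names the field."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but degenerate (e.g. an all-zero image)."""


class MissingLandmarkError(ValidationError):
    """A required landmark class is absent or has too little pixel support."""


class DegenerateGeometryError(ValidationError):
    """A geometric configuration that has no meaningful answer (near-parallel lines)."""


class UndefinedRateError(ValidationError):
    """A rate whose denominator is zero; deliberately not reported as 0."""
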