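"""Exception types shared across the pipeline."""


class FastrackError(Exception):
    """Base class for all fastrack errors."""


class FormatError(FastrackError):
    """A movie file or stream could not be decoded."""


class DimensionError(FastrackError):
    """Arrays or sequences that must agree in shape/length do not."""


class EmptyInputError(FastrackError):
    """An operation received an empty movie, directory, or sequence."""


class ParseError(FastrackError):
    """A track CSV could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateFrameError(FastrackError):
    """A frame is unusable for the requested operation (e.g. zero mean)."""


class ParameterError(FastrackError):
    """A configuration or scene parameter is out of its valid range."""
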