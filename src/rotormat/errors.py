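class RotormatError(Exception):
    """Fatal error raised by rotormat operations (bad input, malformed file)."""


class MatrixFormatError(RotormatError):
    """Malformed scoring-matrix file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
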