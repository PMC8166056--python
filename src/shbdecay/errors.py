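"""Exception hierarchy."""


class ShbDecayError(Exception):
    """Base class for package errors."""


class ParameterError(ShbDecayError, ValueError):
    """A model or surface parameter is outside its supported range."""


class PropagationError(ShbDecayError, RuntimeError):
    """Numerical failure while propagating nuclei or amplitudes."""

    def __init__(self, message: str, frame_index: int | None = None):
        self.frame_index = frame_index
        if frame_index is not None:
            message = f"{message} (frame {frame_index})"
        super().__init__(message)


class ConfigurationError(ShbDecayError, ValueError):
    """Invalid run configuration (unknown restraint coordinate, bad timing...)."""


class InputError(ShbDecayError, ValueError):
    """Malformed user input (indices, probability ranges, empty series...)."""


class GeometryError(ShbDecayError, ValueError):
    """Degenerate geometry (collinear atoms, undefined torsion...)."""

    def __init__(self, message: str, atoms: tuple | None = None):
        self.atoms = atoms
        if atoms is not None:
            message = f"{message} (atoms {atoms})"
        super().__init__(message)


class ParseError(ShbDecayError, ValueError):
    """Malformed file content."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
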