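"""Exception hierarchy shared across the package."""


class EgmfracError(Exception):
    """Base class for all package errors."""


class ParameterError(EgmfracError, ValueError):
    """An argument or configuration value violates its constraints."""


class DegenerateSignalError(EgmfracError, ValueError):
    """Signal is constant / all-zero and the operation is undefined on it."""


class LengthError(EgmfracError, ValueError):
    """Signal is too short for the requested operation."""


class PatternError(EgmfracError, ValueError):
    """A Type IV segment pattern violates its structural preconditions."""


class FormatError(EgmfracError, ValueError):
    """A signal file is malformed (bad header, non-numeric sample, empty body)."""
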