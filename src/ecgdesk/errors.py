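"""Exception hierarchy shared across the package.

Each error class maps to a distinct CLI exit code (see :mod:`ecgdesk.cli`).
"""


class EcgDeskError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class NonFiniteSignalError(EcgDeskError):
    """Input waveform contains NaN or infinite samples."""

    exit_code = 2


class SignalTooShortError(EcgDeskError):
    """Waveform is shorter than the minimum a stage can process."""

    exit_code = 3


class NoSignalError(EcgDeskError):
    """Waveform is empty / flat-lined where signal is required."""

    exit_code = 4


class InsufficientDataError(EcgDeskError):
    """Not enough beats / peaks / recordings for the requested computation."""

    exit_code = 5


class ConfigError(EcgDeskError):
    """Invalid configuration value or combination."""

    exit_code = 6


class ParseError(EcgDeskError):
    """Malformed input file."""

    exit_code = 7


class UnknownItemError(EcgDeskError):
    """A diagnosis item outside the supported 20-item list."""

    exit_code = 8
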