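"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes, so keep the classes coarse:
configuration problems, input/parsing problems, and data that is too
degenerate to screen (e.g. constant docking scores).
"""


class CpvsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CpvsError):
    """Invalid run configuration (bad field values, inconsistent scheme)."""


class ParseError(CpvsError):
    """A molecule record or file could not be parsed.

    ``position`` optionally carries a character/line position when the
    underlying parser exposes one.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class UnsupportedElementError(ParseError):
    """Molecule contains an element outside the supported alphabet."""


class MoleculeError(CpvsError):
    """A molecular graph violates a structural invariant (valence etc.)."""


class DegenerateDataError(CpvsError):
    """Data admits no meaningful model (constant scores, empty input...)."""


class InsufficientClassError(DegenerateDataError):
    """A class has too few examples to split into training + calibration."""


class LibrarySpecError(ConfigError):
    """A synthetic library specification cannot be satisfied."""
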