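"""Exception hierarchy shared across the package."""


class FlorisightError(Exception):
    """Base class for all package errors."""


class FormatError(FlorisightError):
    """Input file cannot be parsed under the declared dialect."""


class DataError(FlorisightError):
    """Parsed data violate a structural invariant (e.g. non-monotone grid)."""


class CoverageError(FlorisightError):
    """A spectrum does not cover the required wavelength window."""


class GridMismatchError(FlorisightError):
    """Two spectra or a spectrum and a template are on different grids."""


class DegenerateInputError(FlorisightError):
    """A computation received inputs for which it is not defined (e.g. all-zero catches)."""


class ConfigError(FlorisightError):
    """Invalid configuration (phenotype registry, model settings, run config)."""


class ConvergenceError(FlorisightError):
    """An iterative fit failed to converge; carries the optimizer trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
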