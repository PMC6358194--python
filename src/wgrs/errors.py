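"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems exit 2, data
format problems exit 3, numerical failures (non-convergence, separation,
collinearity) exit 4.
"""


class WgrsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(WgrsError, ValueError):
    """Invalid configuration or invalid argument combination."""


class FormatError(WgrsError, ValueError):
    """Malformed input file: bad columns, bad codes, duplicate identifiers."""


class AlleleMismatchError(FormatError):
    """A panel SNP was found by id but its allele pair does not match.

    Strand flips are never attempted: a silent flip corrupts every score
    downstream, so mismatches fail loudly.
    """


class NumericalError(WgrsError, RuntimeError):
    """Base class for optimisation failures."""


class SeparationError(NumericalError):
    """Complete or quasi-complete separation in a logistic fit."""


class CollinearityError(NumericalError):
    """Rank-deficient design matrix."""


class ConvergenceError(NumericalError):
    """Iteration limit reached without meeting the gradient tolerance."""
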