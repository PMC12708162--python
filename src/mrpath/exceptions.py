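"""Typed error signals used across the package.

Empty-result and insufficient-data conditions get their own exception types so
pipeline code can branch on them (e.g. relax a p-value threshold) without
string-matching error messages.
"""


class MRPathError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MRPathError):
    """A mandatory column is missing or the file cannot be interpreted."""


class EmptyInstrumentSetError(MRPathError):
    """A screening or harmonization step left no usable SNPs."""


class InsufficientInstrumentsError(MRPathError):
    """An estimator needs more instruments than the set provides."""


class CollinearExposuresError(MRPathError):
    """The multivariable design is rank deficient; names the collinear exposures."""


class IndeterminateDirectionError(MRPathError):
    """Directionality test undefined (no variance explained on either side)."""


class UndefinedProportionError(MRPathError):
    """Proportion mediated undefined because its denominator effect is zero."""
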