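"""Exception hierarchy shared across the package.

Validation problems (bad files, bad configs) and numerical failures are kept
distinct so the command-line layer can map them to different exit codes.
"""


class ActirhythmError(Exception):
    """Base class for all package errors."""


class FormatError(ActirhythmError, ValueError):
    """A file does not conform to the declared dialect or schema."""


class IntegrityError(ActirhythmError, ValueError):
    """Data violate a structural invariant (duplicates, nonpositive weights...)."""


class ConfigurationError(ActirhythmError, ValueError):
    """A configuration value is out of its documented domain."""


class NumericalError(ActirhythmError, RuntimeError):
    """A numerical procedure failed (rank deficiency, separation, divergence)."""
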