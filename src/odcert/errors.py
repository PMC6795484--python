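"""Exception hierarchy.

Validation errors cover malformed values (bad ICD-10 shape, mismatched
dimensions); configuration errors cover bad user configuration (missing
columns, infeasible cross-validation settings); input errors cover
unreadable or structurally unusable input files.
"""


class OdcertError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OdcertError):
    """A value failed a structural or semantic check."""


class ConfigurationError(OdcertError):
    """User-supplied configuration is inconsistent or infeasible."""


class InputError(OdcertError):
    """An input file could not be read or has an unusable structure."""
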