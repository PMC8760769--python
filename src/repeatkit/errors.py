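"""Exception hierarchy for repeatkit."""


class RepeatkitError(Exception):
    """Base class for all repeatkit errors."""


class SchemaError(RepeatkitError):
    """A required column is missing or a column mapping is invalid."""


class IntegrityError(RepeatkitError):
    """The dataset violates a structural invariant (duplicates, unknown ids)."""


class ProtocolError(RepeatkitError):
    """Retreat records do not follow the focal-sampling protocol."""


class DesignError(RepeatkitError):
    """The fixed-effect design matrix is invalid (rank deficiency, bad factor)."""


class DegenerateDataError(RepeatkitError):
    """The response carries no variance; a mixed model cannot be identified."""


class ConvergenceError(RepeatkitError):
    """An iterative fit or resampling scheme failed to stabilise."""


class ConfigurationError(RepeatkitError):
    """User-supplied configuration is inconsistent."""
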