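"""Exception hierarchy.

All package errors derive from :class:`PetdecompError` so callers can catch
one type at the pipeline boundary; subclasses mirror the failure modes of
each stage (schema, validation, degenerate controls, empty designs,
singular fits).
"""


class PetdecompError(Exception):
    """Base class for all petdecomp errors."""


class SchemaError(PetdecompError):
    """A table is missing required columns or has an unknown schema."""


class ValidationError(PetdecompError):
    """A row violates a domain invariant (e.g. fibrillar > total coverage)."""


class DegenerateControlsError(PetdecompError):
    """Wild-type controls have zero standard deviation."""


class InsufficientControlsError(PetdecompError):
    """Fewer than two wild-type controls available for z-scoring."""


class MissingStratumError(PetdecompError):
    """A required (genotype, age) stratum is absent."""


class EmptyDesignError(PetdecompError):
    """Pairing produced zero rows."""


class SingularDesignError(PetdecompError):
    """The regression design matrix is rank deficient."""


class ConfigError(PetdecompError):
    """Invalid simulation or pipeline configuration."""
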