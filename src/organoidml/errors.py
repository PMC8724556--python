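"""Exception hierarchy shared across the pipeline."""


class OrganoidMLError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OrganoidMLError):
    """A file could be read but its structure is inconsistent."""


class ValidationError(OrganoidMLError):
    """Input data violates a documented invariant."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns."""


class ParameterError(OrganoidMLError):
    """A parameter is outside its valid range."""


class TrainingError(OrganoidMLError):
    """A classifier cannot be trained from the given examples."""


class RegistrationError(OrganoidMLError):
    """Two images expected to be co-registered do not line up."""


class DegenerateROIError(ValidationError):
    """A region is too small for feature extraction (< 9 pixels)."""
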