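"""Exception hierarchy shared across the package."""


class BioAutoMLError(Exception):
    """Base class for all package errors."""


class SchemaError(BioAutoMLError):
    """The file or schema violates the modelling contract (duplicate headers,
    outcome with the wrong number of levels, unknown columns, ...)."""


class ParseError(BioAutoMLError):
    """A cell could not be interpreted under the declared schema."""


class ResourceError(BioAutoMLError):
    """A computation would exceed a configured resource cap."""


class ModelError(BioAutoMLError):
    """Training or evaluation failed for an algorithm."""


class IntegrityError(BioAutoMLError):
    """A serialized artifact is corrupted or has an incompatible format version."""
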