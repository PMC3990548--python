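"""Exception types shared across the package."""


class CoexnetError(ValueError):
    """Base class for invalid inputs or configurations."""


class ConfigError(CoexnetError):
    """A simulation or pipeline configuration is invalid."""


class InputError(CoexnetError):
    """Data handed to an operation violates its preconditions."""


class DegenerateFitError(CoexnetError):
    """A fit cannot be performed (e.g. all connectivities identical)."""
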