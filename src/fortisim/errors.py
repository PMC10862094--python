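"""Exception hierarchy shared across the package."""


class FortisimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FortisimError, ValueError):
    """A parameter value violates its invariant; message names the field."""


class DomainError(FortisimError, ValueError):
    """A quantity is outside its mathematical domain (e.g. negative grams)."""


class FormatError(FortisimError, ValueError):
    """A file does not match the expected tabular layout; message locates the cell."""


class EmptyInputError(FortisimError, ValueError):
    """An operation requiring at least one record received none."""


class ConfigurationError(FortisimError, ValueError):
    """A scenario/grid/vehicle configuration is unusable."""


class PipelineError(FortisimError, RuntimeError):
    """A pipeline stage failed; message names the stage, __cause__ keeps the original."""
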