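"""Exception hierarchy shared across the package."""


class SelenetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SelenetError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(SelenetError, ValueError):
    """An input file or stream could not be interpreted at all."""


class DataError(SelenetError, ValueError):
    """Structurally valid input whose content is inconsistent (e.g. a
    sample missing its housekeeping gene)."""


class StatisticsError(SelenetError, ValueError):
    """A statistic is undefined for the given input (single-node graph,
    zero-variance vector, ...)."""


class ResourceError(SelenetError, RuntimeError):
    """A combinatorial computation exceeded its configured budget."""


class EmptySeedError(SelenetError, ValueError):
    """No seed gene could be mapped onto the parent network."""
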