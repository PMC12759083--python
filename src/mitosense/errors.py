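"""Exception hierarchy shared across mitosense modules."""


class MitosenseError(Exception):
    """Base class for all mitosense errors."""


class ConfigurationError(MitosenseError, ValueError):
    """A simulation or run configuration violates an invariant."""


class InputError(MitosenseError, ValueError):
    """An input table, image or parameter is malformed for the requested operation."""


class GenerationError(MitosenseError, RuntimeError):
    """A synthetic-data generator could not satisfy its own constraints."""


class StatisticUndefinedError(MitosenseError, ValueError):
    """The requested statistic is undefined on this input (e.g. constant channel)."""
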