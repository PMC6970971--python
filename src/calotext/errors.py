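"""Exception types shared across the pipeline."""


class CalotextError(Exception):
    """Base class for package errors."""


class SchemaError(CalotextError):
    """An input table or record does not match its declared schema."""


class DegenerateInputError(CalotextError):
    """An operation received input it cannot meaningfully process
    (e.g. a density estimate over fewer than two data points)."""


class UndefinedCaloricResult(CalotextError):
    """A caloric quantity is undefined for the given scope — for example a
    caloric ratio with zero activity mentions.  Signalled explicitly rather
    than coerced to 0 or infinity."""
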