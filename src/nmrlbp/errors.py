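"""Exception hierarchy shared across the package.

All errors derive from :class:`ValueError` so callers that do not care about
the distinction can catch the builtin.
"""


class ParameterError(ValueError):
    """An invalid parameter value; the message names the offending field."""


class DegenerateInputError(ValueError):
    """An operation would produce an empty or meaningless result."""


class FormatError(ValueError):
    """A file on disk does not conform to the expected format."""


class ModelError(ValueError):
    """A classifier cannot be trained or applied (e.g. single-class data)."""
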