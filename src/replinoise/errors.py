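"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`ReplinoiseError`, so callers (and the CLI) can catch one type.
"""


class ReplinoiseError(Exception):
    """Base class for all errors raised by replinoise."""


class FormatError(ReplinoiseError):
    """A file does not conform to the expected dialect (missing column,
    non-integer count, malformed row)."""


class DesignError(ReplinoiseError):
    """The replicate design is inconsistent with the count table or with
    its own invariants (duplicate sample, replicate_index < 1, ...)."""


class DistanceError(ReplinoiseError):
    """A dissimilarity cannot be computed (zero-total vectors, negative
    entries, missing replicate pairs)."""


class FitError(ReplinoiseError):
    """A model fit received invalid input (too few points, non-positive
    copy numbers)."""


class ConfigError(ReplinoiseError):
    """A simulation or pipeline configuration violates its invariants."""
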