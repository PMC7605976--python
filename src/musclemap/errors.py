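"""Exception taxonomy shared by all modules.

Each family maps to a CLI exit code (see :mod:`musclemap.cli`):
I/O and format problems -> 2, validation -> 3, segmentation -> 4, stats -> 5.
"""


class MusclemapError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(MusclemapError):
    """A file could not be parsed as the expected format."""

    exit_code = 2


class MetadataError(MusclemapError):
    """A required metadata attribute is missing or unusable."""

    exit_code = 2


class UnsupportedInputError(MusclemapError):
    """The input is recognized but outside the supported subset."""

    exit_code = 2


class AlignmentError(MusclemapError):
    """Two images that must share a pixel grid do not."""

    exit_code = 3


class DialectError(MusclemapError):
    """A label image contains codes outside the documented dialect."""

    exit_code = 3


class ValidationError(MusclemapError):
    """A semantic precondition failed (e.g. empty muscle compartment)."""

    exit_code = 3


class SchemaError(MusclemapError):
    """A table or spec file is missing required fields."""

    exit_code = 3


class InputError(MusclemapError):
    """A scalar or array argument violates a function precondition."""

    exit_code = 3


class SegmentationError(MusclemapError):
    """The fallback segmenter could not find the expected anatomy."""

    exit_code = 4


class StatsError(MusclemapError):
    """A statistical routine received degenerate input."""

    exit_code = 5
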