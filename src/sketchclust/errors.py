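"""Exception types shared across the package.

Exit-code conventions for script wrappers: 0 success, 2 usage error
(:class:`UsageError`), 3 input error (:class:`InputError`).
"""


class SketchClustError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(SketchClustError):
    """A problem with user-supplied input files (missing, empty, malformed)."""

    exit_code = 3


class EmptyDatasetError(InputError):
    """An input source yielded zero genomes."""


class UsageError(SketchClustError):
    """Invalid parameter or flag combination."""

    exit_code = 2


class ParameterError(UsageError):
    """Sketch/distance parameters are inconsistent with the data."""
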