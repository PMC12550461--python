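"""Exception types shared across the package.

Input/format problems and statistical degeneracies are kept distinct so the
command-line layer can map them to different exit codes.
"""


class GmmDenoiseError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(GmmDenoiseError, ValueError):
    """Structural problem in an input file (missing/duplicate columns, bad FASTA header)."""


class TableParseError(GmmDenoiseError, ValueError):
    """A cell that should be a non-negative integer count failed to parse."""


class DegenerateDataError(GmmDenoiseError, ValueError):
    """Data cannot identify the requested model (too few points, zero spread, ...)."""


class NoErrorComponentError(GmmDenoiseError, ValueError):
    """A filtering threshold was requested from a single-component fit."""
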