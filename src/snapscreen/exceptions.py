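"""Exception hierarchy for screen validation and analysis errors.

All errors raised for invalid scientific input derive from
:class:`ScreenError`, itself a :class:`ValueError`, so callers may catch
either the package hierarchy or the builtin.
"""


class ScreenError(ValueError):
    """Base class for all snapscreen validation/analysis errors."""


class LayoutError(ScreenError):
    """Malformed or inconsistent plate layout (addresses, duplicates, empties)."""


class ReadingError(ScreenError):
    """Invalid plate-reader luminescence data (non-positive, non-numeric, duplicated)."""


class LibraryError(ScreenError):
    """Invalid protein-library annotation table."""


class DesignError(ScreenError):
    """Screen design cannot be assembled (missing wells, unmatched readings)."""


class BackgroundError(ScreenError):
    """Background model cannot be fitted (too few empty wells, zero variance)."""


class ChipError(ScreenError):
    """Invalid ChIP-qPCR input (empty reference group, bad input fraction)."""
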