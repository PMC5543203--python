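"""Domain exceptions."""


class Ki67AssayError(Exception):
    """Base class for all package errors."""


class UndefinedScoreError(Ki67AssayError):
    """A Ki-67 percentage cannot be formed (zero tumor cells counted)."""


class AoiSelectionError(Ki67AssayError):
    """Fewer than the minimum number of clean AOI windows are available."""


class FlowConservationError(Ki67AssayError):
    """A REMARK flow stage dropped cases without an exclusion reason."""
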