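"""Exception types shared across the package."""


class CloneTableFormatError(ValueError):
    """A clone-table file is malformed (missing columns, bad rows).

    ``row_errors`` lists every offending row as ``(line_number, message)`` —
    validation reports all violations, not just the first.
    """

    def __init__(self, message, row_errors=None):
        super().__init__(message)
        self.row_errors = list(row_errors) if row_errors else []


class TreeStructureError(ValueError):
    """A ductal tree is structurally invalid (no/two roots, cycle, orphan)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


class DegenerateSampleError(ValueError):
    """Sample has zero variance (or is otherwise degenerate) where spread is required."""
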