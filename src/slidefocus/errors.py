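"""Exception hierarchy for slidefocus.

All slidefocus errors derive from :class:`SlidefocusError` so callers can
catch the whole family with one clause; the CLI maps subclasses onto
distinct exit codes.
"""


class SlidefocusError(Exception):
    """Base class for all slidefocus errors."""


class SlideFormatError(SlidefocusError):
    """The input file is not a readable slide in a supported format."""


class SlideValidationError(SlidefocusError, ValueError):
    """An argument violates a documented precondition."""


class RegionRangeError(SlidefocusError, ValueError):
    """A requested region lies entirely outside the slide bounds."""


class MergeConflictError(SlidefocusError):
    """Two partial results claim the same sub-tile lattice cell."""

    def __init__(self, coordinate):
        self.coordinate = coordinate
        super().__init__(f"duplicate sub-tile record at grid cell {coordinate}")


class IncompleteGridError(SlidefocusError):
    """Merged results leave lattice cells unfilled."""

    def __init__(self, missing):
        self.missing = list(missing)
        preview = ", ".join(str(c) for c in self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"missing sub-tile records at grid cells: {preview}{more}")


class JobFailedError(SlidefocusError):
    """One or more tile tasks failed; no partial result is returned."""

    def __init__(self, failures):
        # failures: list of (tile_id, diagnostic)
        self.failures = list(failures)
        ids = ", ".join(str(t) for t, _ in self.failures)
        super().__init__(f"job failed on tile(s): {ids}")


class CalibrationError(SlidefocusError):
    """Threshold calibration could not separate the score distributions."""
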