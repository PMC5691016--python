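"""Exception hierarchy for protondosim.

Every failure mode the pipeline can diagnose raises a subclass of
:class:`ProtonDosimError`, so callers can catch one type at the CLI boundary.
"""


class ProtonDosimError(Exception):
    """Base class for all protondosim errors."""


class RangeCoverageError(ProtonDosimError):
    """The evaluation grid does not cover the Bragg peak and its distal falloff."""


class GridSizeError(ProtonDosimError):
    """A requested dose grid would exceed the voxel-count guard."""


class FlatnessError(ProtonDosimError):
    """SOBP synthesis could not reach the requested plateau flatness."""


class ExtractionError(ProtonDosimError):
    """A profile metric (crossing, width, bound) could not be extracted."""


class NormalizationError(ProtonDosimError):
    """Profile normalization is impossible (e.g. all-zero dose)."""


class NoEventsError(ProtonDosimError):
    """A lineal-energy reduction was requested on an empty event set."""


class OrientationError(ProtonDosimError):
    """Unsupported detector orientation (edge-on is diode-only)."""


class ProfileFormatError(ProtonDosimError):
    """Malformed delimited-text profile file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GridFormatError(ProtonDosimError):
    """Binary grid payload inconsistent with its sidecar metadata."""
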