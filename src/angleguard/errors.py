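"""Exception hierarchy.

Every failure mode carries a short machine-readable ``reason`` code (e.g.
``"trace-too-short"``) so that callers can downgrade a quadrant to
*ungradable* instead of aborting a whole screening run.
"""

from __future__ import annotations


class AngleguardError(Exception):
    """Base class for all package errors."""

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(f"{reason}: {message}" if message else reason)


class GeometryError(AngleguardError):
    """Angle-metric computation failed (``trace-too-short``,
    ``landmark-off-trace``, ``degenerate-angle``, ``aod-undefined``)."""


class GradingError(AngleguardError):
    """Eye-level grading failed (``no-configuration``,
    ``needs-third-grader``, ``empty-calibration``)."""


class ValidationError(AngleguardError):
    """Input record or annotation failed schema/invariant validation.

    ``failures`` lists one human-readable message per offending field.
    """

    def __init__(self, failures: list[str], reason: str = "validation-failed"):
        self.failures = list(failures)
        super().__init__(reason, "; ".join(self.failures))
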