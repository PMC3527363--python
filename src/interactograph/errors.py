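"""Exception hierarchy.

User-facing errors (bad files, bad queries) derive from
:class:`InteractographError` so the CLI can map them to exit code 2;
anything else is an internal error (exit 1).
"""

from __future__ import annotations


class InteractographError(Exception):
    """Base class for all user-facing errors."""


class ParseError(InteractographError):
    """A table row could not be parsed or violates a field constraint.

    Carries the file path and 1-based line number of the offending row.
    """

    def __init__(self, path: str, line: int, message: str) -> None:
        self.path = path
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


class IntegrityError(InteractographError):
    """Cross-row/cross-table invariant violation (e.g. duplicate record id)."""


class QueryFormatError(InteractographError):
    """Malformed query string (too many groups, empty group, ...)."""


class ResolutionError(InteractographError):
    """One or more query tokens failed to resolve; carries the reports."""

    def __init__(self, reports) -> None:
        self.reports = list(reports)
        bad = [r for r in self.reports if not r.resolved]
        detail = "; ".join(f"{r.token!r}: {r.outcome.value}" for r in bad)
        super().__init__(f"unresolved query tokens: {detail}")


class ConfigurationError(InteractographError):
    """A run configuration that can never produce results."""


class SubmissionError(InteractographError):
    """A proposal was rejected; carries the verdict when one exists."""

    def __init__(self, message: str, verdict=None) -> None:
        self.verdict = verdict
        super().__init__(message)


class RenderEnvironmentError(InteractographError):
    """A rendering backend (GraphViz executable) is not available."""
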