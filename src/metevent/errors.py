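"""Exception hierarchy shared across the package."""

from __future__ import annotations


class MetEventError(Exception):
    """Base class for all package errors."""


class StandoffParseError(MetEventError):
    """A standoff line could not be parsed.

    Carries the 1-based line number of the offending ``.ann`` line.
    """

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


class SpanIntegrityError(MetEventError):
    """An annotation span does not agree with the document text."""


class DanglingReferenceError(MetEventError):
    """An annotation references an id that does not exist in the document."""


class SchemaError(MetEventError):
    """A document violates the metabolic annotation schema."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"{v.ann_id}: {v.rule}" for v in self.violations)
        super().__init__(f"{len(self.violations)} schema violation(s): {lines}")


class ConfigurationError(MetEventError):
    """Invalid configuration (empty gazetteer, bad proportions, ...)."""


class NamingCollisionError(MetEventError):
    """The same canonical name is used for both an enzyme and a metabolite."""
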