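"""Typed exceptions used across the pipeline.

Every error a stage can raise is one of these, so callers (the orchestrator,
the CLI) can distinguish bad configuration from bad input data from parse
failures, and parse failures always carry file/line context.
"""

from __future__ import annotations


class CovPanelError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(CovPanelError):
    """A parameter or config object violates its invariants."""


class InputError(CovPanelError):
    """Input data violates a precondition of an operation."""


class NoCellsPassQCError(InputError):
    """Every cell was removed by the QC filter."""


class ParseError(CovPanelError):
    """A file failed to parse or validate; carries file and line context."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        ctx = ""
        if path is not None:
            ctx = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + ctx)
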