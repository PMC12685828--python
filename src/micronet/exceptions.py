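"""Typed errors raised across the package.

Every malformed input raises one of these instead of silently coercing,
so callers (and the CLI exit-code mapping) can distinguish bad data from
internal failures.
"""


class MicronetError(Exception):
    """Base class for all package errors."""


class ValidationError(MicronetError, ValueError):
    """An input table or parameter violates a documented invariant."""


class TableParseError(MicronetError, ValueError):
    """A cell or header of an input file could not be parsed.

    The message carries row/column coordinates where applicable.
    """


class DesignError(MicronetError, ValueError):
    """A synthetic community design is infeasible (e.g. module sizes
    exceeding the taxon count)."""


class StageError(MicronetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
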