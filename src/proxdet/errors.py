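"""Exception hierarchy.

Exit-code convention used by the CLI: input/validation problems
(:class:`SchemaError`, :class:`MicrodataValidationError`,
:class:`ReferentialError`, :class:`StratumError`,
:class:`ConfigurationError`) map to exit code 2; computation problems
(:class:`UndefinedEstimateError`, :class:`UnstableEstimateError`) to 1.
"""

from __future__ import annotations


class ProxdetError(Exception):
    """Base class for all package errors."""


class SchemaError(ProxdetError):
    """A CSV file does not have the expected column headers."""


class MicrodataValidationError(ProxdetError):
    """One or more microdata rows failed validation.

    ``rows`` holds ``(row_number, message)`` pairs; row numbers are
    1-based over data rows (header excluded).
    """

    def __init__(self, rows: list[tuple[int, str]]):
        self.rows = list(rows)
        head = "; ".join(f"row {r}: {m}" for r, m in self.rows[:10])
        more = "" if len(self.rows) <= 10 else f" (+{len(self.rows) - 10} more)"
        super().__init__(f"{len(self.rows)} invalid row(s): {head}{more}")


class ReferentialError(ProxdetError):
    """A birth record references a woman_id absent from the women table."""


class StratumError(ProxdetError):
    """A stratum predicate selected an empty universe."""


class UndefinedEstimateError(ProxdetError):
    """An estimator is undefined on the given data (e.g. no births in window)."""


class UnstableEstimateError(ProxdetError):
    """Every fertile age group has an unstable marriage denominator."""


class ConfigurationError(ProxdetError):
    """Inconsistent or infeasible configuration."""
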