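"""Exception hierarchy for input, contract, and statistic errors."""


class DialclaimsError(Exception):
    """Base class for all package errors."""


class FormatError(DialclaimsError):
    """An input file does not have the documented column layout."""


class RowError(DialclaimsError):
    """A single row of an input file could not be parsed.

    Carries the 1-based line number (header = line 1) in ``line``.
    """

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ContractError(DialclaimsError):
    """An operation was called outside its precondition."""


class UndefinedStatisticError(DialclaimsError):
    """A statistic's denominator is zero (or chance agreement is 1)."""


class ScenarioError(DialclaimsError):
    """A simulation scenario field is invalid; names the field."""

    def __init__(self, field: str, message: str):
        super().__init__(f"scenario field {field!r}: {message}")
        self.field = field
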