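"""Exception hierarchy shared across the package.

Two failure classes matter to callers: invalid or inconsistent input
(``ValidationError``, CLI exit code 2) and statistically undefined requests
such as a single-class ROC or an empty nodule set (``UndefinedStatisticError``,
CLI exit code 3).
"""


class NoduleEvalError(Exception):
    """Base class for all errors raised by noduleval."""


class ValidationError(NoduleEvalError):
    """Invalid, inconsistent, or precondition-violating input."""


class UndefinedStatisticError(NoduleEvalError):
    """A requested statistic is undefined for the given data."""
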