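"""Exception hierarchy.

``QuintError`` is the base for everything the library raises deliberately;
the CLI maps it to exit code 1.  ``DegenerateVarianceError`` and
``EmptyArmError`` double as internal signals: during the split search they
mark a candidate as inadmissible rather than aborting the fit.
"""


class QuintError(Exception):
    """Base class for all pyquint errors."""


class FormulaError(QuintError):
    """Malformed role formula (grammar or duplicate names)."""


class ValidationError(QuintError):
    """A tuning parameter or scenario field is outside its valid range."""


class DataError(QuintError):
    """The data cannot support the requested analysis."""


class DegenerateVarianceError(QuintError):
    """Pooled standard deviation is zero; Cohen's d is undefined."""


class EmptyArmError(QuintError):
    """A row subset does not contain both treatment arms."""
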