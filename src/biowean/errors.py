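"""Exception hierarchy.

Input problems (bad profiles, bad configs, bad ratings) derive from
:class:`ValidationError`; numerical/estimation failures derive from
:class:`EstimationError`.  The CLI maps the former to exit code 2 and the
latter to exit code 3.
"""

from __future__ import annotations


class BioweanError(Exception):
    """Base class for all package errors."""


class ValidationError(BioweanError, ValueError):
    """One or more input violations, collected all at once.

    ``messages`` holds every violation found so batch data entry gets a
    complete list rather than the first failure.
    """

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class DomainError(ValidationError):
    """A value outside the model's supported domain (e.g. CID time)."""


class ConfigurationError(BioweanError, ValueError):
    """A coefficient configuration that does not match the model schema."""


class AdjustmentError(BioweanError, ValueError):
    """An invalid weight adjustment (e.g. all ratings zero)."""


class EstimationError(BioweanError, RuntimeError):
    """Model refitting failed (rank deficiency, non-convergence)."""


class SeparationError(EstimationError):
    """Perfect separation in the choice data; logit MLE does not exist."""
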