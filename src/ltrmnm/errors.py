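"""Exception hierarchy.

All errors raised for bad user input derive from :class:`LifetimeRiskError`
so callers (and the CLI) can catch one base class and exit cleanly.
"""


class LifetimeRiskError(ValueError):
    """Base class for all domain errors raised by this package."""


class GridAlignmentError(LifetimeRiskError):
    """Two schedules are not defined on the identical age grid."""


class InputError(LifetimeRiskError):
    """A value violates a documented precondition (units, sign, range)."""


class UsageError(LifetimeRiskError):
    """Operations combined in an unsupported way (e.g. mismatched event kinds)."""
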