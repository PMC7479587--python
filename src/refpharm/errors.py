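"""Exception hierarchy.

Everything raised deliberately by refpharm derives from :class:`RefpharmError`,
split into input problems (bad files, contradictory configuration — CLI exit
code 2) and internal contract breaches (exit code 1).
"""


class RefpharmError(Exception):
    """Base class for all refpharm errors."""


class InputError(RefpharmError):
    """A problem with user-supplied data or configuration."""


class ParseError(InputError):
    """Malformed row in a delimited input table; message names the line."""


class ConflictError(InputError):
    """The same pharmacy appears with contradictory status labels."""


class ConfigError(InputError):
    """Contradictory or out-of-range configuration values."""


class FitError(RefpharmError):
    """Model fitting is impossible, e.g. no labeled pharmacy has any edge."""


class NoReferralDataError(RefpharmError):
    """The pharmacy has no referral edges at all; callers map this to the
    'unknown' prediction."""


class AxisMismatchError(RefpharmError):
    """Two backlink vectors with different referrer axes were combined."""


class SplitError(InputError):
    """A cross-validation split cannot be formed (class smaller than folds)."""


class MetricError(RefpharmError):
    """Metrics requested on an empty (post-policy) confusion table."""
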