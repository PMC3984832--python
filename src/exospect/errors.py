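"""Exception hierarchy shared across the package."""


class ExospectError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(ExospectError, ValueError):
    """Malformed FASTA input (bad header or non-IUPAC symbol)."""


class DegenerateFeatureError(ExospectError, ValueError):
    """A segment produced an all-zero feature vector (e.g. all-N)."""


class UndefinedSNRError(ExospectError, ZeroDivisionError):
    """Signal-to-noise ratio requested on an all-zero spectrum."""


class UndefinedMetricError(ExospectError, ZeroDivisionError):
    """A ratio metric whose denominator is zero."""


class WindowError(ExospectError, ValueError):
    """Sliding-window parameters incompatible with the sequence."""


class RankError(ExospectError, ValueError):
    """Prototype vectors are linearly dependent; adjoints undefined."""


class NoCompetitionError(ExospectError, ValueError):
    """All initial order parameters are zero; no winner can emerge."""


class InstabilityError(ExospectError, ArithmeticError):
    """Order-parameter integration diverged (step size too large)."""


class OrderingError(ExospectError, ValueError):
    """Interval list violates the required sort order."""
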