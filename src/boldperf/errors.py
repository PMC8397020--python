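"""Exception hierarchy for the boldperf pipeline.

All errors derive from :class:`BoldPerfError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
stages where they arise.
"""


class BoldPerfError(Exception):
    """Base class for all boldperf errors."""


class ParadigmError(BoldPerfError, ValueError):
    """A time or frame selection falls outside the cuffing paradigm."""


class ConfigurationError(BoldPerfError, ValueError):
    """Invalid simulator / pipeline configuration (geometry, cohort sizes...)."""


class InputError(BoldPerfError, ValueError):
    """Malformed input data (echo times, masks, empty samples...)."""


class DegenerateROIError(BoldPerfError, ValueError):
    """An ROI lost all its pixels (shifted out of bounds, or no valid fits)."""


class UndefinedCorrelationError(BoldPerfError, ValueError):
    """Rank correlation is undefined (zero variance in a rank vector)."""
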