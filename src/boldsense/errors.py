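"""Exception hierarchy for the boldsense pipeline."""


class BoldSenseError(Exception):
    """Base class for all boldsense errors."""


class GridError(BoldSenseError):
    """Volume grids are incompatible (shape, spacing, or field of view)."""


class DesignError(BoldSenseError):
    """Deconvolution design matrix is invalid (rank-deficient or ill-posed)."""


class QCError(BoldSenseError):
    """A dataset failed a quality-control gate (e.g., too many censored volumes)."""


class ConfigError(BoldSenseError):
    """An invalid configuration value was supplied."""
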