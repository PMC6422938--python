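"""Typed exceptions raised across the package.

All inherit from :class:`TwinH2Error` so callers can catch the package's
failures with one clause; the subclasses distinguish structural pedigree
problems from statistical degeneracies.
"""


class TwinH2Error(Exception):
    """Base class for all twinh2 errors."""


class PedigreeError(TwinH2Error):
    """Structural pedigree problem: dangling parent, cycle, bad MZ group."""


class ConfigurationError(TwinH2Error):
    """Invalid user configuration (counts, variance fractions, flags)."""


class ValidationError(TwinH2Error):
    """Input data fails a precondition (non-finite values, asymmetry, size)."""


class DegenerateTraitError(TwinH2Error):
    """A trait carries no usable variance."""


class UnidentifiableDesignError(TwinH2Error):
    """The pedigree/pair structure cannot separate the variance components."""


class UnsupportedDesignError(TwinH2Error):
    """A model was requested on a structure it does not support (e.g. ACE
    on families where the kinship and shared-environment matrices do not
    commute)."""


class CollinearityError(TwinH2Error):
    """Covariate design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear covariate columns: {', '.join(self.columns)}")


class ConvergenceError(TwinH2Error):
    """An iterative fit failed to converge or produced an inadmissible LRT."""
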