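"""Exception hierarchy.

All package-specific errors derive from :class:`SersQuantError`; those that
signal invalid arguments or inputs also derive from :class:`ValueError` so
callers can catch them generically.
"""


class SersQuantError(Exception):
    """Base class for all sersquant errors."""


class ConfigurationError(SersQuantError, ValueError):
    """A configuration object or file is invalid."""


class CapacityError(ConfigurationError):
    """A plate layout cannot hold the requested samples x replicates."""


class FormatError(SersQuantError, ValueError):
    """A spectral-map or manifest file does not follow the documented dialect."""


class ConsistencyError(SersQuantError, ValueError):
    """Design and data disagree (well ids, counts, axes)."""


class SpectralRangeError(SersQuantError, ValueError):
    """A wavenumber position falls outside the spectrum's axis."""


class RegressionError(SersQuantError, ValueError):
    """A regression is degenerate (constant abscissa, too few points)."""


class EmptyCdfError(SersQuantError, ValueError):
    """No positive values remain to build an empirical CDF from."""


class CdfFitError(SersQuantError, ValueError):
    """Too few CDF points inside the probability range to fit the polynomial."""


class DegeneracyError(SersQuantError, ValueError):
    """A matrix/score configuration is rank-deficient for the requested task."""
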