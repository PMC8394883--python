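"""Exception types raised across the package.

All derive from ValueError so generic input validation can be caught
uniformly, while each stage of the pipeline can still be distinguished.
"""


class DomainError(ValueError):
    """A physical input lies outside the model's validity domain
    (e.g. a wavelength outside a dispersion model's calibrated range)."""


class GridMismatchError(ValueError):
    """Spectra that must share one wavelength grid do not."""


class DegenerateReferenceError(ValueError):
    """Reference (analyte-free) spectra are too close to each other to
    normalize against: |T_par_ref - T_cross_ref| below the floor."""


class UnidentifiableError(ValueError):
    """The azimuthal angle cannot be estimated: every wavelength sits at a
    retardation null where sin^2(delta/2) is below the admissibility floor."""


class InsufficientFringesError(ValueError):
    """Fewer than two interference extrema were detected, so no cell gap
    can be derived from fringe spacing."""


class SingularFitError(ValueError):
    """The calibration design matrix is rank deficient."""


class OutOfRangeError(ValueError):
    """An inverse prediction was requested for a response value with no
    root inside the calibration's fitted range."""


class NonMonotoneCalibrationError(ValueError):
    """Inverse prediction is ambiguous: the fitted polynomial crosses the
    requested response more than once inside the fitted range."""
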