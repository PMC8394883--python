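"""Calibration curves, limit of detection, and inverse prediction.

The dose signal (reduced transmittance T_par, T_cross, or their ratio at
one wavelength) is regressed on x = log10(concentration in g/mL) by
unweighted ordinary least squares, either as a straight line or as a
third-order polynomial — the cubic absorbs the saturation of the response
at both concentration extremes.  Goodness of fit is the plain coefficient
of determination R^2 = 1 - SS_res/SS_tot for both forms.

The limit of detection follows the 3s/m rule: three times the standard
error of the fitted intercept divided by the slope magnitude of a linear
calibration.  With a logarithmic abscissa the quantity 3s/|m| carries
log10-concentration units, so two conventions are implemented behind a
mandatory flag and never silently defaulted:

- ``abscissa-domain``: LOD = 10**(3s/|m|) g/mL (dimensional anchor 1 g/mL);
  invariant under affine rescaling of the response.
- ``signal-domain``: the regression is re-expressed against linear
  concentration over the fitted range and LOD = 3s/|m| directly in g/mL.

Inverse prediction solves the fitted polynomial within the fitted abscissa
range and fails loudly when the root is absent or ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    NonMonotoneCalibrationError,
    OutOfRangeError,
    SingularFitError,
)

RESPONSES = ("T_parallel", "T_crossed", "ratio")
FORMS = {"linear": 1, "cubic-polynomial": 3, "cubic": 3}


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS via lstsq; returns (beta, residual_sd, cov, r2).

    cov is the coefficient covariance residual_var * (X'X)^-1; residual
    variance uses the n - p denominator.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise SingularFitError(
            f"rank-deficient design: {n} points, rank < {p} parameters"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = n - p
    res_var = ss_res / dof if dof > 0 else 0.0
    cov = res_var * np.linalg.inv(X.T @ X)
    return beta, float(np.sqrt(res_var)), cov, r2


class CalibrationCurve(BaseEstimator, RegressorMixin):
    """Polynomial calibration of one response channel at one wavelength.

    Parameters
    ----------
    response : {'T_parallel', 'T_crossed', 'ratio'}
    wavelength : float, nm (metadata; the fit itself is 1-D)
    form : {'linear', 'cubic-polynomial'}

    Attributes (after fit)
    ----------------------
    coef_ : ndarray            polynomial coefficients, intercept first
    intercept_se_ : float      standard error of the fitted intercept
    r_squared_ : float         1 - SS_res/SS_tot
    residual_sd_ : float       sqrt(SS_res / (n - p))
    fit_range_ : (lo, hi)      abscissa range, log10 g/mL
    response_range_ : (lo, hi) fitted response range
    n_points_ : int
    monotone_ : bool           fitted curve strictly monotone on fit_range_
    """

    def __init__(self, response: str = "T_parallel", wavelength: float = 450.0,
                 form: str = "cubic-polynomial"):
        self.response = response
        self.wavelength = wavelength
        self.form = form

    @property
    def _degree(self) -> int:
        try:
            return FORMS[self.form]
        except KeyError:
            raise ValueError(
                f"form must be one of {sorted(FORMS)}, got {self.form!r}"
            ) from None

    def fit(self, concentrations, y, y_sd=None):
        if self.response not in RESPONSES:
            raise ValueError(
                f"response must be one of {RESPONSES}, got {self.response!r}"
            )
        c = np.asarray(concentrations, dtype=float)
        y = np.asarray(y, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise ValueError("concentrations and y must be equal-length 1-D")
        if np.any(c <= 0):
            raise ValueError(
                "concentrations must be strictly positive (true blanks enter "
                "only through the reference spectra, never the fit)"
            )
        deg = self._degree
        x = np.log10(c)
        if np.unique(x).size < deg + 1:
            raise ValueError(
                f"need at least {deg + 1} distinct abscissa values for a "
                f"degree-{deg} fit, got {np.unique(x).size}"
            )
        X = np.vander(x, deg + 1, increasing=True)
        beta, res_sd, cov, r2 = _ols(X, y)
        self.coef_ = beta
        self.cov_ = cov
        self.intercept_se_ = float(np.sqrt(cov[0, 0]))
        self.residual_sd_ = res_sd
        self.r_squared_ = r2
        self.n_points_ = int(x.size)
        self.fit_range_ = (float(x.min()), float(x.max()))
        self.response_range_ = (float(y.min()), float(y.max()))
        self.x_ = x
        self.y_ = y
        self.y_sd_ = None if y_sd is None else np.asarray(y_sd, dtype=float)
        self.concentrations_ = c
        self.monotone_ = self._check_monotone()
        if not self.monotone_:
            warnings.warn(
                f"fitted {self.form} calibration is non-monotone over "
                f"log10(c) in [{self.fit_range_[0]:.3g}, "
                f"{self.fit_range_[1]:.3g}]; inverse prediction may be "
                "ambiguous there", stacklevel=2,
            )
        return self

    def _poly(self):
        # highest-power-first for numpy.polyval / roots
        return self.coef_[::-1]

    def _check_monotone(self) -> bool:
        if self._degree == 1:
            return self.coef_[1] != 0.0
        dcoef = np.polyder(self._poly())
        roots = np.roots(dcoef)
        lo, hi = self.fit_range_
        for r in roots:
            if abs(r.imag) < 1e-9 and lo < r.real < hi:
                return False
        return True

    def predict(self, concentrations):
        c = np.asarray(concentrations, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        return np.polyval(self._poly(), np.log10(c))

    def predict_response_at_log10c(self, x):
        return np.polyval(self._poly(), np.asarray(x, dtype=float))

    def predict_concentration(self, response_value: float,
                              response_sd: float | None = None,
                              z: float = 1.0):
        """Invert the calibration: response -> concentration in g/mL.

        Roots of the fitted polynomial outside ``fit_range_`` are
        discarded; exactly one in-range root is required.  The optional
        interval is first-order: dx = z * response_sd / |dy/dx| at the
        root (z = 1 for a one-sigma band, 1.96 for ~95%).
        """
        lo, hi = self.fit_range_
        tol = 1e-9 * max(1.0, hi - lo)
        poly = self._poly().copy()
        poly[-1] -= response_value
        if self._degree == 1:
            roots = np.array([-poly[1] / poly[0]]) if poly[0] != 0 else np.array([])
        else:
            roots = np.roots(poly)
        real = [r.real for r in np.atleast_1d(roots)
                if abs(r.imag) <= 1e-9 * max(1.0, abs(r.real))]
        in_range = sorted(r for r in real if lo - tol <= r <= hi + tol)
        # collapse numerically coincident roots
        uniq: list[float] = []
        for r in in_range:
            if not uniq or abs(r - uniq[-1]) > 1e-9 * max(1.0, hi - lo):
                uniq.append(r)
        if not uniq:
            raise OutOfRangeError(
                f"response {response_value:.6g} has no root with log10(c) in "
                f"[{lo:.4g}, {hi:.4g}]"
            )
        if len(uniq) > 1:
            raise NonMonotoneCalibrationError(
                "multiple in-range roots for response "
                f"{response_value:.6g}: log10(c) = {uniq}"
            )
        x0 = float(np.clip(uniq[0], lo, hi))
        conc = 10.0 ** x0
        if response_sd is None:
            return ConcentrationPrediction(conc, x0, None, None)
        slope = float(np.polyval(np.polyder(self._poly()), x0))
        if slope == 0.0:
            return ConcentrationPrediction(conc, x0, 0.0, np.inf)
        dx = abs(z * response_sd / slope)
        return ConcentrationPrediction(conc, x0, 10.0 ** (x0 - dx),
                                       10.0 ** (x0 + dx))


@dataclass
class ConcentrationPrediction:
    concentration: float          # g/mL
    log10_concentration: float
    lower: float | None = None    # g/mL, first-order interval
    upper: float | None = None


@dataclass
class LODResult:
    """3s/m limit of detection from a linear calibration."""

    lod_concentration: float      # g/mL
    slope_m: float                # response per log10(g/mL) or per g/mL
    intercept_sd_s: float         # response units
    regression_range: tuple       # (lo, hi) of the regression abscissa
    convention: str               # 'abscissa-domain' | 'signal-domain'


def limit_of_detection(model: CalibrationCurve, convention: str) -> LODResult:
    """LOD = 3s/m with s the intercept standard error, m the slope.

    ``convention`` is mandatory; see the module docstring for the two
    readings of the rule under a logarithmic abscissa.
    """
    if model._degree != 1:
        raise ValueError("limit_of_detection requires a linear-form model")
    if convention == "abscissa-domain":
        m = float(model.coef_[1])
        if m == 0.0:
            raise ValueError("degenerate calibration: zero slope")
        s = model.intercept_se_
        lod = 10.0 ** (3.0 * s / abs(m))
        return LODResult(lod, m, s, model.fit_range_, convention)
    if convention == "signal-domain":
        c = model.concentrations_
        X = np.vander(c, 2, increasing=True)
        beta, _, cov, _ = _ols(X, model.y_)
        m = float(beta[1])
        if m == 0.0:
            raise ValueError("degenerate calibration: zero slope")
        s = float(np.sqrt(cov[0, 0]))
        lod = 3.0 * s / abs(m)
        return LODResult(lod, m, s, (float(c.min()), float(c.max())),
                         convention)
    raise ValueError(
        "convention must be 'abscissa-domain' or 'signal-domain' "
        f"(got {convention!r}); no silent default"
    )


def wavelength_sensitivity_scan(models, convention: str = "abscissa-domain"):
    """Slope magnitude and LOD per wavelength, most sensitive flagged.

    ``models`` are fitted :class:`CalibrationCurve` instances at distinct
    wavelengths.  The sensitivity slope is the linear OLS slope of the
    stored calibration points (which equals the fitted slope for
    linear-form models); the LOD column comes from that linear refit.
    Ties for the maximum |slope| are all flagged.
    """
    import pandas as pd

    models = list(models)
    if len(models) < 2:
        raise ValueError("wavelength scan needs at least 2 wavelengths")
    rows = []
    for mdl in models:
        lin = CalibrationCurve(response=mdl.response,
                               wavelength=mdl.wavelength, form="linear")
        lin.fit(mdl.concentrations_, mdl.y_)
        lod = limit_of_detection(lin, convention)
        rows.append({
            "wavelength_nm": mdl.wavelength,
            "response": mdl.response,
            "slope": float(lin.coef_[1]),
            "abs_slope": abs(float(lin.coef_[1])),
            "lod_g_per_mL": lod.lod_concentration,
            "r_squared": mdl.r_squared_,
        })
    table = pd.DataFrame(rows).sort_values(
        "abs_slope", ascending=False, kind="stable").reset_index(drop=True)
    best = table["abs_slope"].max()
    table["most_sensitive"] = np.isclose(table["abs_slope"], best,
                                         rtol=1e-12, atol=0.0)
    return table


def save_model(model: CalibrationCurve, path) -> None:
    """Serialize a fitted calibration as structured text (YAML)."""
    import yaml

    doc = {
        "response": model.response,
        "wavelength_nm": float(model.wavelength),
        "form": model.form,
        "coefficients_intercept_first": [float(v) for v in model.coef_],
        "intercept_se": model.intercept_se_,
        "residual_sd": model.residual_sd_,
        "r_squared": model.r_squared_,
        "n_points": model.n_points_,
        "fit_range_log10c": [float(v) for v in model.fit_range_],
        "points": {
            "concentration_g_per_mL": [float(v) for v in model.concentrations_],
            "response": [float(v) for v in model.y_],
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> CalibrationCurve:
    """Rebuild a calibration from :func:`save_model` output (refits from
    the stored points, which reproduces every attribute)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    model = CalibrationCurve(response=doc["response"],
                             wavelength=doc["wavelength_nm"],
                             form=doc["form"])
    model.fit(doc["points"]["concentration_g_per_mL"],
              doc["points"]["response"])
    return model


def fit_calibration(points, response: str, wavelength: float,
                    form: str) -> CalibrationCurve:
    """Functional wrapper: ``points`` is an iterable of
    (concentration g/mL, response value, response sd) triples (sd may be
    None)."""
    pts = list(points)
    c = [p[0] for p in pts]
    y = [p[1] for p in pts]
    sd = [p[2] if len(p) > 2 else None for p in pts]
    y_sd = None if any(s is None for s in sd) else sd
    return CalibrationCurve(response=response, wavelength=wavelength,
                            form=form).fit(c, y, y_sd=y_sd)
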