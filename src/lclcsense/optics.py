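"""Forward optics of a planar-aligned liquid-crystal cell between polarizers.

The sensing cell is a thin birefringent slab of nematic lyotropic chromonic
liquid crystal (here disodium cromoglycate, DSCG, which is optically
negative) between two glass substrates.  With the rubbing direction at
azimuthal angle ``phi`` to the analyzer transmission axis and phase
retardation ``delta = 2*pi*d*dn/lambda``, the normalized transmittances are

    I_par   = 1 - sin^2(2 phi) sin^2(delta/2)      (parallel polarizers)
    I_cross =     sin^2(2 phi) sin^2(delta/2)      (crossed polarizers)

with the birefringence ``dn = n_eff - n_perp`` and the effective index

    n_eff = n_perp n_par / sqrt(n_par^2 sin^2 theta + n_perp^2 cos^2 theta)

for pretilt ``theta`` (theta = 0: planar, maximum |dn|; theta = pi/2:
vertical, dn = 0).  Because dn enters only through sin^2, the transmittances
are invariant under dn -> -dn, so the optically negative sign of DSCG never
needs special handling downstream.

A multi-slab Jones-matrix stack is provided as an independent oracle and as
an optional forward model for twisted director profiles; for a uniform
director it collapses to the closed forms above.

Angles are radians throughout this module; user-facing layers (CLI,
synthetic-experiment configuration) speak degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import DomainError, UnidentifiableError
from .spectra import Spectrum

__all__ = [
    "DispersionModel",
    "CellOptics",
    "default_dscg_dispersion",
    "default_cell",
    "effective_index",
    "phase_retardation",
    "transmittance_parallel",
    "transmittance_crossed",
    "simulate_spectrum",
    "jones_stack_transmittance",
    "PhiEstimator",
    "estimate_phi",
]


@dataclass(frozen=True)
class DispersionModel:
    """Two-term Cauchy dispersion for both principal refractive indices.

    ``n(lambda) = A + B / lambda^2`` with lambda in nm and B in nm^2.

    Parameters
    ----------
    n_parallel_coeffs : (A, B)
        Index for light polarized along the director (extraordinary-like).
    n_perp_coeffs : (A, B)
        Index for light polarized perpendicular to the director.
    valid_range : (min_nm, max_nm)
        Wavelength interval over which the coefficients are trusted.
    """

    n_parallel_coeffs: tuple = (1.3720, 1000.0)
    n_perp_coeffs: tuple = (1.3850, 2400.0)
    valid_range: tuple = (380.0, 820.0)

    def __post_init__(self):
        lo, hi = self.valid_range
        if not (0 < lo < hi):
            raise ValueError("valid_range must be an increasing positive interval")
        grid = np.linspace(lo, hi, 64)
        npar = self._cauchy(self.n_parallel_coeffs, grid)
        nperp = self._cauchy(self.n_perp_coeffs, grid)
        if not (np.all(np.isfinite(npar)) and np.all(np.isfinite(nperp))):
            raise ValueError("dispersion evaluates to non-finite indices")
        if np.any(npar <= 1.0) or np.any(nperp <= 1.0):
            raise ValueError("refractive indices must exceed 1 over valid_range")
        sign = np.sign(npar - nperp)
        if np.any(sign != sign[0]):
            raise ValueError(
                "birefringence changes sign inside valid_range; "
                "split the range or fix the coefficients"
            )

    @staticmethod
    def _cauchy(coeffs, wavelength):
        a, b = coeffs
        return a + b / np.asarray(wavelength, dtype=float) ** 2

    def check_wavelength(self, wavelength) -> None:
        wl = np.asarray(wavelength, dtype=float)
        lo, hi = self.valid_range
        if np.any(wl < lo) or np.any(wl > hi):
            raise DomainError(
                f"wavelength outside dispersion valid_range [{lo}, {hi}] nm"
            )

    def n_parallel(self, wavelength):
        self.check_wavelength(wavelength)
        return self._cauchy(self.n_parallel_coeffs, wavelength)

    def n_perp(self, wavelength):
        self.check_wavelength(wavelength)
        return self._cauchy(self.n_perp_coeffs, wavelength)


def default_dscg_dispersion() -> DispersionModel:
    """Package-default DSCG-like dispersion.

    The coefficients are package constants, not measured values: they give a
    negative birefringence whose magnitude decreases from about 0.020 at
    450 nm to 0.015 at 800 nm, the range and trend characteristic of
    nematic DSCG in the visible.
    """
    return DispersionModel()


@dataclass(frozen=True)
class CellOptics:
    """Physical state of the sensing cell.

    gap_d in nm; pretilt_theta (polar angle director-substrate) and
    azimuth_phi (director vs. analyzer transmission axis) in radians.
    """

    gap_d: float = 15000.0
    pretilt_theta: float = 0.0
    azimuth_phi: float = 0.0
    dispersion: DispersionModel = field(default_factory=default_dscg_dispersion)

    def __post_init__(self):
        if not self.gap_d > 0:
            raise ValueError("gap_d must be positive")
        if not 0.0 <= self.pretilt_theta <= math.pi / 2:
            raise ValueError("pretilt_theta must lie in [0, pi/2]")
        if not 0.0 <= self.azimuth_phi <= math.pi / 2:
            raise ValueError("azimuth_phi must lie in [0, pi/2]")


def default_cell(azimuth_phi: float = 0.0, gap_d: float = 15000.0) -> CellOptics:
    """A 15-um planar cell with the default dispersion."""
    return CellOptics(gap_d=gap_d, azimuth_phi=azimuth_phi)


def effective_index(dispersion: DispersionModel, theta: float, wavelength):
    """Effective refractive index at pretilt ``theta``.

    n_eff = n_perp n_par / sqrt(n_par^2 sin^2 theta + n_perp^2 cos^2 theta);
    collapses to n_par at theta = 0 and to n_perp at theta = pi/2.
    """
    if not 0.0 <= theta <= math.pi / 2:
        raise ValueError("theta must lie in [0, pi/2]")
    npar = dispersion.n_parallel(wavelength)
    nperp = dispersion.n_perp(wavelength)
    s, c = math.sin(theta), math.cos(theta)
    return nperp * npar / np.sqrt(npar**2 * s**2 + nperp**2 * c**2)


def birefringence(dispersion: DispersionModel, theta: float, wavelength):
    """dn = n_eff - n_perp (signed; negative for optically negative media)."""
    return effective_index(dispersion, theta, wavelength) - dispersion.n_perp(wavelength)


def phase_retardation(cell: CellOptics, wavelength):
    """delta = 2 pi d dn / lambda, in radians, sign of dn preserved."""
    dn = birefringence(cell.dispersion, cell.pretilt_theta, wavelength)
    return 2.0 * np.pi * cell.gap_d * dn / np.asarray(wavelength, dtype=float)


def transmittance_parallel(phi, delta):
    """I_par = 1 - sin^2(2 phi) sin^2(delta/2)."""
    return 1.0 - np.sin(2.0 * np.asarray(phi, dtype=float)) ** 2 * np.sin(
        np.asarray(delta, dtype=float) / 2.0
    ) ** 2


def transmittance_crossed(phi, delta):
    """I_cross = sin^2(2 phi) sin^2(delta/2)."""
    return np.sin(2.0 * np.asarray(phi, dtype=float)) ** 2 * np.sin(
        np.asarray(delta, dtype=float) / 2.0
    ) ** 2


def simulate_spectrum(cell: CellOptics, grid, scheme: str,
                      condition: str = "with-analyte",
                      replicate_id: int = 0) -> Spectrum:
    """Noiseless forward spectrum of ``cell`` on ``grid`` for one scheme."""
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("wavelength grid is empty")
    cell.dispersion.check_wavelength(grid)
    delta = phase_retardation(cell, grid)
    if scheme == "parallel":
        vals = transmittance_parallel(cell.azimuth_phi, delta)
    elif scheme == "crossed":
        vals = transmittance_crossed(cell.azimuth_phi, delta)
    else:
        raise ValueError(f"scheme must be 'parallel' or 'crossed', got {scheme!r}")
    return Spectrum(grid, vals, scheme=scheme, condition=condition,
                    replicate_id=replicate_id,
                    meta={"azimuth_phi_deg": math.degrees(cell.azimuth_phi),
                          "gap_d_nm": cell.gap_d})


def _rotation(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, s], [-s, c]], dtype=complex)


def jones_stack_transmittance(slab_phis, slab_deltas, scheme: str) -> float:
    """Transmittance of a stack of linear retarders between polarizers.

    Each slab i is a retarder of retardance ``slab_deltas[i]`` whose fast
    axis sits at ``slab_phis[i]`` to the analyzer axis.  Input light is
    polarized along the analyzer axis; the output is projected on the same
    axis (``parallel``) or the orthogonal one (``crossed``).  A uniform
    stack (all phis equal, retardances summing to delta) reproduces the
    closed-form single-retarder transmittances to machine precision, which
    is what makes this an oracle for them.
    """
    phis = np.atleast_1d(np.asarray(slab_phis, dtype=float))
    deltas = np.atleast_1d(np.asarray(slab_deltas, dtype=float))
    if phis.size != deltas.size:
        raise ValueError(
            f"slab_phis ({phis.size}) and slab_deltas ({deltas.size}) "
            "must have equal length"
        )
    if phis.size == 0:
        raise ValueError("slab lists must be nonempty")
    if scheme not in ("parallel", "crossed"):
        raise ValueError(f"scheme must be 'parallel' or 'crossed', got {scheme!r}")
    total = np.eye(2, dtype=complex)
    # light traverses slab 0 first; matrices compose on the left
    for phi, delta in zip(phis, deltas):
        ret = np.array([[np.exp(-0.5j * delta), 0.0],
                        [0.0, np.exp(0.5j * delta)]], dtype=complex)
        slab = _rotation(-phi) @ ret @ _rotation(phi)
        total = slab @ total
    e_in = np.array([1.0, 0.0], dtype=complex)
    e_out = total @ e_in
    idx = 0 if scheme == "parallel" else 1
    return float(np.abs(e_out[idx]) ** 2)


class PhiEstimator(BaseEstimator):
    """Least-squares azimuthal-angle estimator from a spectrum pair.

    Inverts the closed-form transmittances: at each admissible wavelength
    ``sin^2(2 phi) = I_cross / sin^2(delta/2)``, with ``delta(lambda)``
    known from the cell optics.  Both channels contribute residuals
    (``1 - I_par`` carries the same signal as ``I_cross``), and the
    least-squares amplitude has the closed form
    ``s* = sum(w y) / sum(w^2)`` with weights ``w = sin^2(delta/2)``.

    Wavelengths with ``sin^2(delta/2)`` below ``floor`` are excluded: near
    half-wave nulls the angle is unidentifiable.  Estimates are reported on
    [0, pi/4] only; sin^2(2 phi) is symmetric about 45 deg, so an angle of
    70 deg aliases to 20 deg and the branch is resolved by convention.

    Attributes (after fit)
    ----------------------
    phi_ : float            estimate in radians, in [0, pi/4]
    phi_deg_ : float        the same in degrees
    residual_ : float       root-mean-square residual over both channels
    n_wavelengths_ : int    admissible wavelengths used
    """

    def __init__(self, cell: CellOptics | None = None, floor: float = 1e-3):
        self.cell = cell
        self.floor = floor

    def fit(self, pair, y=None):
        s_par, s_cross = pair
        if s_par.scheme != "parallel" or s_cross.scheme != "crossed":
            raise ValueError("pair must be (parallel Spectrum, crossed Spectrum)")
        cell = self.cell if self.cell is not None else default_cell()
        from .spectra import require_common_grid

        grid = require_common_grid(s_par, s_cross)
        delta = phase_retardation(cell, grid)
        w = np.sin(delta / 2.0) ** 2
        keep = w >= self.floor
        if not np.any(keep):
            raise UnidentifiableError(
                f"all {grid.size} wavelengths have sin^2(delta/2) below the "
                f"floor {self.floor}; the azimuthal angle is unidentifiable"
            )
        w = w[keep]
        y_obs = np.concatenate([1.0 - s_par.values[keep], s_cross.values[keep]])
        x = np.concatenate([w, w])
        s_hat = float(np.dot(x, y_obs) / np.dot(x, x))
        s_hat = min(max(s_hat, 0.0), 1.0)
        self.sin2_2phi_ = s_hat
        self.phi_ = 0.5 * math.asin(math.sqrt(s_hat))
        self.phi_deg_ = math.degrees(self.phi_)
        resid = y_obs - s_hat * x
        self.residual_ = float(np.sqrt(np.mean(resid**2)))
        self.n_wavelengths_ = int(np.count_nonzero(keep))
        return self


def estimate_phi(pair, cell: CellOptics, floor: float = 1e-3):
    """Functional wrapper over :class:`PhiEstimator`.

    Returns ``(phi_radians, rms_residual)``.
    """
    est = PhiEstimator(cell=cell, floor=floor).fit(pair)
    return est.phi_, est.residual_
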