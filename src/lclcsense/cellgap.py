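"""Cell-gap estimation from thin-film interference fringes.

An empty cell of gap d behaves as a low-finesse etalon: its transmission
spectrum is modulated as cos(4*pi*d*n/lambda), with maxima at
lambda = 2*n*d/m for integer fringe order m.  The gap follows from fringe
counting between the first and last detected maxima,

    d = N * lambda_1 * lambda_N / (2 * n_medium * (lambda_N - lambda_1)),

where N is the number of fringe intervals.  Only interval counts are used
— the absolute order is never assigned — which makes the estimate robust
to smooth spectral envelopes (lamp profile, coatings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .exceptions import InsufficientFringesError
from .spectra import Spectrum


@dataclass
class FringeSet:
    """Detected interference extrema in one spectrum."""

    extrema_wavelengths: np.ndarray   # nm, strictly increasing
    kind: str = "maxima"
    source_grid: tuple = (0.0, 0.0)   # analyzed interval, nm

    def __post_init__(self):
        self.extrema_wavelengths = np.asarray(self.extrema_wavelengths,
                                              dtype=float)
        if not np.all(np.diff(self.extrema_wavelengths) > 0):
            raise ValueError("extrema must be strictly increasing")

    def __len__(self) -> int:
        return self.extrema_wavelengths.size


def detect_fringes(spectrum: Spectrum, prominence: float = 0.1) -> FringeSet:
    """Locate fringe maxima by prominence-thresholded peak picking.

    ``prominence`` is relative to the spectrum's value range, so a smooth
    positive envelope does not change which peaks survive.  Peak positions
    are refined by parabolic interpolation through the three samples
    around each maximum, which beats the grid quantization.
    """
    if len(spectrum) < 16:
        raise ValueError("need at least 16 samples to detect fringes")
    vals = spectrum.values
    span = float(vals.max() - vals.min())
    if span <= 0:
        raise InsufficientFringesError("constant spectrum: no fringes")
    idx, _ = find_peaks(vals, prominence=prominence * span)
    if idx.size < 2:
        raise InsufficientFringesError(
            f"only {idx.size} fringe maxima found (need >= 2); lower the "
            "prominence or widen the wavelength window"
        )
    lam = spectrum.wavelengths
    peaks = []
    for i in idx:
        if 0 < i < len(spectrum) - 1:
            y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
            denom = y0 - 2.0 * y1 + y2
            shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            # local grid step (grids may be non-uniform)
            step = (lam[i + 1] - lam[i]) if shift >= 0 else (lam[i] - lam[i - 1])
            peaks.append(lam[i] + shift * step)
        else:
            peaks.append(lam[i])
    return FringeSet(np.sort(np.asarray(peaks)), kind="maxima",
                     source_grid=(float(lam[0]), float(lam[-1])))


@dataclass
class GapEstimate:
    d_nm: float
    sd_nm: float
    n_intervals: int
    lambda_first: float
    lambda_last: float

    def report(self) -> str:
        return (f"d_nm={self.d_nm:.1f}\tsd_nm={self.sd_nm:.2f}\t"
                f"N={self.n_intervals}\tlambda_1={self.lambda_first:.2f}\t"
                f"lambda_N={self.lambda_last:.2f}")


def estimate_gap(fringes: FringeSet, medium_index: float = 1.0,
                 wavelength_resolution: float = 0.5) -> GapEstimate:
    """Fringe-counting gap estimate with first-order uncertainty.

    ``medium_index`` is 1 for an empty (air) cell.  The uncertainty
    propagates a per-peak wavelength resolution (default 0.5 nm, a typical
    fiber-spectrometer figure) through the fringe-counting formula.
    """
    if len(fringes) < 2:
        raise InsufficientFringesError("gap estimation needs >= 2 extrema")
    if medium_index < 1.0:
        raise ValueError("medium_index must be >= 1")
    lam = fringes.extrema_wavelengths
    lam1, lamN = float(lam[0]), float(lam[-1])
    if lamN == lam1:
        raise ValueError("degenerate fringe set: identical extrema")
    n_int = len(fringes) - 1
    spread = lamN - lam1
    d = n_int * lam1 * lamN / (2.0 * medium_index * spread)
    # d(lam1): N*lamN/(2n) * d/dlam1 [lam1/(lamN-lam1)] = N*lamN^2/(2n*spread^2)
    dd_dl1 = n_int * lamN**2 / (2.0 * medium_index * spread**2)
    dd_dlN = n_int * lam1**2 / (2.0 * medium_index * spread**2)
    sd = float(np.hypot(dd_dl1, dd_dlN) * wavelength_resolution)
    return GapEstimate(float(d), sd, n_int, lam1, lamN)


class CellGapEstimator(BaseEstimator):
    """sklearn-style wrapper: ``fit(spectrum)`` detects fringes and sets
    ``gap_nm_``, ``gap_sd_nm_``, ``fringes_``."""

    def __init__(self, prominence: float = 0.1, medium_index: float = 1.0,
                 wavelength_resolution: float = 0.5):
        self.prominence = prominence
        self.medium_index = medium_index
        self.wavelength_resolution = wavelength_resolution

    def fit(self, spectrum: Spectrum, y=None):
        self.fringes_ = detect_fringes(spectrum, prominence=self.prominence)
        est = estimate_gap(self.fringes_, medium_index=self.medium_index,
                           wavelength_resolution=self.wavelength_resolution)
        self.gap_nm_ = est.d_nm
        self.gap_sd_nm_ = est.sd_nm
        self.estimate_ = est
        return self
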