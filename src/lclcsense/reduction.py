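"""Reduced-transmittance normalization.

Raw measurements come in fours: the analyte-bearing cell and an
analyte-free reference cell, each under parallel and crossed polarizers.
The reduced transmittance parameters map the blank onto (1, 0):

    T_par   = (S_par   - T_cross_ref) / (T_par_ref - T_cross_ref)
    T_cross = (S_cross - T_cross_ref) / (T_par_ref - T_cross_ref)

per wavelength, where S is measured with analyte and the _ref spectra
without.  The ratio T_par / T_cross is reported where defined; at
blank-like conditions T_cross -> 0 and the ratio diverges, so wavelengths
with |T_cross| < 1e-9 carry NaN and are excluded from ratio calibrations.

No clipping is applied anywhere: under noise the reduced values may fall
slightly outside [0, 1] and that information is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateReferenceError
from .spectra import Spectrum, require_common_grid

REFERENCE_FLOOR = 1e-6     # minimum |T_par_ref - T_cross_ref| per wavelength
RATIO_FLOOR = 1e-9         # |T_cross| below this -> ratio undefined (NaN)


@dataclass
class ReducedTransmittance:
    """Per-wavelength reduced transmittances for one analyte concentration."""

    wavelengths: np.ndarray
    T_parallel: np.ndarray
    T_crossed: np.ndarray
    ratio: np.ndarray
    concentration: float = float("nan")   # g/mL; 0 allowed for blanks
    analyte_label: str = ""

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        for name in ("T_parallel", "T_crossed", "ratio"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.wavelengths.shape:
                raise ValueError(f"{name} length mismatch with wavelengths")
            setattr(self, name, arr)

    def at(self, wavelength: float, channel: str) -> float:
        """Value of one channel at the grid point nearest ``wavelength``."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(getattr(self, _CHANNEL_ATTR[channel])[i])


_CHANNEL_ATTR = {
    "T_parallel": "T_parallel",
    "T_crossed": "T_crossed",
    "ratio": "ratio",
}


class TransmittanceReducer(BaseEstimator, TransformerMixin):
    """Normalizes analyte spectra against analyte-free references.

    ``fit`` takes the reference pair (parallel, crossed); ``transform``
    takes one analyte pair and returns a :class:`ReducedTransmittance`.
    The transform is affine in each input spectrum, which is what the
    superposition tests downstream rely on.
    """

    def __init__(self, reference_floor: float = REFERENCE_FLOOR,
                 ratio_floor: float = RATIO_FLOOR):
        self.reference_floor = reference_floor
        self.ratio_floor = ratio_floor

    def fit(self, references, y=None):
        ref_par, ref_cross = references
        if ref_par.scheme != "parallel" or ref_cross.scheme != "crossed":
            raise ValueError("references must be (parallel, crossed) spectra")
        grid = require_common_grid(ref_par, ref_cross)
        denom = ref_par.values - ref_cross.values
        bad = np.abs(denom) < self.reference_floor
        if np.any(bad):
            lams = grid[bad][:5].tolist()
            raise DegenerateReferenceError(
                f"|T_par_ref - T_cross_ref| < {self.reference_floor} at "
                f"{int(bad.sum())} wavelengths, e.g. {lams} nm"
            )
        self.grid_ = grid
        self.ref_par_ = ref_par
        self.ref_cross_ = ref_cross
        self.denominator_ = denom
        return self

    def transform(self, pair, concentration: float = float("nan"),
                  analyte_label: str = "") -> ReducedTransmittance:
        s_par, s_cross = pair
        if s_par.scheme != "parallel" or s_cross.scheme != "crossed":
            raise ValueError("pair must be (parallel, crossed) spectra")
        require_common_grid(self.ref_par_, s_par, s_cross)
        t_par = (s_par.values - self.ref_cross_.values) / self.denominator_
        t_cross = (s_cross.values - self.ref_cross_.values) / self.denominator_
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(np.abs(t_cross) < self.ratio_floor,
                             np.nan, t_par / t_cross)
        return ReducedTransmittance(
            self.grid_, t_par, t_cross, ratio,
            concentration=concentration, analyte_label=analyte_label,
        )


def reduce_transmittance(s_par: Spectrum, s_cross: Spectrum,
                         ref_par: Spectrum, ref_cross: Spectrum,
                         concentration: float = float("nan"),
                         analyte_label: str = "") -> ReducedTransmittance:
    """One-shot reduction of a four-way spectrum set."""
    reducer = TransmittanceReducer().fit((ref_par, ref_cross))
    return reducer.transform((s_par, s_cross), concentration=concentration,
                             analyte_label=analyte_label)


@dataclass
class AggregatedReduced:
    """Replicate mean and sample standard deviation per wavelength."""

    wavelengths: np.ndarray
    mean: "ReducedTransmittance"
    sd_T_parallel: np.ndarray
    sd_T_crossed: np.ndarray
    sd_ratio: np.ndarray
    n: int
    single_replicate: bool = False

    def sd(self, channel: str) -> np.ndarray:
        return {"T_parallel": self.sd_T_parallel,
                "T_crossed": self.sd_T_crossed,
                "ratio": self.sd_ratio}[channel]


def aggregate_replicates(records) -> AggregatedReduced:
    """Mean and sample sd (n-1 denominator) across replicate reductions.

    All records must share one grid and one concentration.  A single
    record yields sd = 0 by convention, flagged and warned about.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    first = records[0]
    concs = np.array([r.concentration for r in records])
    same = np.isclose(concs, first.concentration, rtol=1e-12) | (
        np.isnan(concs) & np.isnan(first.concentration)
    )
    if not np.all(same):
        raise ValueError(f"mixed concentrations in replicate set: {concs}")
    for r in records[1:]:
        if r.wavelengths.shape != first.wavelengths.shape or np.any(
            r.wavelengths != first.wavelengths
        ):
            raise ValueError("replicates must share one wavelength grid")

    n = len(records)
    stacks = {
        name: np.vstack([getattr(r, name) for r in records])
        for name in ("T_parallel", "T_crossed", "ratio")
    }
    means = {k: np.nanmean(v, axis=0) for k, v in stacks.items()}
    if n == 1:
        warnings.warn("single replicate: standard deviations set to 0",
                      stacklevel=2)
        sds = {k: np.zeros_like(means[k]) for k in stacks}
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sds = {k: np.nanstd(v, axis=0, ddof=1) for k, v in stacks.items()}
    mean_rec = ReducedTransmittance(
        first.wavelengths, means["T_parallel"], means["T_crossed"],
        means["ratio"], concentration=first.concentration,
        analyte_label=first.analyte_label,
    )
    return AggregatedReduced(
        first.wavelengths, mean_rec,
        sds["T_parallel"], sds["T_crossed"], sds["ratio"],
        n=n, single_replicate=(n == 1),
    )


def to_table(reduced: ReducedTransmittance):
    """Reduced record as a pandas DataFrame (wavelength_nm, T_parallel,
    T_crossed, ratio) for text serialization."""
    import pandas as pd

    return pd.DataFrame({
        "wavelength_nm": reduced.wavelengths,
        "T_parallel": reduced.T_parallel,
        "T_crossed": reduced.T_crossed,
        "ratio": reduced.ratio,
    })
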