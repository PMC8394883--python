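"""Spectrum container and plain-text serialization.

A spectrum is a strictly increasing wavelength grid (nm) with one
transmittance value per wavelength, tagged with the polarizer scheme
(``parallel`` or ``crossed``), the analyte condition (``with-analyte`` or
``analyte-free``) and a replicate id.  Files are two-column delimited text
with ``#``-prefixed header comments carrying the metadata; no binary
formats are used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import GridMismatchError

SCHEMES = ("parallel", "crossed")
CONDITIONS = ("with-analyte", "analyte-free")


@dataclass
class Spectrum:
    """Transmittance vs. wavelength for one cell, one polarizer scheme.

    Parameters
    ----------
    wavelengths : array-like
        Strictly increasing grid in nm.
    values : array-like
        Dimensionless transmittance, one per wavelength.  Values may fall
        slightly outside [0, 1] under noise; they are stored untouched.
    scheme : {'parallel', 'crossed'}
    condition : {'with-analyte', 'analyte-free'}
    replicate_id : int
    meta : dict
        Free-form extra metadata (concentration, analyte label, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    scheme: str = "parallel"
    condition: str = "with-analyte"
    replicate_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise ValueError("wavelengths must be a nonempty 1-D array")
        if self.values.shape != self.wavelengths.shape:
            raise ValueError(
                f"values length {self.values.size} != wavelengths length "
                f"{self.wavelengths.size}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("transmittance values must be finite")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    def __len__(self) -> int:
        return self.wavelengths.size

    def same_grid(self, other: "Spectrum", atol: float = 0.0) -> bool:
        if len(self) != len(other):
            return False
        return np.allclose(self.wavelengths, other.wavelengths, rtol=0.0, atol=atol)


def require_common_grid(*spectra: Spectrum) -> np.ndarray:
    """Return the shared grid, or raise listing offending wavelengths."""
    ref = spectra[0]
    for s in spectra[1:]:
        if len(s) != len(ref):
            raise GridMismatchError(
                f"grids differ in length: {len(ref)} vs {len(s)}"
            )
        bad = np.nonzero(s.wavelengths != ref.wavelengths)[0]
        if bad.size:
            offending = s.wavelengths[bad[:5]].tolist()
            raise GridMismatchError(
                f"wavelength grids differ at {bad.size} positions, e.g. "
                f"{offending} nm; resample explicitly with resample()"
            )
    return ref.wavelengths


def resample(spectrum: Spectrum, grid) -> Spectrum:
    """Linear interpolation of a spectrum onto a new grid.

    Resampling is never implicit elsewhere in the package: silently
    interpolating mismatched grids would hide instrument drift.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"target grid [{grid[0]}, {grid[-1]}] nm extends beyond the "
            f"measured range [{lo}, {hi}] nm"
        )
    vals = np.interp(grid, spectrum.wavelengths, spectrum.values)
    return replace(spectrum, wavelengths=grid, values=vals)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write two-column delimited text with '#' metadata header."""
    path = Path(path)
    lines = [
        f"# scheme: {spectrum.scheme}",
        f"# condition: {spectrum.condition}",
        f"# replicate_id: {spectrum.replicate_id}",
    ]
    for k, v in sorted(spectrum.meta.items()):
        lines.append(f"# {k}: {v}")
    lines.append("wavelength_nm\ttransmittance")
    for lam, t in zip(spectrum.wavelengths, spectrum.values):
        lines.append(f"{lam:.6f}\t{t:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> Spectrum:
    """Read the format produced by :func:`write_spectrum`."""
    path = Path(path)
    meta: dict = {}
    wl, vals = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            continue
        if line.startswith("wavelength"):
            continue
        a, b = line.split()
        wl.append(float(a))
        vals.append(float(b))
    scheme = meta.pop("scheme", "parallel")
    condition = meta.pop("condition", "with-analyte")
    replicate_id = int(meta.pop("replicate_id", 0))
    # numeric metadata comes back as float where possible
    parsed = {}
    for k, v in meta.items():
        try:
            parsed[k] = float(v)
        except ValueError:
            parsed[k] = v
    return Spectrum(
        np.array(wl), np.array(vals),
        scheme=scheme, condition=condition,
        replicate_id=replicate_id, meta=parsed,
    )
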