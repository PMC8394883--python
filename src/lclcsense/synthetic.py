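"""In-silico experiments with the statistical structure of a dilution assay.

The generator emulates an end-point measurement campaign: a dilution
series of analyte concentrations (decades from 1e-12 to 1e-5 g/mL by
default), each measured in replicate under parallel and crossed
polarizers, plus analyte-free reference cells, all on one 400-800 nm
grid.  The analyte's effect is summarized by a single azimuthal angle
phi(c) of the director via a logistic link in log10(concentration):

    phi(c) = phi_max / (1 + 10**(-hill * (log10 c - log10 c50)))

with phi(0) = 0.  The link is a synthetic stand-in: the underlying
physics fixes only that phi grows monotonically with analyte load from 0
(planar blank) and saturates, and the logistic is the simplest curve with
that shape.  phi is capped at 45 degrees so the generator stays on the
identifiable branch of sin^2(2 phi).

Noise is per-wavelength ``value * (1 + eps_mult) + eps_add`` with
independent Gaussian draws.  All randomness flows from one seeded
generator in a documented order (references first, then concentrations
ascending, replicates in order, parallel before crossed, multiplicative
before additive draws), so a manifest plus the seed fully determines
every file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .optics import CellOptics, default_cell, simulate_spectrum
from .spectra import Spectrum, write_spectrum

DEFAULT_CONCENTRATIONS = tuple(10.0 ** e for e in range(-12, -4))
DEFAULT_GRID = (400.0, 800.0, 401)


@dataclass(frozen=True)
class DoseResponseLink:
    """Logistic-in-log10(c) link from analyte concentration to azimuth."""

    phi_max: float = math.radians(40.0)   # radians, capped at pi/4
    c50: float = 10.0 ** -8.5             # g/mL at the half-maximal angle
    hill: float = 0.25                    # slope in decades^-1
    form: str = "logistic-in-log10c"

    def __post_init__(self):
        if not 0.0 < self.phi_max <= math.pi / 4 + 1e-12:
            raise ValueError("phi_max must lie in (0, pi/4]")
        if self.c50 <= 0 or self.hill <= 0:
            raise ValueError("c50 and hill must be positive")


def phi_of_concentration(link: DoseResponseLink, c):
    """phi(c) in radians; phi(0) = 0; monotone non-decreasing in c."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    out = np.zeros_like(c, dtype=float)
    pos = c > 0
    with np.errstate(divide="ignore"):
        x = np.log10(c, where=pos, out=np.full_like(c, -np.inf, dtype=float))
    out[pos] = link.phi_max / (
        1.0 + 10.0 ** (-link.hill * (x[pos] - math.log10(link.c50)))
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NoiseModel:
    """Per-wavelength instrument noise: value*(1+eps_mult)+eps_add."""

    multiplicative_sd: float = 0.02
    additive_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.multiplicative_sd < 0 or self.additive_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        eps_m = rng.normal(0.0, self.multiplicative_sd, size=values.shape) \
            if self.multiplicative_sd > 0 else 0.0
        eps_a = rng.normal(0.0, self.additive_sd, size=values.shape) \
            if self.additive_sd > 0 else 0.0
        return values * (1.0 + eps_m) + eps_a


@dataclass(frozen=True)
class SyntheticExperiment:
    """Configuration of one in-silico measurement campaign."""

    concentrations: tuple = DEFAULT_CONCENTRATIONS
    replicates: int = 3
    grid: tuple = DEFAULT_GRID            # (min_nm, max_nm, n_points)
    cell: CellOptics = field(default_factory=default_cell)
    link: DoseResponseLink = field(default_factory=DoseResponseLink)
    noise: NoiseModel = field(default_factory=NoiseModel)
    analyte_label: str = "BSA"

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing "
                             "and positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def wavelengths(self) -> np.ndarray:
        lo, hi, n = self.grid
        return np.linspace(lo, hi, int(n))


@dataclass
class ExperimentData:
    """Generated spectra, in memory, plus the manifest describing them."""

    config: SyntheticExperiment
    references: list                       # [(par, cross)] per replicate
    measurements: dict                     # concentration -> [(par, cross)]
    manifest: "object"                     # pandas DataFrame


def _noisy(spec: Spectrum, noise: NoiseModel, rng) -> Spectrum:
    return replace(spec, values=noise.apply(spec.values, rng))


def generate_experiment(config: SyntheticExperiment,
                        out_dir=None) -> ExperimentData:
    """Simulate the full campaign; optionally write the file tree.

    Draw order (one seeded stream): reference replicates first (parallel
    then crossed within each replicate, multiplicative noise before
    additive within each spectrum), then concentrations ascending with
    the same inner order.  Fixed seed => byte-identical output files.
    """
    import pandas as pd

    rng = np.random.default_rng(config.noise.seed)
    grid = config.wavelengths()
    cell_blank = replace(config.cell, azimuth_phi=0.0)
    rows = []
    references = []
    for rep in range(config.replicates):
        pair = []
        for scheme in ("parallel", "crossed"):
            clean = simulate_spectrum(cell_blank, grid, scheme,
                                      condition="analyte-free",
                                      replicate_id=rep)
            noisy = _noisy(clean, config.noise, rng)
            noisy.meta.update(concentration_g_per_mL=0.0,
                              analyte=config.analyte_label)
            pair.append(noisy)
            rows.append({"file": f"ref_r{rep}_{scheme}.tsv",
                         "condition": "analyte-free", "scheme": scheme,
                         "replicate": rep, "concentration_g_per_mL": 0.0,
                         "azimuth_phi_deg": 0.0})
        references.append(tuple(pair))

    measurements: dict = {}
    for ci, conc in enumerate(config.concentrations):
        phi = float(phi_of_concentration(config.link, conc))
        cell = replace(config.cell, azimuth_phi=phi)
        pairs = []
        for rep in range(config.replicates):
            pair = []
            for scheme in ("parallel", "crossed"):
                clean = simulate_spectrum(cell, grid, scheme,
                                          condition="with-analyte",
                                          replicate_id=rep)
                noisy = _noisy(clean, config.noise, rng)
                noisy.meta.update(concentration_g_per_mL=conc,
                                  analyte=config.analyte_label)
                pair.append(noisy)
                rows.append({
                    "file": f"{config.analyte_label}_c{ci:02d}_r{rep}_{scheme}.tsv",
                    "condition": "with-analyte", "scheme": scheme,
                    "replicate": rep, "concentration_g_per_mL": conc,
                    "azimuth_phi_deg": math.degrees(phi),
                })
            pairs.append(tuple(pair))
        measurements[conc] = pairs

    manifest = pd.DataFrame(rows)
    manifest.insert(0, "seed", config.noise.seed)
    manifest["multiplicative_sd"] = config.noise.multiplicative_sd
    manifest["additive_sd"] = config.noise.additive_sd
    data = ExperimentData(config, references, measurements, manifest)
    if out_dir is not None:
        write_experiment(data, out_dir)
    return data


def write_experiment(data: ExperimentData, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rep, (par, cross) in enumerate(data.references):
        write_spectrum(par, out / f"ref_r{rep}_parallel.tsv")
        write_spectrum(cross, out / f"ref_r{rep}_crossed.tsv")
    label = data.config.analyte_label
    for ci, conc in enumerate(data.config.concentrations):
        for rep, (par, cross) in enumerate(data.measurements[conc]):
            write_spectrum(par, out / f"{label}_c{ci:02d}_r{rep}_parallel.tsv")
            write_spectrum(cross, out / f"{label}_c{ci:02d}_r{rep}_crossed.tsv")
    data.manifest.to_csv(out / "manifest.csv", index=False)


def generate_empty_cell_spectrum(gap_nm: float, grid,
                                 noise: NoiseModel | None = None) -> Spectrum:
    """Two-beam interference spectrum of an empty (air) cell.

    T(lambda) = (1 + cos(4 pi d / lambda)) / 2, maxima at lambda = 2d/m.
    A zero gap gives a flat spectrum.
    """
    if gap_nm < 0:
        raise ValueError("gap must be >= 0")
    grid = np.asarray(grid, dtype=float)
    vals = 0.5 * (1.0 + np.cos(4.0 * np.pi * gap_nm / grid))
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        vals = noise.apply(vals, rng)
    return Spectrum(grid, vals, scheme="parallel", condition="analyte-free",
                    meta={"gap_nm": gap_nm, "kind": "empty-cell"})


def _logistic(x, phi_max, x50, hill):
    return phi_max / (1.0 + 10.0 ** (-hill * (x - x50)))


def fit_dose_response(concentrations, phi_values) -> DoseResponseLink:
    """Refit the logistic link to azimuth estimates along a dilution series.

    Used in parameter-recovery studies: generate with a known link,
    estimate phi per concentration, then recover (phi_max, c50, hill).
    """
    c = np.asarray(concentrations, dtype=float)
    phi = np.asarray(phi_values, dtype=float)
    x = np.log10(c)
    p0 = (min(float(phi.max()) * 1.2 + 1e-3, math.pi / 4),
          float(np.median(x)), 0.5)
    bounds = ([1e-4, x.min() - 4.0, 0.01],
              [math.pi / 4, x.max() + 4.0, 5.0])
    popt, _ = curve_fit(_logistic, x, phi, p0=p0, bounds=bounds,
                        maxfev=20000)
    phi_max, x50, hill = popt
    return DoseResponseLink(phi_max=float(phi_max), c50=float(10.0 ** x50),
                            hill=float(hill))
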