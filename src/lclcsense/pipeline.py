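"""End-to-end quantitation workflow.

Chains the stages the way an assay analyst would: average the
analyte-free reference replicates, reduce every analyte spectrum pair
against them, aggregate replicates per concentration, fit per-wavelength
calibration curves for T_par and T_cross (cubic in log10 c) and the
T_par/T_cross ratio (linear in log10 c), derive 3s/m limits of detection
from linear fits over the low-concentration range, and optionally invert
the calibrations for unknown samples.  Every artifact is delimited text;
every run is reproducible from the config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCurve,
    limit_of_detection,
)
from .reduction import TransmittanceReducer, aggregate_replicates
from .spectra import read_spectrum
from .synthetic import (
    ExperimentData,
    SyntheticExperiment,
    generate_experiment,
)

DEFAULT_WAVELENGTHS = tuple(float(w) for w in range(450, 801, 50))


@dataclass
class RunConfig:
    """Configuration of one quantitation run.

    Exactly one of ``synthetic`` or ``input_dir`` must be set.  All angles
    at this level are degrees, concentrations g/mL, wavelengths nm.
    """

    synthetic: SyntheticExperiment | None = None
    input_dir: str | None = None
    wavelengths: tuple = DEFAULT_WAVELENGTHS
    lod_convention: str = "abscissa-domain"
    lod_n_low: int = 3            # linear range: n lowest concentrations
    unknowns: list = field(default_factory=list)   # [(par, cross) pairs]
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of synthetic config or input_dir is required"
            )
        if len(self.wavelengths) < 1:
            raise ValueError("at least one analysis wavelength is required")


@dataclass
class QuantitationReport:
    config: RunConfig
    aggregated: dict                   # concentration -> AggregatedReduced
    calibrations: dict                 # channel -> {wavelength: model}
    lod_table: pd.DataFrame
    predictions: pd.DataFrame | None
    log: list


def load_experiment(input_dir) -> ExperimentData:
    """Read a generated (or instrument-exported) experiment tree back in."""
    input_dir = Path(input_dir)
    manifest = pd.read_csv(input_dir / "manifest.csv")
    refs: dict = {}
    meas: dict = {}
    for _, row in manifest.iterrows():
        spec = read_spectrum(input_dir / row["file"])
        key = (int(row["replicate"]), row["scheme"])
        if row["condition"] == "analyte-free":
            refs[key] = spec
        else:
            meas.setdefault(float(row["concentration_g_per_mL"]), {})[key] = spec
    n_rep = 1 + max(k[0] for k in refs)
    references = [(refs[(r, "parallel")], refs[(r, "crossed")])
                  for r in range(n_rep)]
    measurements = {}
    for conc in sorted(meas):
        by_key = meas[conc]
        reps = 1 + max(k[0] for k in by_key)
        measurements[conc] = [
            (by_key[(r, "parallel")], by_key[(r, "crossed")])
            for r in range(reps)
        ]
    return ExperimentData(None, references, measurements, manifest)


def _mean_reference_pair(references) -> tuple:
    """Average reference replicates into a single (parallel, crossed) pair."""
    par0, cross0 = references[0]
    par_vals = np.mean([p.values for p, _ in references], axis=0)
    cross_vals = np.mean([c.values for _, c in references], axis=0)
    return (replace(par0, values=par_vals, replicate_id=0),
            replace(cross0, values=cross_vals, replicate_id=0))


def reduce_experiment(data: ExperimentData,
                      analyte_label: str = "") -> dict:
    """Reduce and aggregate every concentration; returns
    {concentration: AggregatedReduced}, concentrations ascending."""
    ref_par, ref_cross = _mean_reference_pair(data.references)
    reducer = TransmittanceReducer().fit((ref_par, ref_cross))
    out = {}
    for conc in sorted(data.measurements):
        records = [
            reducer.transform(pair, concentration=conc,
                              analyte_label=analyte_label)
            for pair in data.measurements[conc]
        ]
        out[conc] = aggregate_replicates(records)
    return out


def _channel_points(aggregated: dict, wavelength: float, channel: str):
    """(concentrations, mean responses, sds) at one wavelength, skipping
    concentrations where the channel is undefined (NaN ratio)."""
    concs, ys, sds = [], [], []
    for conc, agg in aggregated.items():
        y = agg.mean.at(wavelength, channel)
        if np.isnan(y):
            continue
        i = int(np.argmin(np.abs(agg.wavelengths - wavelength)))
        concs.append(conc)
        ys.append(y)
        sds.append(float(agg.sd(channel)[i]))
    return np.array(concs), np.array(ys), np.array(sds)


def run_quantitation(config: RunConfig) -> QuantitationReport:
    log: list = []
    if config.synthetic is not None:
        data = generate_experiment(config.synthetic)
        label = config.synthetic.analyte_label
        log.append(f"generated synthetic experiment: "
                   f"{len(config.synthetic.concentrations)} concentrations, "
                   f"n={config.synthetic.replicates}, "
                   f"seed={config.synthetic.noise.seed}")
    else:
        data = load_experiment(config.input_dir)
        label = ""
        log.append(f"loaded experiment from {config.input_dir}")

    aggregated = reduce_experiment(data, analyte_label=label)
    concs_all = np.array(sorted(aggregated))
    log.append(f"reduced {concs_all.size} concentrations")

    channel_forms = {"T_parallel": "cubic-polynomial",
                     "T_crossed": "cubic-polynomial",
                     "ratio": "linear"}
    calibrations: dict = {ch: {} for ch in channel_forms}
    cal_rows = []
    for channel, form in channel_forms.items():
        for wl in config.wavelengths:
            c, y, sd = _channel_points(aggregated, wl, channel)
            need = 4 if form.startswith("cubic") else 2
            if np.unique(c).size < need:
                log.append(f"skip {channel}@{wl:.0f}nm: "
                           f"{np.unique(c).size} usable points < {need}")
                continue
            model = CalibrationCurve(response=channel, wavelength=wl,
                                     form=form).fit(c, y, y_sd=sd)
            calibrations[channel][wl] = model
            cal_rows.append({
                "channel": channel, "wavelength_nm": wl, "form": form,
                "n_points": model.n_points_,
                "r_squared": model.r_squared_,
                **{f"coef{i}": v for i, v in enumerate(model.coef_)},
            })
    cal_table = pd.DataFrame(cal_rows)

    # 3s/m LODs from linear fits over the low-concentration range
    low = concs_all[: config.lod_n_low]
    lod_rows = []
    for channel in ("T_parallel", "T_crossed"):
        for wl in config.wavelengths:
            c, y, _ = _channel_points(
                {k: v for k, v in aggregated.items() if k in low},
                wl, channel)
            if np.unique(c).size < 2:
                continue
            lin = CalibrationCurve(response=channel, wavelength=wl,
                                   form="linear").fit(c, y)
            res = limit_of_detection(lin, config.lod_convention)
            lod_rows.append({
                "channel": channel, "wavelength_nm": wl,
                "slope": res.slope_m, "intercept_se": res.intercept_sd_s,
                "lod_g_per_mL": res.lod_concentration,
                "convention": res.convention,
            })
    lod_table = pd.DataFrame(lod_rows)
    log.append(f"LOD table: {len(lod_table)} rows, "
               f"convention={config.lod_convention}, "
               f"linear range = {config.lod_n_low} lowest concentrations")

    predictions = None
    if config.unknowns:
        ref_pair = _mean_reference_pair(data.references)
        reducer = TransmittanceReducer().fit(ref_pair)
        pred_rows = []
        for ui, pair in enumerate(config.unknowns):
            red = reducer.transform(pair)
            for channel in ("T_parallel", "T_crossed"):
                for wl, model in calibrations[channel].items():
                    yv = red.at(wl, channel)
                    # first-order response sd: calibration residual scatter
                    # combined with the replicate-level measurement noise
                    meas_sd = 0.0
                    if model.y_sd_ is not None:
                        meas_sd = float(np.nanmedian(model.y_sd_))
                    y_sd = float(np.hypot(model.residual_sd_, meas_sd))
                    try:
                        # ~95% first-order interval
                        pred = model.predict_concentration(
                            yv, response_sd=y_sd, z=1.96)
                    except Exception as exc:   # out of range / ambiguous
                        log.append(f"unknown {ui} {channel}@{wl:.0f}nm: "
                                   f"{type(exc).__name__}: {exc}")
                        continue
                    pred_rows.append({
                        "unknown": ui, "channel": channel,
                        "wavelength_nm": wl, "response": yv,
                        "concentration_g_per_mL": pred.concentration,
                        "lower_g_per_mL": pred.lower,
                        "upper_g_per_mL": pred.upper,
                    })
        predictions = pd.DataFrame(pred_rows)
        log.append(f"predicted {len(config.unknowns)} unknown sample(s)")

    report = QuantitationReport(config, aggregated, calibrations,
                                lod_table, predictions, log)
    if config.out_dir is not None:
        write_report(report, cal_table, config.out_dir)
    return report


def write_report(report: QuantitationReport, cal_table: pd.DataFrame,
                 out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for conc, agg in report.aggregated.items():
        for i, wl in enumerate(agg.wavelengths):
            rows.append({
                "concentration_g_per_mL": conc, "wavelength_nm": wl,
                "T_parallel": agg.mean.T_parallel[i],
                "T_crossed": agg.mean.T_crossed[i],
                "ratio": agg.mean.ratio[i],
                "sd_T_parallel": agg.sd_T_parallel[i],
                "sd_T_crossed": agg.sd_T_crossed[i],
                "n": agg.n,
            })
    pd.DataFrame(rows).to_csv(out / "reduced.csv", index=False)
    cal_table.to_csv(out / "calibrations.csv", index=False)
    report.lod_table.to_csv(out / "lod.csv", index=False)
    if report.predictions is not None:
        report.predictions.to_csv(out / "predictions.csv", index=False)
    (out / "run_log.txt").write_text("\n".join(report.log) + "\n")


def plot_report(report: QuantitationReport, out_dir) -> list:
    """Render the standard figures; returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    # 1. reduced spectra overlay
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for conc, agg in report.aggregated.items():
        axes[0].plot(agg.wavelengths, agg.mean.T_parallel,
                     label=f"{conc:.0e}")
        axes[1].plot(agg.wavelengths, agg.mean.T_crossed)
    axes[0].set_ylabel(r"$T_\parallel$")
    axes[1].set_ylabel(r"$T_\perp$")
    for ax in axes:
        ax.set_xlabel("wavelength (nm)")
    axes[0].legend(fontsize=6, title="c (g/mL)")
    fig.tight_layout()
    p = out / "reduced_spectra.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    # 2. calibration curves with cubic fits
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, channel in zip(axes, ("T_parallel", "T_crossed")):
        for wl, model in sorted(report.calibrations[channel].items()):
            ax.plot(model.x_, model.y_, "o", ms=3)
            xs = np.linspace(*model.fit_range_, 200)
            ax.plot(xs, model.predict_response_at_log10c(xs), "-", lw=1,
                    label=f"{wl:.0f} nm")
        ax.set_xlabel(r"$\log_{10}$ c (g/mL)")
        ax.set_ylabel(channel)
    axes[0].legend(fontsize=6)
    fig.tight_layout()
    p = out / "calibration_curves.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    # 3. ratio linear fits with R^2 annotations
    fig, ax = plt.subplots(figsize=(6, 4))
    for wl, model in sorted(report.calibrations["ratio"].items()):
        ax.plot(model.x_, model.y_, "o", ms=3)
        xs = np.linspace(*model.fit_range_, 50)
        ax.plot(xs, model.predict_response_at_log10c(xs), "-", lw=1,
                label=f"{wl:.0f} nm, $R^2$={model.r_squared_:.3f}")
    ax.set_xlabel(r"$\log_{10}$ c (g/mL)")
    ax.set_ylabel(r"$T_\parallel/T_\perp$")
    if report.calibrations["ratio"]:
        ax.legend(fontsize=6)
    fig.tight_layout()
    p = out / "ratio_calibration.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)
    return paths


def make_unknown_pair(config: SyntheticExperiment, concentration: float,
                      seed_offset: int = 7919) -> tuple:
    """Generate one noisy unknown-sample pair at a hidden concentration,
    on the experiment's grid and noise model but an independent stream."""
    from .optics import simulate_spectrum
    from .synthetic import phi_of_concentration

    rng = np.random.default_rng(config.noise.seed + seed_offset)
    phi = float(phi_of_concentration(config.link, concentration))
    cell = replace(config.cell, azimuth_phi=phi)
    grid = config.wavelengths()
    pair = []
    for scheme in ("parallel", "crossed"):
        clean = simulate_spectrum(cell, grid, scheme)
        pair.append(replace(clean, values=config.noise.apply(clean.values, rng)))
    return tuple(pair)
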