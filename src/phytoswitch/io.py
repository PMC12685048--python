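"""Delimited-text I/O, schema validation, configuration, and workflows.

All tabular formats are UTF-8 comma-separated text with a header row; times
in seconds, wavelengths in nm.  Configuration files are YAML with explicit
unit suffixes on physical keys (e.g. ``off_peak_kw_per_cm2``,
``half_time_us``) because protocol sources mix mW, kW/cm^2 and
umol m^-2 s^-1 — units in key names keep conversions auditable.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError, SchemaError

logger = logging.getLogger("phytoswitch")

#: column schemas: name -> (required columns, strictly-increasing column or None)
TABLE_SCHEMAS = {
    "trace": (["time_s", "signal"], "time_s"),
    "absorbance": (["time_s", "absorbance"], "time_s"),
    "spectrum": (["wavelength_nm", "value"], "wavelength_nm"),
    "titration": (["ph", "signal"], "ph"),
    "phantom": (["x_nm", "y_nm", "weight"], None),
    "maxima": (["cycle", "maximum"], "cycle"),
}


def load_table(path, schema: str) -> pd.DataFrame:
    """Load and validate a delimited-text table against a named schema.

    Unknown extra columns are preserved with a warning; a missing required
    column or a non-monotone ordering column raises ``SchemaError`` naming
    the offending row.
    """
    if schema not in TABLE_SCHEMAS:
        raise InvalidArgumentError(
            f"unknown schema '{schema}'; known: {sorted(TABLE_SCHEMAS)}"
        )
    required, monotone_col = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: extra columns preserved: {extra}", stacklevel=2)
    for col in required:
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(f"{path}: column '{col}' is not numeric")
    if monotone_col is not None:
        diffs = np.diff(df[monotone_col].to_numpy())
        bad = np.nonzero(diffs <= 0)[0]
        if bad.size:
            raise SchemaError(
                f"{path}: column '{monotone_col}' not strictly increasing at row "
                f"{int(bad[0]) + 1}"
            )
    return df


def save_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return cfg


def write_report(report: dict, path) -> None:
    """Write a JSON report (deterministic key order)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def trace_from_table(df: pd.DataFrame, signal_column: str = "signal"):
    from .traces import Trace

    return Trace(df["time_s"].to_numpy(), df[signal_column].to_numpy())


def spectrum_from_table(df: pd.DataFrame):
    from .spectra import Spectrum

    return Spectrum(df["wavelength_nm"].to_numpy(), df["value"].to_numpy())


KNOWN_WORKFLOWS = ("characterize", "simulate-imaging", "make-synthetic")


def run_workflow(config: dict, output_dir=None, seed: int | None = None) -> dict:
    """Execute a named workflow from a validated configuration.

    ``characterize`` runs the trace fitters over a directory of delimited
    trace files (one fit per file, fit kind from the ``fits`` mapping);
    ``simulate-imaging`` runs a phantom scan; ``make-synthetic`` produces a
    synthetic dataset.  Returns the JSON-ready report; stage errors are
    re-raised annotated with the stage name.
    """
    workflow = config.get("workflow")
    if workflow not in KNOWN_WORKFLOWS:
        raise InvalidArgumentError(
            f"unknown workflow '{workflow}'; known: {KNOWN_WORKFLOWS}"
        )
    out = Path(output_dir) if output_dir else Path(config.get("output_dir", "."))
    report = {"workflow": workflow, "seed": seed}
    try:
        if workflow == "characterize":
            report["fits"] = _characterize(config)
        elif workflow == "simulate-imaging":
            report["imaging"] = _simulate_imaging(config, out, seed)
        else:
            report["synthetic"] = _make_synthetic(config, out, seed)
    except Exception as exc:
        logger.error("workflow stage '%s' failed: %s", workflow, exc)
        raise
    write_report(report, out / f"{workflow}-report.json")
    return report


def _characterize(config: dict) -> dict:
    from . import traces as ta

    fits_cfg = config.get("fits", {})
    input_dir = Path(config["input_dir"])
    files = sorted(input_dir.glob("*.csv"))
    if not files:
        raise InvalidArgumentError(f"no input tables found in {input_dir}")
    results = {}
    for path in files:
        kind = fits_cfg.get(path.stem, fits_cfg.get("default", "off_switching"))
        if kind == "off_switching":
            fit = ta.fit_off_switching(trace_from_table(load_table(path, "trace")))
            results[path.stem] = {
                "half_time_s": fit.half_time,
                "residual_fraction": fit.residual_fraction,
                "model": fit.model_label,
            }
        elif kind == "recovery":
            fit = ta.fit_thermal_recovery(trace_from_table(load_table(path, "trace")))
            results[path.stem] = {
                "half_recovery_time_s": fit.half_recovery_time,
                "model": fit.model_label,
                "components": list(fit.components),
            }
        elif kind == "pka":
            df = load_table(path, "titration")
            pka, hill, rep = ta.fit_pka(df["ph"].to_numpy(), df["signal"].to_numpy())
            results[path.stem] = {"pka": pka, "hill": hill, **rep}
        elif kind == "bleach":
            half, params = ta.fit_photobleaching(
                trace_from_table(load_table(path, "trace"))
            )
            results[path.stem] = {"frames_to_half": half, **params}
        else:
            raise InvalidArgumentError(f"unknown fit kind '{kind}' for {path.name}")
    return results


def _simulate_imaging(config: dict, out: Path, seed):
    import tifffile

    from . import resolft as rs

    phantom_path = config.get("phantom")
    if phantom_path:
        df = load_table(phantom_path, "phantom")
        phantom = rs.Phantom(
            positions=df[["x_nm", "y_nm"]].to_numpy(),
            weights=df["weight"].to_numpy(),
            field_size=tuple(config["field_size_nm"]),
        )
    else:
        from .synthetic import generate_filament_phantom

        phantom = generate_filament_phantom(seed=seed)
    seq = rs.PixelSequence(
        relax_time=config.get("relax_time_ms", 5.0) * 1e-3,
        off_time=config.get("off_time_us", 400.0) * 1e-6,
        off_peak=config.get("off_peak_kw_per_cm2", 1.1),
        readout_time=config.get("readout_time_us", 10.0) * 1e-6,
        readout_peak=config.get("readout_peak_kw_per_cm2", 103.0),
        pixel_pitch=config.get("pixel_pitch_nm", 30.0),
    )
    params = rs.default_imaging_parameters()
    off_beam = rs.make_beam_profile("doughnut", seq.off_peak,
                                    config.get("doughnut_width_nm", 320.0), 660.0)
    read_beam = rs.make_beam_profile("gaussian", seq.readout_peak,
                                     config.get("confocal_fwhm_nm", 240.0), 660.0)
    pair = rs.simulate_scan(phantom, seq, params, off_beam, read_beam, seed=seed)
    out.mkdir(parents=True, exist_ok=True)
    for name, img in (("confocal", pair.confocal), ("resolft", pair.resolft)):
        tifffile.imwrite(
            out / f"{name}.tiff",
            np.clip(img, 0, 65535).astype(np.uint16),
        )
    write_report(pair.metadata, out / "imaging-metadata.json")
    return pair.metadata


def _make_synthetic(config: dict, out: Path, seed):
    from . import synthetic as syn

    kind = config.get("kind", "switch_trace")
    out.mkdir(parents=True, exist_ok=True)
    if kind == "switch_trace":
        trace, truth = syn.generate_switching_trace(seed=seed)
        save_table(pd.DataFrame({"time_s": trace.times, "signal": trace.signal}),
                   out / "switch_trace.csv")
    elif kind == "absorbance_series":
        series, truth = syn.generate_absorbance_series(seed=seed)
        save_table(pd.DataFrame({"time_s": series.times,
                                 "absorbance": series.absorbance}),
                   out / "absorbance_series.csv")
    elif kind == "titration":
        ph, signal, truth = syn.generate_titration(noise_fraction=0.03, seed=seed)
        save_table(pd.DataFrame({"ph": ph, "signal": signal}), out / "titration.csv")
    elif kind == "fatigue_series":
        maxima, truth = syn.generate_fatigue_series(noise_fraction=0.02, seed=seed)
        save_table(pd.DataFrame({"cycle": np.arange(maxima.size), "maximum": maxima}),
                   out / "fatigue_series.csv")
    elif kind == "recovery_trace":
        trace, truth = syn.generate_recovery_trace(noise_sd=0.05, seed=seed)
        save_table(pd.DataFrame({"time_s": trace.times, "signal": trace.signal}),
                   out / "recovery_trace.csv")
    elif kind == "bleach_series":
        trace, truth = syn.generate_bleach_series(noise_fraction=0.02, seed=seed)
        save_table(pd.DataFrame({"time_s": trace.times, "signal": trace.signal}),
                   out / "bleach_series.csv")
    elif kind == "phantom":
        phantom = syn.generate_filament_phantom(seed=seed)
        truth = {"n_labels": int(phantom.positions.shape[0])}
        save_table(pd.DataFrame({"x_nm": phantom.positions[:, 0],
                                 "y_nm": phantom.positions[:, 1],
                                 "weight": phantom.weights}),
                   out / "phantom.csv")
    else:
        raise InvalidArgumentError(f"unknown synthetic kind '{kind}'")
    write_report({"kind": kind, "truth": truth}, out / f"{kind}-truth.json")
    return {"kind": kind, "truth": truth}
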