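"""End-to-end runs: calibration, transfer to process data, QC-gated reports.

``run_calibration`` turns a raw calibration series into a fitted model: it
executes the model's preprocessing recipe, selects PLS components by an
80/20 cross-validation split, re-derives VIP intervals from the data for the
refined precipitant models, and evaluates on an optional held-out test
series.  ``run_transfer`` applies fitted models to raw process spectra with
saturation/defect QC computed on the raw averaged blocks; predictions from
flagged spectra are emitted *with* their flag rather than dropped, so the
prediction time series stays complete.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import chemometrics as chem
from .preprocess import PipelineConfig, get_config, run_pipeline
from .qc import QCReport, detect_defective, detect_saturation, DEFAULT_CLIP_LEVEL
from .spectra import SpectrumSet, SpectraError, average_block

__all__ = ["RunManifest", "run_calibration", "run_transfer", "report"]

logger = logging.getLogger("ramanpat")

#: anchors (cm^-1) of the sulfate bands that stay below detector saturation
#: at the high transfer exposure time; the 2-interval refined model keeps the
#: derived VIP intervals containing these.
VIP2_ANCHORS = (451.0, 1106.0)

_UNIT = {"AMS": "mol/L", "VLP": "g/L"}


@dataclass
class RunManifest:
    """Reproducibility record: configs, seeds, hashes, step log."""

    config_name: str = ""
    seed: int | None = None
    steps: list[str] = field(default_factory=list)
    model_hash: str = ""
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def log(self, message: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        self.steps.append(f"{stamp} {message}")
        logger.info(message)

    def to_json(self) -> str:
        return json.dumps({
            "config_name": self.config_name, "seed": self.seed,
            "steps": self.steps, "model_hash": self.model_hash,
            "inputs": self.inputs, "outputs": self.outputs, "extra": self.extra,
        }, indent=2, default=str)


def _model_hash(model) -> str:
    return hashlib.sha256(chem.model_to_json(model).encode()).hexdigest()[:16]


def _analyte_of(config: PipelineConfig) -> str:
    return "AMS" if config.name.endswith("AMS") or config.normalize_wavenumber else "VLP"


def derive_vip_config(calib_set: SpectrumSet, config: PipelineConfig,
                      seed: int, threshold: float = 1.0, min_width: int = 5,
                      merge_gap: float = 5.0) -> tuple[PipelineConfig, list]:
    """Re-derive the crop intervals of a refined (VIP) model from the data.

    Fits the full-spectrum PLS model, computes VIP scores, groups
    above-threshold wavenumbers into intervals, and — for the 2-interval
    model — keeps the intervals containing the non-saturating sulfate band
    anchors.  Falls back to the built-in intervals if derivation selects
    nothing usable.
    """
    base = get_config("PLS_AMS", average_n=config.average_n)
    processed = run_pipeline(calib_set, base)
    X, y = processed.intensity_matrix, processed.reference
    a_sel, _ = chem.cv_select_components(X, y, seed=seed)
    model = chem.nipals_pls_fit(X, y, a_sel)
    vip = chem.vip_scores(model, wavenumbers=processed.axis.values)
    intervals = chem.select_vip_intervals(vip, threshold=threshold,
                                          min_width=min_width, merge_gap=merge_gap)
    if config.name == "PLS_VIP2_AMS":
        kept = [iv for iv in intervals
                if any(iv[0] <= a <= iv[1] for a in VIP2_ANCHORS)]
        intervals = kept or intervals
    if not intervals:
        return config, []
    return replace(config, crop_include=tuple(intervals)), intervals


def run_calibration(calib_set: SpectrumSet, config_name: str | PipelineConfig,
                    seed: int = 0, test_set: SpectrumSet | None = None,
                    derive_vip: bool = True):
    """Fit one calibration model; returns ``(model, fit_report, manifest)``.

    The test evaluation follows the calibration design: precipitant models
    are tested on a series recorded at a different exposure time, product
    models on a held-out series at the training exposure time (``test_set``
    supplies either).  Without a test set the report is the training fit.
    """
    if calib_set.reference is None:
        raise SpectraError("calibration set carries no reference concentrations")
    config = (get_config(config_name) if isinstance(config_name, str)
              else config_name)
    manifest = RunManifest(config_name=config.name, seed=seed)
    manifest.log(f"calibrate {config.name} on {len(calib_set)} raw spectra")
    if derive_vip and config.name.startswith("PLS_VIP"):
        config, intervals = derive_vip_config(calib_set, config, seed)
        manifest.extra["vip_intervals"] = [list(iv) for iv in intervals]
        manifest.extra["vip_threshold"] = 1.0
        manifest.log(f"derived VIP intervals: {intervals}")
    processed = run_pipeline(calib_set, config)
    manifest.extra["pipeline_steps"] = list(processed.provenance)
    X, y = processed.intensity_matrix, processed.reference
    if config.name.startswith("LR"):
        model = chem.fit_linear(processed, config.crop_include[0][0])
        manifest.log(f"linear fit at {model.wavenumber} cm^-1")
    else:
        a_sel, cv_table = chem.cv_select_components(X, y, seed=seed)
        manifest.extra["cv_table"] = {str(k): v for k, v in cv_table.items()}
        manifest.extra["selected_components"] = a_sel
        manifest.log(f"CV selected {a_sel} latent variables")
        model = chem.nipals_pls_fit(X, y, a_sel)
        model.retained_wavenumbers = processed.axis.values.copy()
        model.scaler = getattr(processed, "scaler_state", None)
    model.pipeline = config
    manifest.model_hash = _model_hash(model)
    if test_set is not None:
        test_processed = run_pipeline(
            test_set, config, scaler=getattr(processed, "scaler_state", None))
        fit_report = chem.metrics(chem.predict(model, test_processed),
                                  test_processed.reference)
        manifest.log(f"test evaluation: RMSE={fit_report.rmse:.4g} R2={fit_report.r2}")
    else:
        fit_report = chem.metrics(chem.predict(model, processed), y)
        manifest.log(f"training fit: RMSE={fit_report.rmse:.4g} R2={fit_report.r2}")
    return model, fit_report, manifest


def _retained_intervals(model) -> list[tuple[float, float]]:
    if isinstance(model, chem.LinearModel):
        return [(model.wavenumber, model.wavenumber)]
    return [tuple(iv) for iv in model.pipeline.crop_include]


def run_transfer(models: list, process_set: SpectrumSet,
                 qc: dict | None = None):
    """Apply calibrated models to raw process spectra with QC gating.

    Returns ``(prediction_table, qc_report, manifest)``.  QC runs on the
    raw averaged blocks: oversaturation of the sulfate band flags the
    predictions of every model whose retained wavenumbers intersect the
    saturated interval; defective spectra flag all models.  Flagged rows
    are emitted with their flag, ordered by dv.
    """
    if not models:
        raise ValueError("no models supplied")
    qc = dict(qc or {})
    clip_level = qc.get("clip_level", DEFAULT_CLIP_LEVEL)
    band = qc.get("band", (940.0, 1020.0))
    defect_window = qc.get("defect_window", 7)
    defect_k = qc.get("defect_k", 6.0)
    run_qc = qc.get("enabled", True)
    manifest = RunManifest(config_name="transfer")
    n_avg = models[0].pipeline.average_n or 1
    averaged = average_block(process_set, n_avg) if n_avg > 1 else process_set
    manifest.log(f"averaged {len(process_set)} recordings into {len(averaged)} blocks")
    n = len(averaged)
    if run_qc:
        sat = [detect_saturation(s, clip_level=clip_level, band=band)
               for s in averaged]
        try:
            defect = detect_defective(averaged, window=defect_window, k=defect_k)
        except SpectraError:
            defect = QCReport(flags=["ok"] * n, saturated_intervals=[None] * n,
                              defect_scores=np.zeros(n))
        qc_report = QCReport(
            flags=[("defective" if d == "defective" else s_flag)
                   for (s_flag, _), d in zip(sat, defect.flags)],
            saturated_intervals=[iv for _, iv in sat],
            defect_scores=defect.defect_scores)
    else:
        sat = [("ok", None)] * n
        qc_report = QCReport(flags=["ok"] * n, saturated_intervals=[None] * n,
                             defect_scores=np.zeros(n))
    rows = []
    for model in models:
        config = model.pipeline
        if config is None:
            raise ValueError("model lacks its preprocessing pipeline")
        if config.normalize_wavenumber is None:
            exposures = {s.exposure_time_ms for s in averaged}
            required = qc.get("vlp_exposure_ms", 1250.0)
            if exposures != {required}:
                raise SpectraError(
                    f"model {config.name} lacks normalization and requires "
                    f"{required} ms data, got exposure times {sorted(exposures)}")
        processed = run_pipeline(averaged, replace(config, average_n=None),
                                 scaler=model.scaler if hasattr(model, "scaler") else None)
        preds = chem.predict(model, processed)
        intervals = _retained_intervals(model)
        analyte = _analyte_of(config)
        for i, spec in enumerate(averaged):
            flag = "ok"
            if qc_report.flags[i] == "defective":
                flag = "defective"
            elif sat[i][0] == "saturated":
                lo, hi = sat[i][1]
                if any(a <= hi and b >= lo for a, b in intervals):
                    flag = "saturated"
            rows.append({"dv": spec.dv, "model_name": config.name,
                         "prediction": float(preds[i]), "unit": _UNIT[analyte],
                         "flag": flag})
        manifest.log(f"transferred {config.name} (hash {_model_hash(model)})")
    table = (pd.DataFrame(rows)
             .sort_values(["dv", "model_name"], kind="stable")
             .reset_index(drop=True))
    return table, qc_report, manifest


def report(prediction_table: pd.DataFrame,
           ground_truth: pd.DataFrame | None = None,
           include_flagged: bool = False) -> dict:
    """Summarize predictions: flag counts and, with truth, RMSE/R2 per model.

    ``ground_truth`` columns: ``dv`` plus ``c_ams`` and/or ``c_vlp``; truth
    is interpolated onto each prediction's dv.  Flagged rows are excluded
    from the error metrics by default.
    """
    summary: dict = {"models": {}, "n_rows": int(len(prediction_table))}
    for name, group in prediction_table.groupby("model_name"):
        entry: dict = {"flag_counts": group["flag"].value_counts().to_dict()}
        if ground_truth is not None:
            col = "c_ams" if group["unit"].iloc[0] == "mol/L" else "c_vlp"
            if col in ground_truth.columns:
                rows = group if include_flagged else group[group["flag"] == "ok"]
                if len(rows) >= 2:
                    truth = np.interp(rows["dv"].to_numpy(dtype=float),
                                      ground_truth["dv"].to_numpy(dtype=float),
                                      ground_truth[col].to_numpy(dtype=float))
                    fit = chem.metrics(rows["prediction"].to_numpy(dtype=float), truth)
                    entry["rmse"] = fit.rmse
                    entry["r2"] = fit.r2
                    entry["n_used"] = fit.n_test
        summary["models"][str(name)] = entry
    return summary
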