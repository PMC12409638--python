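"""Canonical synthetic study conditions and their evaluation runs.

These functions reproduce, on synthetic data, the calibration and transfer
studies the package is built around: cross-exposure-time precipitant
calibration (fit at 175 ms, test at 110 ms), product calibration with
residual-precipitant interference at 1,250 ms, and saturation-aware model
transfer to a continuous dual-stage filtration run.  All problem sizes and
noise levels are the package's standard study conditions (12 evenly spaced
precipitant levels over 0-1.1 M and 8 product levels over 0-2.2 g/L, 50
recordings per level, detector noise 0.3% of full scale per recording); a
single base seed deterministically derives every stream of randomness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import chemometrics as chem
from .orchestrate import run_calibration, run_transfer, report
from .preprocess import get_config, run_pipeline
from .synthetic import (GeneratorConfig, generate_process_spectra,
                        generate_stock_series, simulate_cff_process)

__all__ = ["derive_seeds", "ams_calibration_study", "vlp_calibration_study",
           "saturation_transfer_study", "noiseless_identity_study"]

AMS_LEVELS = np.linspace(0.0, 1.1, 12)
VLP_LEVELS = np.linspace(0.0, 2.2, 8)
RECORDINGS_PER_LEVEL = 50
CALIB_EXPOSURE_MS = 175.0
TEST_EXPOSURE_MS = 110.0
VLP_EXPOSURE_MS = 1250.0


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent sub-seeds (< 2^31) from one base seed."""
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2 ** 31, size=n)]


def ams_calibration_study(base_seed: int = 1) -> dict:
    """Precipitant calibration at 175 ms, test at 110 ms.

    Fits the single-wavenumber linear model, the full-spectrum PLS model
    (components by 80/20 cross-validation over 2-10) and the two refined
    VIP-interval models; reports test RMSE / R^2 for each and the CV
    component selection across three CV seeds.
    """
    calib_seed, test_seed, cv_a, cv_b, cv_c = derive_seeds(base_seed, 5)
    config = GeneratorConfig(seed=base_seed)
    calib = generate_stock_series("AMS", AMS_LEVELS, RECORDINGS_PER_LEVEL,
                                  CALIB_EXPOSURE_MS, config, seed=calib_seed)
    test = generate_stock_series("AMS", AMS_LEVELS, RECORDINGS_PER_LEVEL,
                                 TEST_EXPOSURE_MS, config, seed=test_seed)
    out: dict = {"n_levels": len(AMS_LEVELS)}
    lr_model, lr_fit, _ = run_calibration(calib, "LR_AMS", seed=cv_a,
                                          test_set=test)
    out["lr_rmse"], out["lr_r2"] = lr_fit.rmse, lr_fit.r2
    pls_model, pls_fit, pls_manifest = run_calibration(calib, "PLS_AMS",
                                                       seed=cv_a, test_set=test)
    out["pls_rmse"], out["pls_r2"] = pls_fit.rmse, pls_fit.r2
    out["pls_components"] = pls_manifest.extra["selected_components"]
    # component selection stability across CV splits
    processed = run_pipeline(calib, get_config("PLS_AMS"))
    X, y = processed.intensity_matrix, processed.reference
    out["cv_components_by_seed"] = [
        chem.cv_select_components(X, y, seed=s)[0] for s in (cv_a, cv_b, cv_c)]
    for name, key in (("PLS_VIP4_AMS", "vip4"), ("PLS_VIP2_AMS", "vip2")):
        model, fit, manifest = run_calibration(calib, name, seed=cv_a,
                                               test_set=test)
        out[f"{key}_rmse"], out[f"{key}_r2"] = fit.rmse, fit.r2
        out[f"{key}_intervals"] = manifest.extra.get("vip_intervals", [])
        out[f"{key}_model"] = model
    out["lr_model"], out["pls_model"] = lr_model, pls_model
    out["calib_set"] = calib
    return out


def vlp_calibration_study(base_seed: int = 1) -> dict:
    """Product calibration and held-out test series, both at 1,250 ms.

    Runs all four pre-crop x crop pipeline combinations and reports the
    test RMSE / R^2 per model.
    """
    calib_seed, test_seed, cv_seed = derive_seeds(base_seed + 7, 3)
    config = GeneratorConfig(seed=base_seed)
    calib = generate_stock_series("VLP", VLP_LEVELS, RECORDINGS_PER_LEVEL,
                                  VLP_EXPOSURE_MS, config, seed=calib_seed)
    test = generate_stock_series("VLP", VLP_LEVELS, RECORDINGS_PER_LEVEL,
                                 VLP_EXPOSURE_MS, config, seed=test_seed)
    out: dict = {"n_levels": len(VLP_LEVELS)}
    for name in ("PLS_P1_C1_VLP", "PLS_P1_C2_VLP", "PLS_P2_C1_VLP",
                 "PLS_P2_C2_VLP"):
        _, fit, _ = run_calibration(calib, name, seed=cv_seed, test_set=test)
        out[name] = {"rmse": fit.rmse, "r2": fit.r2}
    return out


def saturation_transfer_study(base_seed: int = 1, dv_max: float = 7.0,
                              dt: float = 0.1, reps: int = RECORDINGS_PER_LEVEL,
                              inject: dict | None = None) -> dict:
    """Transfer precipitant models to a continuous 1,250 ms process run.

    The 980 cm^-1 band oversaturates above ~0.2 M, so the linear and
    full-spectrum PLS models are flagged in the saturated window while the
    2-interval VIP model, restricted to non-saturating sulfate bands,
    recovers the rising-then-falling precipitant trace.
    """
    calib_seed, cv_seed, proc_seed = derive_seeds(base_seed + 13, 3)
    config = GeneratorConfig(seed=base_seed)
    calib = generate_stock_series("AMS", AMS_LEVELS, RECORDINGS_PER_LEVEL,
                                  CALIB_EXPOSURE_MS, config, seed=calib_seed)
    models = [run_calibration(calib, name, seed=cv_seed)[0]
              for name in ("LR_AMS", "PLS_AMS", "PLS_VIP2_AMS")]
    trace = simulate_cff_process(c0_ams=1.1, vlp_total=1.5, rho=0.55,
                                 dv_max=dv_max, dt=dt)
    process = generate_process_spectra(trace, "continuous", VLP_EXPOSURE_MS,
                                       config, inject=inject, seed=proc_seed,
                                       reps=reps)
    qc_params = {"clip_level": config.clip_level}
    if inject and inject.get("defective_window"):
        qc_params["defect_window"] = 61
    table, qc_report, _ = run_transfer(models, process, qc=qc_params)
    truth = pd.DataFrame({"dv": trace.dv_grid, "c_ams": trace.c_ams_stage2,
                          "c_vlp": trace.c_vlp_stage2})
    summary = report(table, truth)
    return {"table": table, "qc_report": qc_report, "summary": summary,
            "trace": trace, "models": models}


def noiseless_identity_study(n_levels: int = 12) -> float:
    """Exact end-to-end recovery on noiseless, drift-free data.

    Generates a noiseless precipitant series, runs the linear-regression
    pipeline without averaging (the recordings are identical) and returns
    the maximum absolute prediction error in mol/L; below detector
    saturation this is an exact-identity property of the pipeline.
    """
    config = GeneratorConfig(seed=0).noiseless()
    levels = np.linspace(0.0, 1.1, n_levels)
    calib = generate_stock_series("AMS", levels, 1, CALIB_EXPOSURE_MS, config,
                                  seed=0)
    lr_cfg = get_config("LR_AMS", average_n=None)
    _, fit, _ = run_calibration(calib, lr_cfg, seed=0)
    return float(np.max(np.abs(fit.predictions - calib.reference)))
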