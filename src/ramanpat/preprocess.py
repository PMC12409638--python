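"""Preprocessing operators and attribute-specific pipelines.

Each calibration model owns an ordered preprocessing recipe
(:class:`PipelineConfig`): block averaging, OH-band normalization (precipitant
pipelines only), pre-cropping of interferent bands (product pipelines only),
asPLS baseline subtraction, Savitzky-Golay smoothing, cropping to the model's
wavenumber interval(s), and optional scaling to unit variance.  The fixed step
order is

    average -> normalize -> precrop -> baseline -> smooth -> crop -> scale

Pre-cropped spectra are *spliced* (the gap is closed) before baseline
correction and smoothing by default, so the filters see one concatenated
vector; per-segment filtering is available via ``splice=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml
from scipy.signal import savgol_filter

from .baseline import aspls_baseline
from .spectra import (Spectrum, SpectrumSet, SpectraError, WavenumberAxis,
                      average_block)

__all__ = [
    "PipelineConfig", "ScalerState", "normalize_oh", "savgol_smooth",
    "precrop", "crop", "fit_scaler", "apply_scaler", "run_pipeline",
    "BUILTIN_CONFIGS", "get_config",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class PipelineConfig:
    """One preprocessing + model-building recipe.

    Baseline parameters follow the attribute-specific settings: the
    precipitant (AMS) pipelines use ``lambda=6e7``, second-order differences
    and tolerance 1e-3; the product (VLP) pipelines use ``lambda=1e9``,
    tolerance 1e-4 and second/third-order differences depending on the
    pre-crop interval.
    """

    name: str
    normalize_wavenumber: float | None = None
    precrop_exclude: tuple[Interval, ...] = ()
    baseline_lambda: float = 6e7
    baseline_diff_order: int = 2
    baseline_tol: float = 1e-3
    sg_window: int = 11
    sg_polyorder: int = 2
    crop_include: tuple[Interval, ...] = ()
    scale_unit_variance: bool = False
    average_n: int | None = 50
    splice: bool = True
    normalize_window: int = 5  # points around the reference wavenumber; 1 = strict

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")
        if self.baseline_diff_order not in (2, 3):
            raise ValueError("baseline_diff_order must be 2 or 3")
        if self.baseline_lambda <= 0 or self.baseline_tol <= 0:
            raise ValueError("baseline parameters must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["precrop_exclude"] = [list(iv) for iv in self.precrop_exclude]
        d["crop_include"] = [list(iv) for iv in self.crop_include]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["precrop_exclude"] = tuple(tuple(iv) for iv in d.get("precrop_exclude", ()))
        d["crop_include"] = tuple(tuple(iv) for iv in d.get("crop_include", ()))
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))


@dataclass
class ScalerState:
    """Per-wavenumber centering/scaling statistics learned on training data."""

    wavenumbers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            bad = np.asarray(self.wavenumbers)[self.sd <= 0]
            raise SpectraError(f"zero variance at wavenumbers {bad.tolist()}")


def normalize_oh(spectrum: Spectrum, wavenumber: float = 3299.0,
                 window: int = 5) -> Spectrum:
    """Divide by the (window-averaged) intensity at the OH reference band.

    Removes exposure-time and turbidity scaling: same-composition spectra
    recorded at different exposure times coincide after normalization, below
    detector saturation.  ``window=1`` uses the single reference channel.
    """
    axis = spectrum.axis
    i0 = axis.index_of(wavenumber)
    half = (window - 1) // 2
    lo, hi = max(0, i0 - half), min(len(axis), i0 + half + 1)
    ref = float(np.mean(spectrum.intensities[lo:hi]))
    if ref <= 0:
        raise SpectraError(
            f"reference intensity at {wavenumber} cm^-1 is {ref}: normalization undefined"
        )
    return spectrum.with_intensities(spectrum.intensities / ref)


def _check_segments(axis: WavenumberAxis, window: int) -> None:
    for sl, (a, b) in zip(axis.segment_slices(), axis.segments):
        if sl.stop - sl.start < window:
            raise SpectraError(
                f"segment [{a}, {b}] has {sl.stop - sl.start} points < window {window}"
            )


def savgol_smooth(spectrum: Spectrum, window: int = 11, polyorder: int = 2,
                  splice: bool = True) -> Spectrum:
    """Savitzky-Golay least-squares smoothing, length preserving.

    Edges are handled by refitting the edge-window polynomial (no
    wraparound).  With ``splice=True`` (the pipeline default) the whole
    possibly pre-cropped vector is filtered as one concatenated series;
    otherwise each contiguous axis segment is filtered separately.
    """
    if window % 2 == 0 or window <= polyorder:
        raise SpectraError("window must be odd and greater than polyorder")
    y = spectrum.intensities
    if splice:
        if y.size < window:
            raise SpectraError("spectrum shorter than the smoothing window")
        out = savgol_filter(y, window, polyorder, mode="interp")
    else:
        _check_segments(spectrum.axis, window)
        out = y.copy()
        for sl in spectrum.axis.segment_slices():
            out[sl] = savgol_filter(y[sl], window, polyorder, mode="interp")
    return spectrum.with_intensities(out)


def _mask_for_intervals(values: np.ndarray, intervals) -> np.ndarray:
    mask = np.zeros(values.size, dtype=bool)
    for a, b in intervals:
        mask |= (values >= a) & (values <= b)
    return mask


def _subset_axis(axis: WavenumberAxis, keep: np.ndarray) -> WavenumberAxis:
    """New axis from a boolean keep-mask, splitting segments at removed runs."""
    values = axis.values[keep]
    if values.size == 0:
        raise SpectraError("operation would remove the entire axis")
    segments: list[Interval] = []
    start = None
    kept_idx = np.flatnonzero(keep)
    prev = None
    for i in kept_idx:
        if prev is None or i != prev + 1:
            if start is not None:
                segments.append((float(axis.values[start]), float(axis.values[prev])))
            start = i
        prev = i
    segments.append((float(axis.values[start]), float(axis.values[prev])))
    return WavenumberAxis(values, tuple(segments))


def precrop(spectrum: Spectrum, exclude) -> Spectrum:
    """Remove interior wavenumber intervals (inclusive endpoints)."""
    exclude = [(float(a), float(b)) for a, b in exclude]
    if not exclude:
        return spectrum
    keep = ~_mask_for_intervals(spectrum.axis.values, exclude)
    axis = _subset_axis(spectrum.axis, keep)
    return spectrum.with_intensities(spectrum.intensities[keep], axis=axis)


def crop(spectrum: Spectrum, include) -> Spectrum:
    """Retain only wavenumbers inside the union of inclusive intervals.

    ``include`` may also be a single wavenumber (degenerate interval).
    """
    if np.isscalar(include):
        include = [(float(include), float(include))]
    include = [(float(a), float(b)) for a, b in include]
    keep = _mask_for_intervals(spectrum.axis.values, include)
    if not np.any(keep):
        raise SpectraError("crop intervals do not intersect the axis")
    axis = _subset_axis(spectrum.axis, keep)
    return spectrum.with_intensities(spectrum.intensities[keep], axis=axis)


def fit_scaler(trainset: SpectrumSet) -> ScalerState:
    if len(trainset) < 2:
        raise SpectraError("scaler needs at least 2 training spectra")
    X = trainset.intensity_matrix
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    return ScalerState(wavenumbers=trainset.axis.values.copy(), mean=mean, sd=sd)


def apply_scaler(spectrum: Spectrum, state: ScalerState) -> Spectrum:
    if not np.array_equal(spectrum.axis.values, state.wavenumbers):
        raise SpectraError("scaler state was fitted on a different axis")
    return spectrum.with_intensities((spectrum.intensities - state.mean) / state.sd)


def run_pipeline(spectrum_set: SpectrumSet, config: PipelineConfig,
                 baseline_fn=aspls_baseline,
                 scaler: ScalerState | None = None) -> SpectrumSet:
    """Apply the full preprocessing recipe to a set of raw spectra.

    Returns a new SpectrumSet whose ``provenance`` records the executed
    steps.  If the config requests unit-variance scaling and no ``scaler``
    is supplied, one is fitted on this set (training behavior) and attached
    to the result as ``scaler_state`` for reuse at transfer time.
    """
    out = spectrum_set

    def _step(name, fn):
        nonlocal out
        try:
            out = out.map(fn, step=name)
        except Exception as exc:
            raise SpectraError(f"pipeline step {name!r} failed: {exc}") from exc

    if config.average_n is not None and config.average_n > 1:
        out = average_block(out, config.average_n)
    if config.normalize_wavenumber is not None:
        wn, win = config.normalize_wavenumber, config.normalize_window
        _step(f"normalize_oh({wn})", lambda s: normalize_oh(s, wn, win))
    if config.precrop_exclude:
        _step(f"precrop({list(config.precrop_exclude)})",
              lambda s: precrop(s, config.precrop_exclude))

    def _subtract_baseline(s: Spectrum) -> Spectrum:
        y = s.intensities
        if config.splice:
            res = baseline_fn(y, config.baseline_lambda, config.baseline_diff_order,
                              config.baseline_tol)
            corrected = y - res.baseline
        else:
            corrected = y.copy()
            for sl in s.axis.segment_slices():
                res = baseline_fn(y[sl], config.baseline_lambda,
                                  config.baseline_diff_order, config.baseline_tol)
                corrected[sl] = y[sl] - res.baseline
        return s.with_intensities(corrected)

    _step(f"aspls_baseline(lam={config.baseline_lambda:g}, "
          f"d={config.baseline_diff_order}, tol={config.baseline_tol:g})",
          _subtract_baseline)
    _step(f"savgol_smooth(w={config.sg_window}, p={config.sg_polyorder})",
          lambda s: savgol_smooth(s, config.sg_window, config.sg_polyorder,
                                  splice=config.splice))
    if config.crop_include:
        _step(f"crop({list(config.crop_include)})",
              lambda s: crop(s, config.crop_include))
    fitted = scaler
    if config.scale_unit_variance:
        if fitted is None:
            fitted = fit_scaler(out)
        _step("scale_unit_variance", lambda s: apply_scaler(s, fitted))
    out.scaler_state = fitted  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Built-in pipeline recipes (one per calibration model)
# ---------------------------------------------------------------------------

_AMS = dict(normalize_wavenumber=3299.0, baseline_lambda=6e7,
            baseline_diff_order=2, baseline_tol=1e-3)
_VLP_P1 = dict(precrop_exclude=((920.0, 1030.0),), baseline_lambda=1e9,
               baseline_diff_order=2, baseline_tol=1e-4)
_VLP_P2 = dict(precrop_exclude=((920.0, 1200.0),), baseline_lambda=1e9,
               baseline_diff_order=3, baseline_tol=1e-4)

#: Derived VIP intervals reported for the precipitant calibration; the
#: 4-interval and 2-interval refined models use them as the default crop.
VIP_INTERVALS_AMS: tuple[Interval, ...] = (
    (427.0, 471.0), (600.0, 634.0), (960.0, 999.0), (1103.0, 1115.0))

BUILTIN_CONFIGS: dict[str, PipelineConfig] = {
    cfg.name: cfg for cfg in [
        PipelineConfig(name="LR_AMS", crop_include=((980.0, 980.0),), **_AMS),
        PipelineConfig(name="PLS_AMS", crop_include=((340.0, 2650.0),), **_AMS),
        PipelineConfig(name="PLS_VIP4_AMS", crop_include=VIP_INTERVALS_AMS,
                       scale_unit_variance=True, **_AMS),
        PipelineConfig(name="PLS_VIP2_AMS",
                       crop_include=((427.0, 471.0), (1103.0, 1115.0)),
                       scale_unit_variance=True, **_AMS),
        PipelineConfig(name="PLS_P1_C1_VLP", crop_include=((1203.0, 1349.0),), **_VLP_P1),
        PipelineConfig(name="PLS_P1_C2_VLP", crop_include=((1331.0, 1349.0),), **_VLP_P1),
        PipelineConfig(name="PLS_P2_C1_VLP", crop_include=((1203.0, 1349.0),), **_VLP_P2),
        PipelineConfig(name="PLS_P2_C2_VLP", crop_include=((1331.0, 1349.0),), **_VLP_P2),
    ]
}


def get_config(name: str, **overrides) -> PipelineConfig:
    """Fetch a built-in pipeline recipe, optionally overriding fields."""
    try:
        cfg = BUILTIN_CONFIGS[name]
    except KeyError:
        raise KeyError(f"unknown pipeline config {name!r}; "
                       f"available: {sorted(BUILTIN_CONFIGS)}") from None
    return replace(cfg, **overrides) if overrides else cfg
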