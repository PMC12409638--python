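"""Synthetic Raman spectra and dual-stage filtration process traces.

The generator emulates the statistical structure the analysis pipeline
assumes: ammonium-sulfate calibration series prepared along a wash /
re-dissolution buffer mixing gradient, VLP dilution series with a residual
sulfate background, and on-line process spectra from the second membrane
stage of a dual-stage cross-flow filtration — rise-then-fall precipitant
concentration, accumulating product, exposure-time intensity scaling,
concentration-dependent baseline drift, detector clipping with a fold-back
split-peak artifact, probe fouling, and injectable defective acquisitions.

Band positions follow standard Raman assignments (sulfate 451/618/980/1106,
ammonium 1420, phenylalanine 1004, tyrosine 1206, backbone/Tris 1249,
backbone+tryptophan 1341, amide I 1660, broad water OH around 3250 cm^-1);
widths and amplitudes are generator parameters.  The 980 cm^-1 sulfate
amplitude is set so the band reaches the detector full scale at 0.2 M at
1,250 ms exposure — the critical concentration for oversaturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .spectra import Spectrum, SpectrumSet, WavenumberAxis

__all__ = [
    "BandSpec", "GeneratorConfig", "ProcessTrace",
    "generate_spectrum", "generate_stock_series",
    "simulate_cff_process", "generate_process_spectra",
    "DEFAULT_BANDS",
]

AMS_RANGE = (0.0, 1.1)   # mol/L covered by the buffer mixing gradient
VLP_RANGE = (0.0, 2.2)   # g/L covered by the dilution series


@dataclass(frozen=True)
class BandSpec:
    center: float                 # cm^-1
    width: float                  # Gaussian sigma or Lorentzian gamma, cm^-1
    amplitude_per_unit: float     # counts per concentration unit per ms
    component: str
    shape: str = "gaussian"

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = wavenumbers - self.center
        if self.shape == "gaussian":
            return np.exp(-0.5 * (d / self.width) ** 2)
        if self.shape == "lorentzian":
            return 1.0 / (1.0 + (d / self.width) ** 2)
        raise ValueError(f"unknown band shape {self.shape!r}")


#: 980 cm^-1 amplitude such that 1250 ms x 0.2 M x amp = 65535 counts.
_SULFATE_980_AMP = 65535.0 / (1250.0 * 0.2)

DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(451.0, 6.0, 30.0, "sulfate"),
    BandSpec(618.0, 6.0, 25.0, "sulfate"),
    BandSpec(980.0, 5.0, _SULFATE_980_AMP, "sulfate"),
    BandSpec(1106.0, 12.0, 20.0, "sulfate"),
    BandSpec(1420.0, 10.0, 8.0, "ammonium"),
    BandSpec(1004.0, 4.0, 2.0, "phe"),
    BandSpec(1206.0, 6.0, 1.2, "tyr"),
    BandSpec(1249.0, 10.0, 1.5, "backbone"),
    BandSpec(1341.0, 9.0, 1.8, "trp_backbone"),
    BandSpec(1660.0, 15.0, 1.5, "amide1"),
    BandSpec(1249.0, 10.0, 1.2, "tris"),
    # composite water OH / probe background envelope; broad enough that the
    # attribute pipelines' Whittaker baseline can track it
    BandSpec(3250.0, 650.0, 30.0, "water_oh"),
)

_PROTEIN_COMPONENTS = ("phe", "tyr", "backbone", "trp_backbone", "amide1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Instrument + sample model parameters for the synthetic generator."""

    band_library: tuple[BandSpec, ...] = DEFAULT_BANDS
    baseline_offset_per_unit: float = 6.0    # counts/ms per M AMS (broad drift)
    baseline_offset_vlp: float = 2.0         # counts/ms per g/L VLP
    baseline_offset_mix: float = 2.0         # counts/ms at buffer_mix = 1
    baseline_jitter_sd: float = 0.10         # relative drift fluctuation per spectrum
    mixing_jitter_sd: float = 0.02           # buffer mixing imprecision per level
    noise_sigma_frac: float = 0.003          # of full scale, per recording
    clip_level: float = 65535.0              # 16-bit detector full scale
    saturation_fold_k: float = 0.15          # split-peak fold-back factor
    fold_floor_frac: float = 0.8             # folded values floored at this x clip
    fouling_rate: float = 0.15               # g/L-equivalent protein signal per DV
    residual_ams: float = 0.05               # mol/L in VLP stock solutions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_frac < 0:
            raise ValueError("noise_sigma_frac must be >= 0")
        if self.clip_level <= 0:
            raise ValueError("clip_level must be positive")
        if not 0 <= self.saturation_fold_k <= 1:
            raise ValueError("saturation_fold_k must lie in [0, 1]")

    def noiseless(self) -> "GeneratorConfig":
        """Deterministic variant: no noise, no drift, no jitter."""
        return replace(self, noise_sigma_frac=0.0, baseline_offset_per_unit=0.0,
                       baseline_offset_vlp=0.0, baseline_offset_mix=0.0,
                       baseline_jitter_sd=0.0, mixing_jitter_sd=0.0)


def _baseline_shape_broad(wn: np.ndarray) -> np.ndarray:
    # broad scattering hump, essentially zero near the OH reference band
    return np.exp(-0.5 * ((wn - 1000.0) / 800.0) ** 2)


def _baseline_shape_ramp(wn: np.ndarray) -> np.ndarray:
    return 1.2 - 0.9 * (wn - wn[0]) / max(wn[-1] - wn[0], 1.0)


def generate_spectrum(composition: dict[str, float], exposure_ms: float,
                      config: GeneratorConfig, rng: np.random.Generator,
                      axis: WavenumberAxis | None = None,
                      baseline_scale: float = 1.0, extra_offset: float = 0.0,
                      **spectrum_kwargs) -> Spectrum:
    """One raw recording: band signal + drift + noise + detector model.

    ``I(v) = t_exp * [sum_b c_comp A_b shape_b(v) + drift(v)] + noise``,
    then values above the clip level L are folded,
    ``I_obs = L - k (I_true - L)``, floored at ``fold_floor_frac * L``
    (yielding the split-peak artifact) and finally capped at L.
    """
    for comp, conc in composition.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {comp!r}")
    if axis is None:
        axis = WavenumberAxis.full()
    wn = axis.values
    signal = np.zeros(wn.size)
    for band in config.band_library:
        conc = composition.get(band.component, 0.0)
        if conc > 0:
            signal += conc * band.amplitude_per_unit * band.profile(wn)
    drift = np.zeros(wn.size)
    c_ams = composition.get("sulfate", 0.0)
    c_vlp = composition.get("trp_backbone", 0.0)
    mix = composition.get("buffer_mix", 0.0)
    if config.baseline_offset_per_unit and c_ams:
        drift += config.baseline_offset_per_unit * c_ams * _baseline_shape_broad(wn)
    if config.baseline_offset_vlp and c_vlp:
        drift += config.baseline_offset_vlp * c_vlp * _baseline_shape_broad(wn)
    if config.baseline_offset_mix and mix:
        drift += config.baseline_offset_mix * mix * _baseline_shape_ramp(wn)
    drift *= baseline_scale
    intensity = exposure_ms * (signal + drift)
    if extra_offset:
        intensity = intensity + extra_offset
    if config.noise_sigma_frac > 0:
        intensity = intensity + rng.normal(
            0.0, config.noise_sigma_frac * config.clip_level, wn.size)
    # detector model: fold-back above full scale, floor, hard cap
    L = config.clip_level
    over = intensity > L
    if np.any(over):
        folded = L - config.saturation_fold_k * (intensity[over] - L)
        intensity[over] = np.maximum(folded, config.fold_floor_frac * L)
        intensity = np.minimum(intensity, L)
    return Spectrum(axis, intensity, exposure_time_ms=exposure_ms,
                    **spectrum_kwargs)


def _composition_ams(c: float, mix: float) -> dict[str, float]:
    return {"sulfate": c, "ammonium": c, "tris": 1.0, "water_oh": 1.0,
            "buffer_mix": mix}


def _composition_vlp(c: float, residual_ams: float) -> dict[str, float]:
    comp = {comp_name: c for comp_name in _PROTEIN_COMPONENTS}
    comp.update({"sulfate": residual_ams, "ammonium": residual_ams,
                 "tris": 1.0, "water_oh": 1.0, "buffer_mix": 1.0})
    return comp


def generate_stock_series(analyte: str, levels, reps: int, exposure_ms: float,
                          config: GeneratorConfig, seed: int) -> SpectrumSet:
    """Off-line calibration series emulating stock-solution measurements.

    AMS series co-vary the buffer composition along the wash /
    re-dissolution mixing gradient (with per-level mixing imprecision); VLP
    series carry a fixed residual-AMS background.  ``reps`` recordings per
    level with fresh noise; the reference vector is attached.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    levels = [float(c) for c in levels]
    lo, hi = {"AMS": AMS_RANGE, "VLP": VLP_RANGE}[analyte]
    for c in levels:
        if not (lo <= c <= hi):
            raise ValueError(f"{analyte} level {c} outside [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    axis = WavenumberAxis.full()
    spectra: list[Spectrum] = []
    refs: list[float] = []
    for i, c in enumerate(levels):
        if analyte == "AMS":
            mix = c / AMS_RANGE[1]
            if config.mixing_jitter_sd > 0:
                mix = max(0.0, mix + rng.normal(0.0, config.mixing_jitter_sd))
            comp = _composition_ams(c, mix)
        else:
            comp = _composition_vlp(c, config.residual_ams)
        for r in range(reps):
            bscale = 1.0
            if config.baseline_jitter_sd > 0:
                bscale = max(0.0, 1.0 + rng.normal(0.0, config.baseline_jitter_sd))
            spectra.append(generate_spectrum(
                comp, exposure_ms, config, rng, axis=axis, baseline_scale=bscale,
                sample_id=f"{analyte}_L{i:02d}_r{r:03d}", acquisition_mode="offline"))
            refs.append(c)
    return SpectrumSet(spectra, reference=np.array(refs),
                       analyte=analyte)  # type: ignore[arg-type]


@dataclass
class ProcessTrace:
    """Stage-2 concentration time series over diafiltration volume."""

    dv_grid: np.ndarray
    c_ams_stage2: np.ndarray
    c_vlp_stage2: np.ndarray
    phase: np.ndarray          # "DF" or "UF" per grid point
    volume: np.ndarray         # mL per grid point

    def __post_init__(self) -> None:
        if np.any(self.c_ams_stage2 < 0) or np.any(self.c_vlp_stage2 < 0):
            raise ValueError("concentrations must be >= 0")
        in_df = self.phase == "DF"
        if np.any(np.diff(self.volume[in_df]) < -1e-12):
            raise ValueError("volume may only decrease during the UF phase")


def simulate_cff_process(c0_ams: float, vlp_total: float, rho: float,
                         dv_max: float, uf_factor: float = 2.5,
                         dt: float = 0.1, uf_span: float = 1.0,
                         volume_ml: float = 25.0,
                         redissolution_threshold: float = 0.4,
                         redissolution_width: float = 0.08) -> ProcessTrace:
    """Two-stage diafiltration washout followed by ultrafiltration.

    Stage 1 is ideal constant-volume washout, ``C1(v) = c0 exp(-v)``; the
    stage-2 precipitant balance ``dC2/dv = rho (C1 - C2)`` is integrated
    numerically on the dv grid (rho is the stage-2/stage-1 exchange-rate
    ratio).  Product release follows a logistic switch as C1 falls below the
    re-dissolution threshold; released product is fully retained in stage 2.
    During UF the retentate volume shrinks by ``uf_factor``, concentrating
    the product, while the freely membrane-permeant precipitant stays at its
    end-of-DF concentration.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    if dv_max < 1:
        raise ValueError("dv_max must be >= 1")
    dv_df = np.arange(0.0, dv_max + dt / 2, dt)
    c1 = c0_ams * np.exp(-dv_df)
    if c0_ams == 0:
        c2 = np.zeros_like(dv_df)
    else:
        sol = solve_ivp(lambda v, c: rho * (c0_ams * np.exp(-v) - c),
                        (0.0, dv_df[-1]), [0.0], t_eval=dv_df,
                        rtol=1e-10, atol=1e-12 * max(c0_ams, 1.0))
        c2 = np.clip(sol.y[0], 0.0, None)
    release = 1.0 / (1.0 + np.exp((c1 - redissolution_threshold) / redissolution_width))
    c_vlp = vlp_total * release
    n_uf = max(2, int(round(uf_span / dt)))
    dv_uf = dv_df[-1] + dt * np.arange(1, n_uf + 1)
    vol_uf = np.linspace(volume_ml, volume_ml / uf_factor, n_uf + 1)[1:]
    c_vlp_uf = c_vlp[-1] * volume_ml / vol_uf
    c2_uf = np.full(n_uf, c2[-1])
    return ProcessTrace(
        dv_grid=np.concatenate([dv_df, dv_uf]),
        c_ams_stage2=np.concatenate([c2, c2_uf]),
        c_vlp_stage2=np.concatenate([c_vlp, c_vlp_uf]),
        phase=np.array(["DF"] * dv_df.size + ["UF"] * n_uf),
        volume=np.concatenate([np.full(dv_df.size, volume_ml), vol_uf]),
    )


def _semi_continuous_windows(trace: ProcessTrace, half_width: float = 0.15
                             ) -> np.ndarray:
    """Mask of grid points inside sampling windows (0.5 DV, each DV, UF end)."""
    dv_df_max = trace.dv_grid[trace.phase == "DF"].max()
    points = [0.5] + [float(k) for k in range(1, int(np.floor(dv_df_max)) + 1)]
    mask = np.zeros(trace.dv_grid.size, dtype=bool)
    for p in points:
        mask |= np.abs(trace.dv_grid - p) <= half_width
    uf = np.flatnonzero(trace.phase == "UF")
    if uf.size:
        mask[uf[-2:]] = True
    return mask


def generate_process_spectra(trace: ProcessTrace, mode: str, exposure_ms: float,
                             config: GeneratorConfig, inject: dict | None = None,
                             seed: int = 0, reps: int = 50) -> SpectrumSet:
    """On-line spectra along a process trace, one block of ``reps`` per step.

    ``continuous`` mode covers the whole trace; ``semi_continuous`` records
    only inside windows around the sampling points.  ``inject`` may enable
    probe fouling (protein signal growing linearly with DV) and/or a
    ``defective_window`` dv interval whose spectra receive gross baseline
    offsets.
    """
    inject = inject or {}
    fouling = bool(inject.get("fouling", False))
    defective_window = inject.get("defective_window")
    if defective_window is not None:
        lo, hi = defective_window
        if hi < trace.dv_grid[0] or lo > trace.dv_grid[-1]:
            raise ValueError("defective_window lies outside the process trace")
    if mode == "continuous":
        mask = np.ones(trace.dv_grid.size, dtype=bool)
    elif mode == "semi_continuous":
        mask = _semi_continuous_windows(trace)
    else:
        raise ValueError(f"unknown acquisition mode {mode!r}")
    rng = np.random.default_rng(seed)
    axis = WavenumberAxis.full()
    spectra: list[Spectrum] = []
    for i in np.flatnonzero(mask):
        dv = float(trace.dv_grid[i])
        c_ams = float(trace.c_ams_stage2[i])
        c_vlp = float(trace.c_vlp_stage2[i])
        comp = {comp_name: c_vlp for comp_name in _PROTEIN_COMPONENTS}
        if fouling:
            extra = config.fouling_rate * dv
            comp = {k: v + extra for k, v in comp.items()}
        comp.update({"sulfate": c_ams, "ammonium": c_ams, "tris": 1.0,
                     "water_oh": 1.0, "buffer_mix": min(1.0, c_ams / AMS_RANGE[1])})
        defective = (defective_window is not None
                     and defective_window[0] <= dv <= defective_window[1])
        for r in range(reps):
            bscale = 1.0
            if config.baseline_jitter_sd > 0:
                bscale = max(0.0, 1.0 + rng.normal(0.0, config.baseline_jitter_sd))
            extra_offset = 0.0
            if defective:
                extra_offset = 0.25 * config.clip_level * rng.uniform(0.8, 1.2)
            spectra.append(generate_spectrum(
                comp, exposure_ms, config, rng, axis=axis,
                baseline_scale=bscale, extra_offset=extra_offset,
                dv=dv, sample_id=f"dv{dv:05.2f}_r{r:03d}",
                acquisition_mode=mode))  # type: ignore[arg-type]
    return SpectrumSet(spectra)
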