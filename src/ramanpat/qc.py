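"""Quality control: detector oversaturation and defective-spectrum flags.

At high exposure times the predominant 980 cm^-1 sulfate band can exceed
the detector's full scale.  A clipped band appears either as a plateau at
the clip level or as a *split peak* — two flank maxima with an interior
minimum — and quantification from the affected region is unreliable, so
transfer predictions from such spectra are flagged rather than dropped.
Defective spectra (gross baseline shifts unrelated to composition, as seen
in fouled on-line loops) are flagged by a robust rolling-statistics outlier
test on the total intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet, SpectraError

__all__ = ["QCReport", "detect_saturation", "detect_defective"]

DEFAULT_CLIP_LEVEL = 65535.0  # 16-bit full scale
DEFAULT_SULFATE_BAND = (940.0, 1020.0)


@dataclass
class QCReport:
    """Per-spectrum QC flags and scores."""

    flags: list[str] = field(default_factory=list)            # ok | saturated | defective
    saturated_intervals: list[tuple[float, float] | None] = field(default_factory=list)
    defect_scores: np.ndarray | None = None

    def to_frame(self, spectrum_set: SpectrumSet | None = None) -> pd.DataFrame:
        n = len(self.flags)
        frame = pd.DataFrame({
            "flag": self.flags,
            "defect_score": (self.defect_scores
                             if self.defect_scores is not None else [np.nan] * n),
            "saturated_interval": [
                f"{iv[0]:g}-{iv[1]:g}" if iv else "" for iv in
                (self.saturated_intervals or [None] * n)
            ],
        })
        if spectrum_set is not None:
            frame.insert(0, "spectrum_id", [s.sample_id for s in spectrum_set])
            frame.insert(1, "dv", [s.dv for s in spectrum_set])
        return frame


def detect_saturation(spectrum: Spectrum, clip_level: float = DEFAULT_CLIP_LEVEL,
                      band: tuple[float, float] = DEFAULT_SULFATE_BAND,
                      plateau_points: int = 3, plateau_frac: float = 0.005,
                      split_depth_frac: float = 0.05
                      ) -> tuple[str, tuple[float, float] | None]:
    """Flag a raw spectrum whose band region is clipped or split.

    Saturated if (a) >= ``plateau_points`` consecutive in-band points lie
    within ``plateau_frac`` of the clip level, or (b) the band shows two
    local maxima with an interior minimum deeper than ``split_depth_frac``
    of the band amplitude.  Spectra whose band maximum stays below
    0.9 * clip_level are never flagged.  Returns ``(flag, interval)``.
    """
    wn = spectrum.axis.values
    mask = (wn >= band[0]) & (wn <= band[1])
    if not np.any(mask):
        raise SpectraError(f"band {band} outside the spectrum axis")
    y = spectrum.intensities[mask]
    x = wn[mask]
    if y.max() < 0.9 * clip_level:
        return "ok", None
    near = y >= clip_level * (1.0 - plateau_frac)
    run = 0
    for flag_val in near:
        run = run + 1 if flag_val else 0
        if run >= plateau_points:
            lo, hi = x[near].min(), x[near].max()
            return "saturated", (float(lo), float(hi))
    # split-peak signature: interior minimum between two local maxima
    interior = np.arange(1, y.size - 1)
    maxima = interior[(y[interior] >= y[interior - 1]) & (y[interior] > y[interior + 1])]
    if maxima.size >= 2:
        amplitude = float(np.ptp(y))
        for i, j in zip(maxima[:-1], maxima[1:]):
            valley = y[i:j + 1].min()
            depth = min(y[i], y[j]) - valley
            if amplitude > 0 and depth / amplitude > split_depth_frac:
                return "saturated", (float(x[i]), float(x[j]))
    return "ok", None


def detect_defective(spectrum_set: SpectrumSet, window: int = 7,
                     k: float = 6.0, mad_floor_frac: float = 0.005) -> QCReport:
    """Flag spectra whose total intensity is a rolling robust outlier.

    Each spectrum's median-normalized total intensity is compared against
    the rolling median of its ``window`` neighbors; the defect score is the
    absolute deviation in units of the rolling MAD.  Scores above ``k``
    flag the spectrum as defective.  The MAD is floored at
    ``mad_floor_frac`` of the local intensity level so that smooth process
    dynamics in low-noise series are not mistaken for defects; a genuinely
    defective acquisition shifts the total intensity by tens of percent and
    clears the floor easily.  Invariant to a global rescaling of the set.
    """
    n = len(spectrum_set)
    if n < 5:
        raise SpectraError("need at least 5 time-ordered spectra")
    if n < window:
        raise SpectraError(f"fewer spectra ({n}) than window ({window})")
    totals = np.array([float(np.sum(s.intensities)) for s in spectrum_set])
    med = float(np.median(totals))
    norm = totals / med if med != 0 else totals
    series = pd.Series(norm)
    roll_med = series.rolling(window, center=True, min_periods=1).median().to_numpy()
    dev = np.abs(norm - roll_med)
    roll_mad = (pd.Series(dev).rolling(window, center=True, min_periods=1)
                .median().to_numpy())
    global_mad = float(np.median(dev))
    level_floor = mad_floor_frac * np.abs(roll_med)
    floor = np.maximum(np.maximum(roll_mad, global_mad), level_floor)
    scores = dev / np.maximum(floor, 1e-12)
    flags = ["defective" if s > k else "ok" for s in scores]
    return QCReport(flags=flags, saturated_intervals=[None] * n,
                    defect_scores=scores)
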