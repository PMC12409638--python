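"""Core spectrum containers and plain-text I/O.

A :class:`Spectrum` is an intensity vector on a shared
:class:`WavenumberAxis`; a :class:`SpectrumSet` is an ordered collection of
spectra on one identical axis, optionally carrying per-spectrum reference
concentrations for calibration.  The axis keeps track of contiguous
*segments* so that interior wavenumber intervals removed by pre-cropping
remain visible to downstream operators.

On-disk formats are deliberately plain text: a wide CSV (wavenumber column
followed by one column per spectrum) with a companion ``.meta.csv`` for
acquisition metadata, and optionally single-spectrum JCAMP-DX files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "SpectrumSet",
    "read_spectrum_table",
    "write_spectrum_table",
    "average_block",
]

AcquisitionMode = Literal["offline", "semi_continuous", "continuous"]

#: Instrument grid: 200–3300 cm^-1 at 1 cm^-1 resolution.
FULL_RANGE = (200.0, 3300.0)


class SpectraError(ValueError):
    """Raised on invalid spectral data or malformed on-disk tables."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid with contiguity bookkeeping.

    ``segments`` lists the inclusive intervals (cm^-1) whose union is exactly
    the set of axis values; pre-cropping introduces additional segments.
    """

    values: np.ndarray
    segments: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise SpectraError("axis must be a non-empty 1-D array")
        if not np.all(np.diff(values) > 0):
            raise SpectraError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "values", values)
        if self.segments is None:
            object.__setattr__(
                self, "segments", ((float(values[0]), float(values[-1])),)
            )
        else:
            segs = tuple((float(a), float(b)) for a, b in self.segments)
            for (a, b) in segs:
                if a > b:
                    raise SpectraError(f"segment [{a}, {b}] reversed")
            for (_, b0), (a1, _) in zip(segs, segs[1:]):
                if b0 >= a1:
                    raise SpectraError("segments must be sorted and disjoint")
            n_in = sum(
                int(np.count_nonzero((values >= a) & (values <= b))) for a, b in segs
            )
            if n_in != values.size:
                raise SpectraError("segments do not cover the axis values exactly")
            object.__setattr__(self, "segments", segs)

    @classmethod
    def full(cls, lo: float = FULL_RANGE[0], hi: float = FULL_RANGE[1],
             step: float = 1.0) -> "WavenumberAxis":
        """The default instrument axis (200–3300 cm^-1, 1 cm^-1 spacing)."""
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
            and self.segments == other.segments
        )

    def index_of(self, wavenumber: float) -> int:
        idx = np.flatnonzero(np.isclose(self.values, wavenumber, rtol=0, atol=1e-9))
        if idx.size == 0:
            raise SpectraError(f"wavenumber {wavenumber} cm^-1 not on axis")
        return int(idx[0])

    def segment_slices(self) -> list[slice]:
        """Index slices of the value array, one per contiguous segment."""
        out: list[slice] = []
        start = 0
        for a, b in self.segments:
            n = int(np.count_nonzero((self.values >= a) & (self.values <= b)))
            out.append(slice(start, start + n))
            start += n
        return out


@dataclass
class Spectrum:
    """One Raman acquisition: intensities on an axis plus metadata."""

    axis: WavenumberAxis
    intensities: np.ndarray
    exposure_time_ms: float = 175.0
    dv: float | None = None
    sample_id: str = ""
    acquisition_mode: AcquisitionMode = "offline"
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.axis),):
            raise SpectraError(
                f"intensities length {self.intensities.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraError("intensities must be finite")
        if not self.exposure_time_ms > 0:
            raise SpectraError("exposure_time_ms must be positive")

    def with_intensities(self, values: np.ndarray,
                         axis: WavenumberAxis | None = None) -> "Spectrum":
        return replace(self, intensities=np.asarray(values, dtype=float),
                       axis=axis if axis is not None else self.axis,
                       flags=set(self.flags))

    def intensity_at(self, wavenumber: float) -> float:
        return float(self.intensities[self.axis.index_of(wavenumber)])


@dataclass
class SpectrumSet:
    """Ordered spectra on one shared axis, optionally with references."""

    spectra: list[Spectrum]
    reference: np.ndarray | None = None
    analyte: Literal["AMS", "VLP", "none"] = "none"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra:
            axis0 = self.spectra[0].axis
            for i, s in enumerate(self.spectra):
                if s.axis != axis0:
                    raise SpectraError(f"spectrum {i} axis differs from the set axis")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != (len(self.spectra),):
                raise SpectraError("reference must have one value per spectrum")
            if np.any(self.reference < 0):
                raise SpectraError("reference concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def axis(self) -> WavenumberAxis:
        if not self.spectra:
            raise SpectraError("empty spectrum set has no axis")
        return self.spectra[0].axis

    @property
    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_wavenumbers) matrix of intensities."""
        return np.vstack([s.intensities for s in self.spectra])

    def map(self, fn, step: str | None = None) -> "SpectrumSet":
        """Apply a Spectrum -> Spectrum operator to every member."""
        out = SpectrumSet(
            [fn(s) for s in self.spectra],
            reference=None if self.reference is None else self.reference.copy(),
            analyte=self.analyte,
            provenance=list(self.provenance),
        )
        if step:
            out.provenance.append(step)
        return out


def average_block(spectrum_set: SpectrumSet, n: int) -> SpectrumSet:
    """Average consecutive non-overlapping blocks of ``n`` spectra.

    Metadata is taken from each block's first spectrum; ``dv`` and the
    reference value become the block mean.  A trailing partial block is
    dropped so every output spectrum carries the same noise level.
    """
    if n <= 0:
        raise SpectraError("block size must be positive")
    if len(spectrum_set) == 0:
        raise SpectraError("cannot average an empty set")
    n_blocks = len(spectrum_set) // n
    if n_blocks == 0:
        raise SpectraError(f"fewer than {n} spectra, nothing to average")
    out_spectra: list[Spectrum] = []
    out_ref: list[float] = []
    for b in range(n_blocks):
        block = spectrum_set.spectra[b * n:(b + 1) * n]
        first = block[0]
        mean_int = np.mean([s.intensities for s in block], axis=0)
        dvs = [s.dv for s in block if s.dv is not None]
        avg = replace(
            first,
            intensities=mean_int,
            dv=float(np.mean(dvs)) if dvs else None,
            flags=set().union(*(s.flags for s in block)),
        )
        out_spectra.append(avg)
        if spectrum_set.reference is not None:
            out_ref.append(float(np.mean(spectrum_set.reference[b * n:(b + 1) * n])))
    return SpectrumSet(
        out_spectra,
        reference=np.array(out_ref) if spectrum_set.reference is not None else None,
        analyte=spectrum_set.analyte,
        provenance=list(spectrum_set.provenance) + [f"average_block(n={n})"],
    )


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

_WAVENUMBER_COL = "wavenumber_cm-1"
_META_COLS = ["spectrum_id", "exposure_time_ms", "dv", "sample_id",
              "acquisition_mode", "reference_value", "reference_unit"]
_UNIT_BY_ANALYTE = {"AMS": "mol/L", "VLP": "g/L", "none": ""}


def _meta_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.csv") if path.suffix else path


def write_spectrum_table(spectrum_set: SpectrumSet, path: str | Path,
                         dialect: str = "csv_wide") -> Path:
    """Write a SpectrumSet; round-trips losslessly via :func:`read_spectrum_table`."""
    if len(spectrum_set) == 0:
        raise SpectraError("refusing to write an empty spectrum set")
    path = Path(path)
    if dialect == "csv_wide":
        axis = spectrum_set.axis
        cols = {_WAVENUMBER_COL: axis.values}
        ids = []
        for i, s in enumerate(spectrum_set):
            sid = s.sample_id or f"spectrum_{i}"
            if sid in cols:
                sid = f"{sid}_{i}"
            ids.append(sid)
            cols[sid] = s.intensities
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.14g")
        meta = pd.DataFrame({
            "spectrum_id": ids,
            "exposure_time_ms": [s.exposure_time_ms for s in spectrum_set],
            "dv": [s.dv for s in spectrum_set],
            "sample_id": [s.sample_id for s in spectrum_set],
            "acquisition_mode": [s.acquisition_mode for s in spectrum_set],
            "reference_value": (
                spectrum_set.reference
                if spectrum_set.reference is not None
                else [None] * len(spectrum_set)
            ),
            "reference_unit": [_UNIT_BY_ANALYTE[spectrum_set.analyte]] * len(spectrum_set),
        })
        meta.to_csv(path.parent / (path.stem + ".meta.csv"), index=False,
                    float_format="%.14g")
        return path
    if dialect == "jcamp_dx":
        if len(spectrum_set) != 1:
            raise SpectraError("jcamp_dx dialect writes one spectrum per file")
        _write_jcamp(spectrum_set.spectra[0], path)
        return path
    raise SpectraError(f"unknown dialect {dialect!r}")


def read_spectrum_table(path: str | Path, dialect: str = "csv_wide") -> SpectrumSet:
    """Read a spectral table written by :func:`write_spectrum_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv_wide":
        table = pd.read_csv(path)
        if table.shape[1] < 2:
            raise SpectraError(f"{path}: need a wavenumber column plus >=1 spectrum column")
        if table.columns[0] != _WAVENUMBER_COL:
            raise SpectraError(
                f"{path}: first column must be {_WAVENUMBER_COL!r}, got {table.columns[0]!r}"
            )
        wn = table.iloc[:, 0].to_numpy(dtype=float)
        if np.any(np.diff(wn) <= 0):
            bad = int(np.flatnonzero(np.diff(wn) <= 0)[0]) + 2  # 1-based data row
            raise SpectraError(f"{path}: non-monotone wavenumber axis at row {bad}")
        axis = WavenumberAxis(wn)
        meta_file = path.parent / (path.stem + ".meta.csv")
        meta = pd.read_csv(meta_file).set_index("spectrum_id") if meta_file.exists() else None
        spectra = []
        refs: list[float] = []
        has_ref = False
        unit = ""
        for col in table.columns[1:]:
            y = table[col].to_numpy(dtype=float)
            kwargs: dict = {"sample_id": str(col)}
            if meta is not None and col in meta.index:
                row = meta.loc[col]
                kwargs = {
                    "exposure_time_ms": float(row["exposure_time_ms"]),
                    "dv": None if pd.isna(row["dv"]) else float(row["dv"]),
                    "sample_id": str(row["sample_id"]) if not pd.isna(row["sample_id"]) else str(col),
                    "acquisition_mode": str(row["acquisition_mode"]),
                }
                if not pd.isna(row.get("reference_value")):
                    has_ref = True
                    refs.append(float(row["reference_value"]))
                    unit = str(row.get("reference_unit", ""))
                else:
                    refs.append(np.nan)
            spectra.append(Spectrum(axis, y, **kwargs))
        analyte = {"mol/L": "AMS", "g/L": "VLP"}.get(unit, "none")
        return SpectrumSet(
            spectra,
            reference=np.array(refs) if has_ref and not np.any(np.isnan(refs)) else None,
            analyte=analyte,  # type: ignore[arg-type]
        )
    if dialect == "jcamp_dx":
        return SpectrumSet([_read_jcamp(path)])
    raise SpectraError(f"unknown dialect {dialect!r}")


# -- minimal JCAMP-DX (XYDATA=(X++(Y..Y)), AFFN) ----------------------------

def _write_jcamp(spectrum: Spectrum, path: Path) -> None:
    wn = spectrum.axis.values
    dx = np.diff(wn)
    if not np.allclose(dx, dx[0]):
        raise SpectraError("jcamp_dx requires an equally spaced axis")
    lines = [
        "##TITLE=" + (spectrum.sample_id or "spectrum"),
        "##JCAMP-DX=4.24",
        "##DATA TYPE=RAMAN SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ARBITRARY UNITS",
        f"##$EXPOSURETIMEMS={spectrum.exposure_time_ms:.14g}",
        f"##FIRSTX={wn[0]:.14g}",
        f"##LASTX={wn[-1]:.14g}",
        f"##DELTAX={dx[0]:.14g}",
        f"##NPOINTS={wn.size}",
        "##XFACTOR=1",
        "##YFACTOR=1",
        "##XYDATA=(X++(Y..Y))",
    ]
    for i in range(0, wn.size, 6):
        ys = " ".join(f"{y:.14g}" for y in spectrum.intensities[i:i + 6])
        lines.append(f"{wn[i]:.14g} {ys}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def _read_jcamp(path: Path) -> Spectrum:
    header: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = val.strip()
            continue
        if in_data:
            parts = re.split(r"[\s,]+", line)
            ys.extend(float(v) for v in parts[1:])  # first token is X
    try:
        first_x = float(header["FIRSTX"])
        delta = float(header["DELTAX"])
        npoints = int(header["NPOINTS"])
    except KeyError as exc:
        raise SpectraError(f"{path}: missing JCAMP header {exc}") from exc
    if len(ys) != npoints:
        raise SpectraError(f"{path}: NPOINTS={npoints} but parsed {len(ys)} y values")
    yfactor = float(header.get("YFACTOR", "1"))
    axis = WavenumberAxis(first_x + delta * np.arange(npoints))
    return Spectrum(
        axis,
        yfactor * np.asarray(ys),
        exposure_time_ms=float(header.get("$EXPOSURETIMEMS", "175")),
        sample_id=header.get("TITLE", ""),
    )
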