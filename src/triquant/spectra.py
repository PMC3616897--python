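"""Core spectral containers, grid arithmetic and CSV persistence.

Absorbance spectra live on a strictly increasing, uniform wavelength grid
(nanometres) with absorbance in AU for a 1 cm path.  Everything downstream
— the ratio-subtraction resolver, the univariate calibrations and the ANN
calibration — consumes these containers.

Two CSV layouts are supported: a single-spectrum file with columns
``wavelength_nm,absorbance`` (a headerless variant is available via the
``dialect`` argument) and a matrix file whose first column is the
wavelength and whose remaining columns are one sample each, sample
identifiers in the header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralWindow",
    "GridError",
    "SpectrumParseError",
    "ANN_WINDOW",
    "PLATEAU_WINDOW",
    "default_grid",
    "read_spectrum",
    "write_spectrum",
    "read_spectra_matrix",
    "write_spectra_matrix",
    "restrict",
    "value_at",
]

#: Uniformity tolerance on the wavelength step, in nm.
GRID_TOL_NM = 1e-9


class GridError(ValueError):
    """The wavelength axis is not a strictly increasing uniform grid."""


class SpectrumParseError(ValueError):
    """A CSV cell could not be interpreted as a number."""


@dataclass(frozen=True)
class SpectralWindow:
    """A wavelength interval ``[start_nm, end_nm]`` (or ``[start, end)``).

    ``closed=False`` selects the half-open convention used for the ANN
    input region, where [230, 340) on a 1 nm grid yields 110 points.
    """

    start_nm: float
    end_nm: float
    closed: bool = True

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ValueError(
                f"window start {self.start_nm} must be below end {self.end_nm}"
            )

    def contains(self, wavelength_nm: float) -> bool:
        if self.closed:
            return self.start_nm <= wavelength_nm <= self.end_nm
        return self.start_nm <= wavelength_nm < self.end_nm


#: ANN input region: half-open [230, 340) nm -> 110 points on a 1 nm grid.
ANN_WINDOW = SpectralWindow(230.0, 340.0, closed=False)
#: Plateau where only AML absorbs, used for the ratio-spectrum constant.
PLATEAU_WINDOW = SpectralWindow(350.0, 400.0)


def default_grid(start_nm: float = 200.0, end_nm: float = 400.0,
                 step_nm: float = 1.0) -> np.ndarray:
    """Default acquisition grid: 200-400 nm at 1 nm (201 points)."""
    n = int(round((end_nm - start_nm) / step_nm)) + 1
    return start_nm + step_nm * np.arange(n)


@dataclass
class Spectrum:
    """A sampled absorbance curve on a uniform wavelength grid.

    Parameters
    ----------
    wavelengths_nm :
        Strictly increasing uniform grid (nm), at least two points.
    absorbance_au :
        Absorbance values (AU, 1 cm path), same length as the grid.
    label :
        Free-text analyte or mixture identifier.
    concentrations_ug_per_ml :
        Optional per-analyte concentration map in ug/mL.
    """

    wavelengths_nm: np.ndarray
    absorbance_au: np.ndarray
    label: str = ""
    concentrations_ug_per_ml: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance_au = np.asarray(self.absorbance_au, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.absorbance_au.ndim != 1:
            raise ValueError("wavelengths and absorbance must be 1-D")
        if self.wavelengths_nm.size != self.absorbance_au.size:
            raise ValueError("wavelengths and absorbance lengths differ")
        if self.wavelengths_nm.size < 2:
            raise ValueError("a spectrum needs at least two points")
        steps = np.diff(self.wavelengths_nm)
        if np.any(steps <= 0):
            raise GridError("wavelength grid must be strictly increasing")
        if np.ptp(steps) > GRID_TOL_NM:
            raise GridError(
                f"wavelength grid step varies by {np.ptp(steps):.3g} nm "
                f"(tolerance {GRID_TOL_NM} nm)"
            )
        if not np.all(np.isfinite(self.absorbance_au)):
            raise ValueError("absorbance values must be finite")

    # -- geometry ---------------------------------------------------------
    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    @property
    def n_points(self) -> int:
        return int(self.wavelengths_nm.size)

    def value_at(self, wavelength_nm: float) -> float:
        """Absorbance at ``wavelength_nm``; linear interpolation off-grid."""
        return value_at(self, wavelength_nm)

    def restrict(self, window: SpectralWindow) -> "Spectrum":
        return restrict(self, window)

    def with_absorbance(self, absorbance_au: np.ndarray,
                        label: str | None = None) -> "Spectrum":
        """Copy of this spectrum with new absorbance values (same grid)."""
        return replace(
            self,
            absorbance_au=np.asarray(absorbance_au, dtype=float),
            label=self.label if label is None else label,
        )


def value_at(spectrum: Spectrum, wavelength_nm: float) -> float:
    """Absorbance at a wavelength: exact sample on-grid, linear
    interpolation between neighbours otherwise.

    Raises
    ------
    ValueError
        If the wavelength lies outside the spectrum's grid range.
    """
    lo = spectrum.wavelengths_nm[0]
    hi = spectrum.wavelengths_nm[-1]
    if not lo <= wavelength_nm <= hi:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside grid [{lo}, {hi}] nm"
        )
    return float(np.interp(wavelength_nm, spectrum.wavelengths_nm,
                           spectrum.absorbance_au))


def restrict(spectrum: Spectrum, window: SpectralWindow) -> Spectrum:
    """Sub-spectrum on the window, preserving the grid step.

    The window's ``closed`` flag picks the inclusion convention for the
    upper edge; the lower edge is always included when on-grid.
    """
    w = spectrum.wavelengths_nm
    if window.start_nm < w[0] - GRID_TOL_NM or window.end_nm > w[-1] + GRID_TOL_NM:
        raise ValueError(
            f"window [{window.start_nm}, {window.end_nm}] outside the "
            f"spectrum grid [{w[0]}, {w[-1]}]"
        )
    if window.closed:
        mask = (w >= window.start_nm - GRID_TOL_NM) & (w <= window.end_nm + GRID_TOL_NM)
    else:
        mask = (w >= window.start_nm - GRID_TOL_NM) & (w < window.end_nm - GRID_TOL_NM)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than two grid points")
    return replace(
        spectrum,
        wavelengths_nm=w[mask],
        absorbance_au=spectrum.absorbance_au[mask],
    )


# -- CSV persistence ------------------------------------------------------

_DIALECTS = ("headered", "headerless")


def read_spectrum(path: str | Path, dialect: str = "headered",
                  label: str | None = None) -> Spectrum:
    """Read a two-column spectrum CSV.

    ``dialect='headered'`` (default) expects a header row naming the two
    columns; ``'headerless'`` reads bare numeric rows.  Rows are sorted by
    wavelength before validation, so file row order is immaterial, but a
    duplicated wavelength is a grid error.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {_DIALECTS}")
    path = Path(path)
    header = 0 if dialect == "headered" else None
    raw = pd.read_csv(path, header=header, dtype=str, comment="#")
    if raw.shape[1] < 2:
        raise SpectrumParseError(f"{path}: expected two columns, got {raw.shape[1]}")
    cols = []
    for j in range(2):
        col = pd.to_numeric(raw.iloc[:, j], errors="coerce")
        bad = np.nonzero(col.isna().to_numpy())[0]
        if bad.size:
            raise SpectrumParseError(
                f"{path}: non-numeric cell in column {j} at data row {bad[0]}"
            )
        cols.append(col.to_numpy(dtype=float))
    wl, ab = cols
    order = np.argsort(wl)
    wl, ab = wl[order], ab[order]
    if np.any(np.diff(wl) == 0):
        raise GridError(f"{path}: duplicated wavelength row")
    return Spectrum(wl, ab, label=label if label is not None else path.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path,
                   dialect: str = "headered") -> None:
    """Write a spectrum as a two-column CSV (full float precision)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {_DIALECTS}")
    df = pd.DataFrame({
        "wavelength_nm": spectrum.wavelengths_nm,
        "absorbance": spectrum.absorbance_au,
    })
    df.to_csv(path, index=False, header=(dialect == "headered"),
              float_format="%.17g")


def read_spectra_matrix(path: str | Path) -> list[Spectrum]:
    """Read a multi-spectrum matrix CSV (wavelength column + one column
    per sample, sample identifiers in the header)."""
    df = pd.read_csv(path)
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    order = np.argsort(wl)
    wl = wl[order]
    if np.any(np.diff(wl) == 0):
        raise GridError(f"{path}: duplicated wavelength row")
    return [
        Spectrum(wl, df[c].to_numpy(dtype=float)[order], label=str(c))
        for c in df.columns[1:]
    ]


def write_spectra_matrix(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra sharing one grid as a matrix CSV."""
    if not spectra:
        raise ValueError("no spectra to write")
    wl = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if s.n_points != wl.size or np.max(np.abs(s.wavelengths_nm - wl)) > GRID_TOL_NM:
            raise GridError("spectra do not share a wavelength grid")
    data = {"wavelength_nm": wl}
    for i, s in enumerate(spectra):
        data[s.label or f"sample_{i + 1}"] = s.absorbance_au
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
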