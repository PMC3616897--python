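"""Ratio-subtraction resolution of an extended interfering component.

Given a ternary mixture spectrum in which one component (here AML, "Y")
absorbs beyond the others ("X" = OLM + HCT), the algorithm is

1. divide the mixture by a unit-concentration divisor spectrum Y' of the
   interferent, giving a ratio spectrum X/Y' + Y/Y';
2. read the constant Y/Y' as the flat level of the ratio spectrum in a
   plateau where only Y absorbs (350-400 nm by default);
3. subtract the constant and multiply back by Y' to recover X.

On noiseless Beer-Lambert data the round trip is exact, and the recovered
X spectrum does not depend on the divisor concentration used — the
divisor is a free normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectra import (
    GRID_TOL_NM,
    PLATEAU_WINDOW,
    SpectralWindow,
    Spectrum,
    restrict,
)

__all__ = [
    "DIVISION_FLOOR_AU",
    "UnusableDivisorError",
    "RatioSubtractionResult",
    "normalize_divisor",
    "plateau_constant",
    "ratio_subtract",
]

#: Grid points where the divisor absorbance falls below this value are
#: excluded from the ratio; division by near-zero absorbance is unstable.
DIVISION_FLOOR_AU = 1e-4

#: Plateau spread above this fraction of the constant records a warning.
FLATNESS_TOL = 0.05


_log = logging.getLogger(__name__)


class UnusableDivisorError(ValueError):
    """The divisor is below the division floor across the needed region."""


@dataclass
class RatioSubtractionResult:
    """Outcome of one ratio-subtraction pass.

    ``constant`` is the plateau estimate of Y/Y'; with a unit-normalized
    divisor it equals the interferent concentration, reported as
    ``interferent_ug_per_ml`` after rescaling by the divisor
    concentration.  ``flatness`` is the SD of the ratio spectrum inside
    the plateau; a large value relative to the constant means the plateau
    assumption (only Y absorbs there) is doubtful.
    """

    ratio_spectrum: Spectrum
    constant: float
    plateau_window: SpectralWindow
    recovered_spectrum: Spectrum
    flatness: float
    interferent_ug_per_ml: float
    warnings: list[str] = field(default_factory=list)


def normalize_divisor(pure_spectrum: Spectrum, concentration_ug_per_ml: float) -> Spectrum:
    """Scale a pure-component spectrum to unit concentration (Y').

    The result is an absorptivity-like curve: dividing any mixture by it
    expresses the interferent contribution directly in ug/mL.
    """
    if concentration_ug_per_ml <= 0:
        raise ValueError("divisor concentration must be > 0")
    out = pure_spectrum.with_absorbance(
        pure_spectrum.absorbance_au / concentration_ug_per_ml,
        label=f"{pure_spectrum.label}/{concentration_ug_per_ml:g}",
    )
    out.concentrations_ug_per_ml = None
    return out


def plateau_constant(ratio: Spectrum, plateau: SpectralWindow,
                     estimator: str = "median") -> tuple[float, float]:
    """Location and spread of the ratio spectrum inside the plateau.

    Returns ``(constant, flatness)`` where the constant is the median
    (or mean, with ``estimator='mean'``) of the plateau values and the
    flatness their sample SD.  The median is the default because it is
    robust to edge effects at the plateau boundaries.
    """
    sub = restrict(ratio, plateau)
    vals = sub.absorbance_au
    if estimator == "median":
        constant = float(np.median(vals))
    elif estimator == "mean":
        constant = float(np.mean(vals))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    flatness = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return constant, flatness


def _largest_support_block(mask: np.ndarray) -> slice:
    """Largest contiguous run of True values (the working region)."""
    if not mask.any():
        raise UnusableDivisorError("divisor below the division floor everywhere")
    idx = np.flatnonzero(mask)
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    k = int(np.argmax(idx[ends] - idx[starts]))
    return slice(int(idx[starts[k]]), int(idx[ends[k]]) + 1)


def ratio_subtract(mixture: Spectrum, divisor: Spectrum,
                   plateau: SpectralWindow = PLATEAU_WINDOW,
                   divisor_concentration_ug_per_ml: float = 1.0,
                   floor_au: float = DIVISION_FLOOR_AU,
                   estimator: str = "median") -> RatioSubtractionResult:
    """Remove the interferent from a mixture spectrum.

    ``divisor`` is the (typically unit-normalized) pure interferent
    spectrum; ``divisor_concentration_ug_per_ml`` states the concentration
    it represents so the interferent estimate ``constant * concentration``
    can be reported.  The ratio is computed only where the divisor is at
    or above ``floor_au``; the recovered spectrum is returned on the
    largest contiguous block of that support.
    """
    if mixture.n_points != divisor.n_points or \
            np.max(np.abs(mixture.wavelengths_nm - divisor.wavelengths_nm)) > GRID_TOL_NM:
        raise ValueError("mixture and divisor must share a wavelength grid")

    support = _largest_support_block(divisor.absorbance_au >= floor_au)
    wl = mixture.wavelengths_nm[support]
    ratio_vals = mixture.absorbance_au[support] / divisor.absorbance_au[support]
    ratio = Spectrum(wl, ratio_vals, label=f"{mixture.label}_ratio")

    if plateau.end_nm < wl[0] or plateau.start_nm > wl[-1]:
        raise UnusableDivisorError(
            "divisor below the division floor across the plateau window"
        )
    clipped = SpectralWindow(max(plateau.start_nm, wl[0]),
                             min(plateau.end_nm, wl[-1]), closed=plateau.closed)
    constant, flatness = plateau_constant(ratio, clipped, estimator=estimator)

    notes: list[str] = []
    if constant != 0 and flatness > FLATNESS_TOL * abs(constant):
        msg = (f"plateau is not flat: SD {flatness:.4g} exceeds "
               f"{FLATNESS_TOL:.0%} of the constant {constant:.4g}")
        notes.append(msg)
        _log.warning(msg)

    recovered_vals = (ratio_vals - constant) * divisor.absorbance_au[support]
    recovered = Spectrum(wl, recovered_vals, label=f"{mixture.label}_recovered")

    return RatioSubtractionResult(
        ratio_spectrum=ratio,
        constant=constant,
        plateau_window=clipped,
        recovered_spectrum=recovered,
        flatness=flatness,
        interferent_ug_per_ml=constant * divisor_concentration_ug_per_ml,
        warnings=notes,
    )
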