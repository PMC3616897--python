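"""Synthetic Beer-Lambert spectra for the AML/OLM/HCT ternary system.

The generator emulates the qualitative structure of the three drugs'
UV-vis spectra that the resolution methods rely on, without claiming to
reproduce the true absorptivity curves:

* all three components overlap heavily in 200-300 nm;
* amlodipine (AML) alone absorbs above 340 nm, with a measurable band at
  359 nm;
* hydrochlorothiazide (HCT) absorbs at 315 nm where olmesartan (OLM) does
  not;
* OLM and HCT share a single isoabsorptive crossing at 260.5 nm inside
  230-340 nm.

Each pure component is a sum of Gaussian absorptivity bands
(AU mL ug^-1), optionally clipped to zero above a hard cutoff wavelength.
Mixtures follow Beer-Lambert additivity with optional additive Gaussian
noise.  Band amplitudes are frozen so a 10 ug/mL solution peaks between
0.1 and 1.0 AU, which puts the direct calibration slopes at the same
order of magnitude as a bench spectrophotometer would give (about
0.011 AU per ug/mL for AML at 359 nm).

The 260.5 nm crossing is solved, not hand-tuned: two OLM band amplitudes
are chosen so the OLM-HCT absorptivity difference is zero at 260.5 nm
*and* antisymmetric across the bracketing 260/261 nm grid points.  The
second condition makes linear interpolation on the default 1 nm grid
agree exactly with the analytic crossing, so the isoabsorptive read is
free of interpolation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum, default_grid

__all__ = [
    "ANALYTES",
    "PureComponentModel",
    "NoiseModel",
    "default_library",
    "make_pure_spectrum",
    "make_mixture",
    "make_dataset",
]

#: Canonical analyte order used throughout the package.
ANALYTES = ("AML", "OLM", "HCT")


@dataclass(frozen=True)
class PureComponentModel:
    """Parametric absorptivity curve for one analyte.

    ``bands`` is a sequence of ``(center_nm, sigma_nm, peak)`` Gaussian
    bands with ``peak`` in AU mL ug^-1.  When ``hard_cutoff_nm`` is set the
    absorptivity is exactly zero at and above that wavelength, mimicking a
    compound that simply stops absorbing.
    """

    analyte_id: str
    bands: tuple[tuple[float, float, float], ...]
    hard_cutoff_nm: float | None = None

    def __post_init__(self) -> None:
        for c, s, p in self.bands:
            if s <= 0:
                raise ValueError(f"{self.analyte_id}: band sigma must be > 0")
            if p < 0:
                raise ValueError(f"{self.analyte_id}: peak absorptivity must be >= 0")

    def absorptivity(self, wavelengths_nm: np.ndarray | float) -> np.ndarray:
        """Absorptivity (AU mL ug^-1) at the given wavelengths."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        a = np.zeros_like(lam)
        for center, sigma, peak in self.bands:
            a = a + peak * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
        if self.hard_cutoff_nm is not None:
            a = np.where(lam >= self.hard_cutoff_nm, 0.0, a)
        return a


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian absorbance noise.

    ``uv_edge_sd_au`` optionally adds extra noise below ``uv_edge_nm`` to
    mimic the unreliable short-wavelength end of a real instrument; it is
    zero by default.
    """

    sd_au: float = 0.0
    seed: int = 0
    uv_edge_sd_au: float = 0.0
    uv_edge_nm: float = 230.0

    def __post_init__(self) -> None:
        if self.sd_au < 0 or self.uv_edge_sd_au < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def sample(self, wavelengths_nm: np.ndarray,
               rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(self.seed)
        eps = rng.normal(0.0, self.sd_au, size=wavelengths_nm.size) \
            if self.sd_au > 0 else np.zeros(wavelengths_nm.size)
        if self.uv_edge_sd_au > 0:
            edge = wavelengths_nm < self.uv_edge_nm
            eps = eps + np.where(
                edge, rng.normal(0.0, self.uv_edge_sd_au, size=wavelengths_nm.size), 0.0
            )
        return eps


# -- frozen band parameters ----------------------------------------------

_AML_BANDS = ((238.0, 16.0, 0.050), (359.0, 20.0, 0.011))
_HCT_FIXED_BANDS = ((226.0, 14.0, 0.045), (270.0, 18.0, 0.040))
_HCT_315_BAND = (315.0, 10.0)          # amplitude solved below
_OLM_FIXED_BAND = (232.0, 13.0, 0.060)
_OLM_SOLVED_BANDS = ((253.0, 15.0), (265.0, 14.0))   # amplitudes solved below
_OLM_CUTOFF_NM = 310.0
_HCT_CUTOFF_NM = 340.0
_ISO_NM = 260.5
_HCT_315_TARGET = 0.010                # absorptivity of HCT at 315 nm


def _gauss(lam: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def default_library() -> dict[str, PureComponentModel]:
    """The frozen three-component band library.

    Constructed constraints (all exact by construction):

    * OLM and HCT absorptivity are zero for wavelengths >= 340 nm (OLM
      already from 310 nm, so it is also zero at 315 nm);
    * AML absorptivity is positive at 359 nm (0.011 AU mL/ug);
    * HCT absorptivity at 315 nm equals 0.010 AU mL/ug;
    * OLM and HCT absorptivities are equal at exactly 260.5 nm, the only
      crossing inside 230-340 nm, and the equality also holds for linear
      interpolation between the 260 and 261 nm grid samples.
    """
    # HCT: fix the 315 nm absorptivity by solving the local band amplitude.
    pts315 = np.array([315.0])
    rest = sum(p * _gauss(pts315, c, s) for c, s, p in _HCT_FIXED_BANDS)[0]
    p315 = _HCT_315_TARGET - rest
    hct = PureComponentModel(
        "HCT",
        _HCT_FIXED_BANDS + ((_HCT_315_BAND[0], _HCT_315_BAND[1], p315),),
        hard_cutoff_nm=_HCT_CUTOFF_NM,
    )

    # OLM: solve two band amplitudes so that the OLM-HCT difference d
    # satisfies d(260.5) = 0 and d(260) + d(261) = 0.  The second condition
    # makes the 1 nm-grid linear interpolant of both curves agree at
    # 260.5 nm as well.
    pts = np.array([_ISO_NM, 260.0, 261.0])
    (c1, s1), (c2, s2) = _OLM_SOLVED_BANDS
    g1, g2 = _gauss(pts, c1, s1), _gauss(pts, c2, s2)
    cf, sf, pf = _OLM_FIXED_BAND
    fixed = pf * _gauss(pts, cf, sf)
    h = hct.absorptivity(pts)
    m = np.array([[g1[0], g2[0]], [g1[1] + g1[2], g2[1] + g2[2]]])
    rhs = np.array([h[0] - fixed[0], (h[1] - fixed[1]) + (h[2] - fixed[2])])
    amp1, amp2 = np.linalg.solve(m, rhs)
    olm = PureComponentModel(
        "OLM",
        (_OLM_FIXED_BAND, (c1, s1, float(amp1)), (c2, s2, float(amp2))),
        hard_cutoff_nm=_OLM_CUTOFF_NM,
    )

    aml = PureComponentModel("AML", _AML_BANDS)
    return {"AML": aml, "OLM": olm, "HCT": hct}


# -- spectrum synthesis ---------------------------------------------------

def make_mixture(library: Mapping[str, PureComponentModel],
                 concentrations_ug_per_ml: Mapping[str, float],
                 noise: NoiseModel | None = None,
                 grid_nm: np.ndarray | None = None,
                 rng: np.random.Generator | None = None,
                 background: Callable[[np.ndarray], np.ndarray] | None = None,
                 label: str = "") -> Spectrum:
    """Beer-Lambert mixture spectrum: A(lam) = sum_i c_i a_i(lam) + eps.

    ``background`` optionally adds a smooth excipient-like curve (AU) on
    top of the analyte signal; it is zero by default.  Noise is drawn from
    ``noise`` (reproducible via its seed, or via an explicit ``rng``).
    """
    lam = default_grid() if grid_nm is None else np.asarray(grid_nm, dtype=float)
    a = np.zeros_like(lam)
    for analyte, conc in concentrations_ug_per_ml.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {analyte}: {conc}")
        if analyte not in library:
            raise KeyError(f"analyte {analyte!r} not in library")
        a = a + conc * library[analyte].absorptivity(lam)
    if background is not None:
        a = a + background(lam)
    if noise is not None:
        a = a + noise.sample(lam, rng=rng)
    return Spectrum(lam, a, label=label,
                    concentrations_ug_per_ml=dict(concentrations_ug_per_ml))


def make_pure_spectrum(model: PureComponentModel, concentration_ug_per_ml: float,
                       noise: NoiseModel | None = None,
                       grid_nm: np.ndarray | None = None,
                       rng: np.random.Generator | None = None) -> Spectrum:
    """Spectrum of a single pure standard at the given concentration."""
    return make_mixture(
        {model.analyte_id: model}, {model.analyte_id: concentration_ug_per_ml},
        noise=noise, grid_nm=grid_nm, rng=rng,
        label=f"{model.analyte_id}_{concentration_ug_per_ml:g}",
    )


def make_dataset(design, library: Mapping[str, PureComponentModel],
                 noise: NoiseModel | None = None,
                 grid_nm: np.ndarray | None = None) -> tuple[list[Spectrum], pd.DataFrame]:
    """One spectrum per design row, paired with the concentration table.

    ``design`` is a :class:`~triquant.design.DesignMatrix` (anything with a
    ``concentrations`` DataFrame whose columns are analyte identifiers).
    A single generator seeded from ``noise.seed`` drives all rows, so a
    fixed seed gives a bit-identical dataset.
    """
    conc = design.concentrations
    rng = np.random.default_rng(noise.seed) if noise is not None else None
    spectra = []
    for i, row in conc.iterrows():
        spectra.append(
            make_mixture(library, row.to_dict(), noise=noise, grid_nm=grid_nm,
                         rng=rng, label=f"mix_{i + 1:02d}")
        )
    return spectra, conc.copy()
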