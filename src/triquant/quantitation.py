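"""Univariate calibration and the orchestrated three-analyte resolution.

The spectrophotometric route determines

* AML directly at 359 nm, where neither OLM nor HCT absorbs;
* HCT at 315 nm on the spectrum recovered after ratio-subtracting AML,
  where OLM does not absorb;
* OLM + HCT jointly at the 260.5 nm isoabsorptive point (where OLM and
  HCT have the same absorptivity) on the same recovered spectrum, so OLM
  follows by subtraction.

Each read goes through an ordinary least-squares calibration line fitted
on pure standards at the same wavelength.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ratio_subtraction import RatioSubtractionResult, normalize_divisor, ratio_subtract
from .simulate import NoiseModel, PureComponentModel, make_pure_spectrum
from .spectra import PLATEAU_WINDOW, SpectralWindow, Spectrum

__all__ = [
    "AML_NM",
    "HCT_NM",
    "ISO_NM",
    "CalibrationLine",
    "TernaryResult",
    "ExtrapolationWarning",
    "IsoPointNotFoundError",
    "fit_line",
    "predict_concentration",
    "find_isoabsorptive_point",
    "build_calibration_lines",
    "resolve_ternary",
    "DEFAULT_STANDARDS",
]

#: Measurement wavelengths of the spectrophotometric route.
AML_NM = 359.0
HCT_NM = 315.0
ISO_NM = 260.5

#: Calibration standard concentrations (ug/mL).  AML and HCT are linear
#: over 5-40; the isoabsorptive line is fitted on standards over 2.5-40.
DEFAULT_STANDARDS: dict[str, tuple[float, ...]] = {
    "aml": (5, 10, 15, 20, 25, 30, 35, 40),
    "hct": (5, 10, 15, 20, 25, 30, 35, 40),
    "iso": (2.5, 5, 10, 15, 20, 25, 30, 40),
}


class ExtrapolationWarning(UserWarning):
    """A concentration was predicted outside the line's fitted range."""


class IsoPointNotFoundError(ValueError):
    """No isoabsorptive crossing inside the search window."""


@dataclass
class CalibrationLine:
    """A fitted absorbance-vs-concentration line at one wavelength.

    ``sigma_intercept`` is the OLS standard error of the intercept, the
    sigma entering the LOD/LOQ formulas.
    """

    wavelength_nm: float
    slope: float                       # AU per ug/mL
    intercept: float                   # AU
    r: float
    sigma_intercept: float
    range_ug_per_ml: tuple[float, float]
    analyte: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        lo, hi = self.range_ug_per_ml
        if not lo < hi:
            raise ValueError("range low must be below range high")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["range_ug_per_ml"] = list(self.range_ug_per_ml)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationLine":
        d = dict(d)
        d["range_ug_per_ml"] = tuple(d["range_ug_per_ml"])
        return cls(**d)


@dataclass
class TernaryResult:
    """Resolved concentrations of one ternary mixture (ug/mL).

    ``olm_ug_per_ml`` is ``total_iso_ug_per_ml - hct_ug_per_ml`` by
    construction.  Negative estimates are reported as-is (with a warning
    message in ``warnings``) because they are a useful quality signal.
    """

    aml_ug_per_ml: float
    hct_ug_per_ml: float
    olm_ug_per_ml: float
    total_iso_ug_per_ml: float
    diagnostics: RatioSubtractionResult
    recoveries_pct: dict[str, float] | None = None
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {"AML": self.aml_ug_per_ml, "OLM": self.olm_ug_per_ml,
                "HCT": self.hct_ug_per_ml}


def fit_line(concentrations_ug_per_ml: Sequence[float],
             absorbances_au: Sequence[float],
             wavelength_nm: float,
             analyte: str = "") -> CalibrationLine:
    """Ordinary least-squares calibration line A = slope*C + intercept."""
    c = np.asarray(concentrations_ug_per_ml, dtype=float)
    a = np.asarray(absorbances_au, dtype=float)
    if c.size != a.size:
        raise ValueError("concentration and absorbance lengths differ")
    if c.size < 3:
        raise ValueError("at least 3 calibration points are required")
    if np.ptp(c) == 0:
        raise ValueError("degenerate design: concentrations are all equal")
    fit = stats.linregress(c, a)
    return CalibrationLine(
        wavelength_nm=wavelength_nm,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        sigma_intercept=float(fit.intercept_stderr),
        range_ug_per_ml=(float(c.min()), float(c.max())),
        analyte=analyte,
    )


def predict_concentration(line: CalibrationLine, absorbance_au: float) -> float:
    """Invert the calibration line: C = (A - intercept) / slope.

    Extrapolation outside the fitted range raises an
    :class:`ExtrapolationWarning` but still returns the value.
    """
    conc = (absorbance_au - line.intercept) / line.slope
    lo, hi = line.range_ug_per_ml
    if not lo <= conc <= hi:
        warnings.warn(
            f"predicted {conc:.3g} ug/mL lies outside the calibrated "
            f"range [{lo:g}, {hi:g}] at {line.wavelength_nm:g} nm",
            ExtrapolationWarning, stacklevel=2,
        )
    return float(conc)


def find_isoabsorptive_point(pure_a: Spectrum, pure_b: Spectrum,
                             conc_a_ug_per_ml: float, conc_b_ug_per_ml: float,
                             search: SpectralWindow) -> list[float]:
    """Crossing wavelengths of two unit-normalized spectra in a window.

    Both spectra are scaled to unit concentration; crossings of their
    difference are located by sign change between adjacent grid points
    with linear root refinement.  An exact zero at an interior grid point
    counts as a crossing only when the neighbours change sign across it,
    so regions where both curves are flat zero are not reported.

    Returns all crossings (usually one).  Raises
    :class:`IsoPointNotFoundError` when none is found — in particular for
    two proportional spectra, which cross nowhere or everywhere.
    """
    a = normalize_divisor(pure_a, conc_a_ug_per_ml).restrict(search)
    b = normalize_divisor(pure_b, conc_b_ug_per_ml).restrict(search)
    if a.n_points != b.n_points or np.any(a.wavelengths_nm != b.wavelengths_nm):
        raise ValueError("spectra must share a wavelength grid")
    wl = a.wavelengths_nm
    d = a.absorbance_au - b.absorbance_au
    crossings: list[float] = []
    for i in range(d.size - 1):
        if d[i] * d[i + 1] < 0:
            t = d[i] / (d[i] - d[i + 1])
            crossings.append(float(wl[i] + t * (wl[i + 1] - wl[i])))
        elif d[i] == 0 and 0 < i and d[i - 1] * d[i + 1] < 0:
            crossings.append(float(wl[i]))
    if d[-1] == 0 and d.size > 1 and d[-2] != 0:
        # end-point zero reached with a nonzero approach is a touch, not
        # an isolated crossing; ignore it.
        pass
    if not crossings:
        raise IsoPointNotFoundError(
            f"no isoabsorptive crossing in [{search.start_nm}, {search.end_nm}] nm"
        )
    return crossings


def build_calibration_lines(library: Mapping[str, PureComponentModel],
                            noise: NoiseModel | None = None,
                            standards: Mapping[str, Sequence[float]] | None = None,
                            rng: np.random.Generator | None = None,
                            iso_on: str = "HCT") -> dict[str, CalibrationLine]:
    """Fit the three working calibration lines from simulated standards.

    ``aml`` at 359 nm on AML standards, ``hct`` at 315 nm on HCT
    standards, and ``iso`` at 260.5 nm on standards of ``iso_on`` (HCT by
    default; OLM standards are equivalent at the isoabsorptive point).
    """
    std = {**DEFAULT_STANDARDS, **(standards or {})}
    specs = [("aml", "AML", AML_NM, std["aml"]),
             ("hct", "HCT", HCT_NM, std["hct"]),
             ("iso", iso_on, ISO_NM, std["iso"])]
    lines: dict[str, CalibrationLine] = {}
    for key, analyte, wl, concs in specs:
        absorbances = [
            make_pure_spectrum(library[analyte], c, noise=noise, rng=rng).value_at(wl)
            for c in concs
        ]
        lines[key] = fit_line(concs, absorbances, wl, analyte=analyte)
    return lines


def resolve_ternary(mixture: Spectrum, pure_aml: Spectrum,
                    lines: Mapping[str, CalibrationLine],
                    aml_divisor_concentration_ug_per_ml: float | None = None,
                    plateau: SpectralWindow = PLATEAU_WINDOW,
                    true_concentrations_ug_per_ml: Mapping[str, float] | None = None,
                    ) -> TernaryResult:
    """Full spectrophotometric resolution of one ternary mixture.

    Steps: direct AML read at 359 nm; ratio subtraction with the
    normalized pure AML spectrum as divisor; HCT read at 315 nm and the
    OLM+HCT total at 260.5 nm on the recovered spectrum; OLM by
    subtraction.  When the true composition is supplied, per-analyte
    recoveries (percent) are attached.
    """
    for key in ("aml", "hct", "iso"):
        if key not in lines:
            raise KeyError(f"missing calibration line {key!r}")
    if aml_divisor_concentration_ug_per_ml is None:
        conc_map = pure_aml.concentrations_ug_per_ml or {}
        aml_divisor_concentration_ug_per_ml = conc_map.get("AML")
        if aml_divisor_concentration_ug_per_ml is None:
            raise ValueError(
                "divisor concentration not given and not recorded on the "
                "pure AML spectrum"
            )

    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        aml = predict_concentration(lines["aml"], mixture.value_at(AML_NM))

        divisor = normalize_divisor(pure_aml, aml_divisor_concentration_ug_per_ml)
        rs = ratio_subtract(mixture, divisor, plateau=plateau,
                            divisor_concentration_ug_per_ml=1.0)
        recovered = rs.recovered_spectrum
        hct = predict_concentration(lines["hct"], recovered.value_at(HCT_NM))
        total = predict_concentration(lines["iso"], recovered.value_at(ISO_NM))
    olm = total - hct

    for name, value in (("AML", aml), ("HCT", hct), ("OLM", olm)):
        if value < 0:
            notes.append(f"negative concentration estimate for {name}: {value:.4g}")
    notes.extend(rs.warnings)

    recoveries = None
    if true_concentrations_ug_per_ml is not None:
        from .validation import recovery
        recoveries = {
            name: recovery(found, true_concentrations_ug_per_ml[name])
            for name, found in (("AML", aml), ("OLM", olm), ("HCT", hct))
            if name in true_concentrations_ug_per_ml
        }

    return TernaryResult(
        aml_ug_per_ml=float(aml),
        hct_ug_per_ml=float(hct),
        olm_ug_per_ml=float(olm),
        total_iso_ug_per_ml=float(total),
        diagnostics=rs,
        recoveries_pct=recoveries,
        warnings=notes,
    )
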