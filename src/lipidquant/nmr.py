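"""Stoichiometric deconvolution of acylglycerol classes from 1H NMR spectra.

The pipeline is: normalize the spectrum so the TMS reference integral is
exactly 1, integrate the six assignment windows, back-substitute the
triangular proton-count system into per-species mole numbers, and convert
those to mole and weight percentages.

Mole numbers are expressed in units of C x (TMS-normalized area), where C
is the unknown proportionality constant between signal area and proton
count.  C cancels in every percentage, so it is carried symbolically as
1.0 unless the caller supplies a value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import (
    AssignmentTable,
    DEFAULT_MASSES,
    GlycerideSpecies,
    MolecularMasses,
    QUANT_WINDOW_ORDER,
    W_12DAG,
    W_13DAG,
    W_1MAG,
    W_2MAG,
    W_ALPHA,
    W_ESTER,
    default_assignment_table,
)

__all__ = [
    "Spectrum",
    "WindowAreas",
    "MoleVector",
    "CompositionReport",
    "normalize_to_tms",
    "integrate_window",
    "window_areas",
    "mole_numbers",
    "mole_percents",
    "weight_percents",
    "quantify",
    "TmsReferenceError",
    "CompositionError",
]

DEFAULT_TMS_WINDOW = (-0.05, 0.05)


class TmsReferenceError(ValueError):
    """The TMS reference signal is missing or non-positive."""


class CompositionError(ValueError):
    """The window areas are inconsistent with any non-negative composition."""


@dataclass
class Spectrum:
    """A 1D 1H spectrum: ppm axis and intensity trace.

    The ppm axis must be strictly monotone; it is stored descending
    (high field left), the NMR plotting convention.  Intensities are in
    arbitrary instrument units.
    """

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        if self.ppm.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        d = np.diff(self.ppm)
        if np.all(d > 0):
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d < 0):
            raise ValueError("ppm axis must be strictly monotone")

    @property
    def ppm_min(self) -> float:
        return float(self.ppm[-1])

    @property
    def ppm_max(self) -> float:
        return float(self.ppm[0])

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensity * factor)


def integrate_window(
    spec: Spectrum, lo: float, hi: float, baseline: str = "none"
) -> float:
    """Trapezoidal integral of intensity over the closed window [lo, hi].

    Window borders falling between grid points are handled by linear
    interpolation of the intensity at ``lo`` and ``hi``.  With
    ``baseline="linear"`` the chord between the two border intensities is
    subtracted before integrating (a per-window linear baseline).
    """
    if not lo < hi:
        raise ValueError(f"window bounds must satisfy lo < hi, got [{lo}, {hi}]")
    if lo < spec.ppm_min or hi > spec.ppm_max:
        raise ValueError(
            f"window [{lo}, {hi}] outside the spectrum range "
            f"[{spec.ppm_min}, {spec.ppm_max}]"
        )
    if baseline not in ("none", "linear"):
        raise ValueError(f"unknown baseline mode {baseline!r}")

    # work on an ascending copy for interpolation/integration
    x = spec.ppm[::-1]
    y = spec.intensity[::-1]
    inside = (x > lo) & (x < hi)
    y_lo = float(np.interp(lo, x, y))
    y_hi = float(np.interp(hi, x, y))
    xs = np.concatenate(([lo], x[inside], [hi]))
    ys = np.concatenate(([y_lo], y[inside], [y_hi]))
    if baseline == "linear":
        ys = ys - (y_lo + (y_hi - y_lo) * (xs - lo) / (hi - lo))
    return float(np.trapezoid(ys, xs))


def normalize_to_tms(
    spec: Spectrum, tms_window: tuple[float, float] = DEFAULT_TMS_WINDOW
) -> tuple[Spectrum, float]:
    """Scale the spectrum so the TMS integral over ``tms_window`` is 1.00000.

    Returns the scaled spectrum and the raw TMS integral.  A non-positive
    TMS integral raises :class:`TmsReferenceError`: quantification without
    the reference would be meaningless and there is no silent fallback.
    """
    lo, hi = tms_window
    area = integrate_window(spec, lo, hi)
    if area <= 0.0:
        raise TmsReferenceError(
            f"TMS integral over [{lo}, {hi}] ppm is {area:g}; "
            "a positive reference signal is required"
        )
    return spec.scaled(1.0 / area), area


@dataclass
class WindowAreas:
    """Integrated areas of the six quantification windows (TMS units)."""

    areas: dict[str, float]
    tms_area_raw: float = float("nan")

    #: negative areas larger in magnitude than this fraction of the largest
    #: window area indicate a corrupted baseline rather than noise
    NEGATIVE_AREA_REL_TOL = 1e-2

    def validate(self, rel_tol: float = NEGATIVE_AREA_REL_TOL) -> None:
        biggest = max((abs(a) for a in self.areas.values()), default=0.0)
        floor = -rel_tol * biggest
        for key, a in self.areas.items():
            if a < floor:
                raise CompositionError(
                    f"window {key} integrates to {a:g}, below the noise floor"
                )


def window_areas(
    spec: Spectrum,
    table: AssignmentTable | None = None,
    baseline: str = "none",
    tms_window: tuple[float, float] = DEFAULT_TMS_WINDOW,
) -> WindowAreas:
    """TMS-normalize ``spec`` and integrate every quantification window."""
    table = table or default_assignment_table()
    normed, raw = normalize_to_tms(spec, tms_window)
    areas = {
        key: integrate_window(normed, lo, hi, baseline)
        for key, (lo, hi) in table.quant_windows().items()
    }
    wa = WindowAreas(areas, tms_area_raw=raw)
    wa.validate()
    return wa


@dataclass
class MoleVector:
    """Per-species mole numbers in units of C x (normalized area)."""

    n_1mag: float
    n_2mag: float
    n_12dag: float
    n_13dag: float
    n_tag: float
    n_fa: float
    c_constant: float = 1.0
    clamped: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "1-MAG": self.n_1mag,
            "2-MAG": self.n_2mag,
            "1,2-DAG": self.n_12dag,
            "1,3-DAG": self.n_13dag,
            "TAG": self.n_tag,
            "FA": self.n_fa,
        }

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())


def mole_numbers(
    areas: WindowAreas,
    c_constant: float = 1.0,
    clamp_rel_tol: float = 0.05,
) -> MoleVector:
    """Back-substitute window areas into per-species mole numbers.

    The glyceryl windows give 1-MAG, 2-MAG, 1,2-DAG and 1,3-DAG directly;
    TAG is what remains of the 4.11-4.38 ppm ester envelope after removing
    the partial-glyceride contributions, and the free fatty acid is the
    remainder of the alpha-CH2 window after removing every esterified
    chain.  Small negative remainders (magnitude up to
    ``clamp_rel_tol`` x total moles) are clamped to zero and recorded in
    ``clamped``; larger ones indicate a mis-referenced or mis-assigned
    spectrum and raise :class:`CompositionError`.
    """
    a = areas.areas
    missing = [k for k in QUANT_WINDOW_ORDER if k not in a]
    if missing:
        raise ValueError(f"missing window areas: {missing}")
    C = c_constant

    n_1mag = C * a[W_1MAG]
    n_2mag = C * a[W_2MAG] / 4.0
    n_12dag = C * a[W_12DAG] / 2.0
    n_13dag = C * a[W_13DAG]
    n_tag = (C * a[W_ESTER] - 2 * n_1mag - 2 * n_12dag - 4 * n_13dag) / 4.0
    n_fa = (
        C * a[W_ALPHA]
        - 6 * n_tag
        - 4 * n_12dag
        - 4 * n_13dag
        - 2 * n_1mag
        - 2 * n_2mag
    ) / 2.0

    names = ["1-MAG", "2-MAG", "1,2-DAG", "1,3-DAG", "TAG", "FA"]
    vals = [n_1mag, n_2mag, n_12dag, n_13dag, n_tag, n_fa]
    scale = sum(v for v in vals if v > 0)
    floor = -clamp_rel_tol * scale
    clamped: list[str] = []
    for i, (name, v) in enumerate(zip(names, vals)):
        if v < 0:
            if v < floor:
                raise CompositionError(
                    f"mole number of {name} is {v:g} "
                    f"(more negative than {floor:g}); the window budget for "
                    "this species is inconsistent with the other windows"
                )
            vals[i] = 0.0
            clamped.append(name)
    return MoleVector(*vals, c_constant=C, clamped=clamped)


def mole_percents(moles: MoleVector) -> dict[str, float]:
    """Mole percentages of MAG (pooled), 1,2-DAG, 1,3-DAG, DAG, TAG, FA.

    The denominator is the sum over all six species, so the result is
    independent of the proportionality constant C.  The pooled DAG entry
    is exactly the sum of its positional isomers.
    """
    total = moles.total
    if total <= 0:
        raise CompositionError(
            "all mole numbers are zero; the composition is undefined"
        )
    p12 = 100.0 * moles.n_12dag / total
    p13 = 100.0 * moles.n_13dag / total
    return {
        "MAG": 100.0 * (moles.n_1mag + moles.n_2mag) / total,
        "1,2-DAG": p12,
        "1,3-DAG": p13,
        "DAG": p12 + p13,
        "TAG": 100.0 * moles.n_tag / total,
        "FA": 100.0 * moles.n_fa / total,
    }


def weight_percents(
    mole_pct: dict[str, float], masses: MolecularMasses = DEFAULT_MASSES
) -> dict[str, float]:
    """Convert mole percentages to weight percentages.

    Each class is weighted by its average molecular mass (both DAG isomers
    use the DAG mass); the denominator runs over MAG, DAG, TAG and FA.
    """
    denom = (
        mole_pct["MAG"] * masses.m_mag
        + mole_pct["DAG"] * masses.m_dag
        + mole_pct["TAG"] * masses.m_tag
        + mole_pct["FA"] * masses.m_fa
    )
    if denom <= 0:
        raise CompositionError("weight-percent denominator is non-positive")
    w12 = 100.0 * mole_pct["1,2-DAG"] * masses.m_dag / denom
    w13 = 100.0 * mole_pct["1,3-DAG"] * masses.m_dag / denom
    return {
        "MAG": 100.0 * mole_pct["MAG"] * masses.m_mag / denom,
        "1,2-DAG": w12,
        "1,3-DAG": w13,
        "DAG": w12 + w13,
        "TAG": 100.0 * mole_pct["TAG"] * masses.m_tag / denom,
        "FA": 100.0 * mole_pct["FA"] * masses.m_fa / denom,
    }


@dataclass
class CompositionReport:
    """Full quantification result for one spectrum."""

    mole_percent: dict[str, float]
    weight_percent: dict[str, float]
    moles: MoleVector
    areas: WindowAreas
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mole_percent": self.mole_percent,
            "weight_percent": self.weight_percent,
            "mole_numbers": self.moles.as_dict(),
            "window_areas": self.areas.areas,
            "tms_area_raw": self.areas.tms_area_raw,
            "diagnostics": self.diagnostics,
        }


def _tms_snr(spec: Spectrum, tms_window: tuple[float, float]) -> float:
    """Crude TMS signal-to-noise: peak height over a robust noise sd.

    Noise is estimated from 6-9.5 ppm (or whatever part of it the spectrum
    covers), a region empty of lipid signals.
    """
    lo = max(6.0, spec.ppm_min)
    hi = min(9.5, spec.ppm_max)
    if hi <= lo:
        return float("nan")
    quiet = spec.intensity[(spec.ppm >= lo) & (spec.ppm <= hi)]
    if quiet.size < 16:
        return float("nan")
    sd = 1.4826 * float(np.median(np.abs(quiet - np.median(quiet))))
    in_tms = (spec.ppm >= tms_window[0]) & (spec.ppm <= tms_window[1])
    peak = float(np.max(spec.intensity[in_tms])) if in_tms.any() else float("nan")
    return peak / sd if sd > 0 else float("inf")


def quantify(
    spec: Spectrum,
    table: AssignmentTable | None = None,
    masses: MolecularMasses = DEFAULT_MASSES,
    baseline: str = "none",
    tms_window: tuple[float, float] = DEFAULT_TMS_WINDOW,
    c_constant: float = 1.0,
) -> CompositionReport:
    """Quantify glyceride classes in a 1H spectrum, end to end."""
    table = table or default_assignment_table()
    areas = window_areas(spec, table, baseline=baseline, tms_window=tms_window)
    moles = mole_numbers(areas, c_constant=c_constant)
    mol_pct = mole_percents(moles)
    wt_pct = weight_percents(mol_pct, masses)
    diags = {
        "clamped_species": list(moles.clamped),
        "tms_snr": _tms_snr(spec, tms_window),
        "baseline": baseline,
    }
    if moles.clamped:
        warnings.warn(
            f"mole numbers clamped to zero for {moles.clamped}",
            stacklevel=2,
        )
    return CompositionReport(mol_pct, wt_pct, moles, areas, diags)
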