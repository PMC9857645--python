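"""Synthetic data with known ground truth for every pipeline stage.

Simulated 1H spectra are sums of Lorentzian lines on a uniform ppm grid:
one line per quantification window carrying the window's stoichiometric
area (instrument gain x moles x protons), a TMS reference line at 0 ppm,
broader cosmetic acyl-chain envelopes (CH3, bulk CH2, beta/allylic/
bis-allylic CH2, olefinic CH), and additive Gaussian noise.  Each
quantification line is amplitude-scaled so that its trapezoidal integral
*inside its own window* equals the stoichiometric area exactly; what one
window's tails deposit into the other windows is left in as the realistic
imperfection the recovery tests have to absorb.

FAME peak tables are drawn as lognormal-noised areas around a ground-truth
fractional composition, and batch fixtures bundle spectra, FAME tables and
fermentation records with a truth manifest for end-to-end testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AssignmentTable,
    FattyAcidCode,
    GlycerideSpecies,
    default_assignment_table,
    parse_fa_code,
)
from .nmr import DEFAULT_TMS_WINDOW, Spectrum, integrate_window, MoleVector, mole_percents, weight_percents

__all__ = [
    "GroundTruthComposition",
    "SimulationParams",
    "simulate_spectrum",
    "simulate_fame_table",
    "generate_batch_fixture",
    "true_percentages",
]


@dataclass(frozen=True)
class GroundTruthComposition:
    """True mole numbers per glyceride species, plus spectrum-level knobs.

    ``mean_double_bonds`` is the average number of C=C per acyl chain
    (drives the cosmetic unsaturation signals only); ``gain`` is the
    arbitrary instrument scale that TMS normalization must cancel.
    """

    moles: dict[GlycerideSpecies, float]
    mean_double_bonds: float = 0.9
    gain: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.moles.values()):
            raise ValueError("mole numbers must be non-negative")
        if not any(v > 0 for v in self.moles.values()):
            raise ValueError("at least one species must have positive moles")
        if self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if not 0 <= self.mean_double_bonds <= 3:
            raise ValueError("mean double bonds per chain must be in [0, 3]")

    def mole(self, sp: GlycerideSpecies) -> float:
        return self.moles.get(sp, 0.0)

    @property
    def total_chains(self) -> float:
        return sum(m * sp.acyl_count for sp, m in self.moles.items())


@dataclass(frozen=True)
class SimulationParams:
    """Grid, lineshape and noise settings for spectrum synthesis."""

    ppm_max: float = 10.0
    ppm_min: float = -0.5
    n_points: int = 2**16
    hwhm: float = 0.001  # ppm; 0.6 Hz at 600 MHz
    noise_sd_rel: float = 1e-3  # relative to the tallest peak
    # mole ratio TMS : total analyte for ~0.03 % v/v TMS in CDCl3 against
    # ~10 mg lipid, when analyte moles are expressed on a unit-sum scale
    tms_moles: float = 0.125
    tms_window: tuple[float, float] = DEFAULT_TMS_WINDOW

    def __post_init__(self) -> None:
        if self.hwhm <= 0:
            raise ValueError("Lorentzian half-width must be positive")
        if self.n_points < 16:
            raise ValueError("grid too coarse")
        if self.ppm_min >= self.ppm_max:
            raise ValueError("ppm_min must be below ppm_max")

    def grid(self) -> np.ndarray:
        # descending, the storage convention
        return np.linspace(self.ppm_max, self.ppm_min, self.n_points)


def _lorentz(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-total-area Lorentzian."""
    return (hwhm / np.pi) / ((x - center) ** 2 + hwhm**2)


def _gauss(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-total-area Gaussian parameterized by its HWHM."""
    sigma = hwhm / np.sqrt(2.0 * np.log(2.0))
    return np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


# cosmetic acyl-chain envelope: (center ppm, HWHM ppm, protons per chain
# as a function of mean double bonds d)
_ACYL_ENVELOPE = (
    (0.88, 0.008, lambda d: 3.0),  # terminal CH3
    (1.30, 0.020, lambda d: 20.0),  # bulk (CH2)n
    (1.61, 0.010, lambda d: 2.0),  # beta CH2
    (2.02, 0.010, lambda d: 4.0 * d),  # allylic CH2
    (2.76, 0.008, lambda d: 2.0 * max(d - 1.0, 0.0)),  # bis-allylic CH2
    (5.35, 0.012, lambda d: 2.0 * d),  # olefinic CH=CH
)


def simulate_spectrum(
    truth: GroundTruthComposition,
    params: SimulationParams = SimulationParams(),
    table: AssignmentTable | None = None,
    seed: int | None = None,
) -> tuple[Spectrum, dict]:
    """Synthesize a spectrum realizing ``truth`` and return it with a
    ground-truth record (true mole/weight percentages).

    Raises if any quantification window spans fewer than 4 grid points.
    """
    table = table or default_assignment_table()
    x = params.grid()
    dx = (params.ppm_max - params.ppm_min) / (params.n_points - 1)
    windows = table.quant_windows()
    counts = table.proton_counts()
    for key, (lo, hi) in windows.items():
        if lo < params.ppm_min or hi > params.ppm_max:
            raise ValueError(f"grid does not cover window {key}")
        if (hi - lo) / dx < 4:
            raise ValueError(
                f"window {key} spans fewer than 4 grid points; "
                "increase n_points or widen the grid"
            )

    y = np.zeros_like(x)

    def add_contained(center: float, lo: float, hi: float, area: float) -> None:
        """Add a line whose in-window trapezoidal integral equals ``area``."""
        if area <= 0:
            return
        curve = _lorentz(x, center, params.hwhm)
        frac = integrate_window(Spectrum(x.copy(), curve), lo, hi)
        y[:] += (area / frac) * curve

    for key, (lo, hi) in windows.items():
        total = sum(
            truth.mole(sp) * protons for sp, protons in counts[key].items()
        )
        add_contained(0.5 * (lo + hi), lo, hi, truth.gain * total)

    # TMS reference: 12 equivalent protons at 0.00 ppm
    add_contained(
        0.0,
        params.tms_window[0],
        params.tms_window[1],
        truth.gain * 12.0 * params.tms_moles,
    )

    # cosmetic realism: acyl-chain envelopes plus glyceryl CH/CH2OH signals.
    # The envelopes are clusters of many overlapping multiplets, so they are
    # rendered as Gaussians: a single-Lorentzian wing at tens of linewidths
    # would deposit spurious area in the analyte windows that no real
    # multiplet cluster produces.
    d = truth.mean_double_bonds
    chains = truth.total_chains
    for center, hwhm, protons_per_chain in _ACYL_ENVELOPE:
        area = truth.gain * protons_per_chain(d) * chains
        if area > 0:
            y += area * _gauss(x, center, hwhm)
    for center, hwhm, sp, protons in (
        (3.65, 0.004, GlycerideSpecies.MAG_1, 2),  # 1-MAG CH2OH
        (5.08, 0.004, GlycerideSpecies.DAG_12, 1),  # 1,2-DAG CH(OCOR')
        (5.26, 0.004, GlycerideSpecies.TAG, 1),  # TAG CH(OCOR')
    ):
        area = truth.gain * truth.mole(sp) * protons
        if area > 0:
            y += area * _lorentz(x, center, hwhm)

    if params.noise_sd_rel > 0:
        rng = np.random.default_rng(seed if seed is not None else truth.seed)
        y += rng.normal(0.0, params.noise_sd_rel * float(y.max()), y.shape)

    record = true_percentages(truth)
    record.update(
        {
            "moles": {sp.label: m for sp, m in truth.moles.items()},
            "gain": truth.gain,
            "mean_double_bonds": d,
        }
    )
    return Spectrum(x, y), record


def true_percentages(truth: GroundTruthComposition) -> dict:
    """Ground-truth mole and weight percentages implied by ``truth``."""
    mv = MoleVector(
        n_1mag=truth.mole(GlycerideSpecies.MAG_1),
        n_2mag=truth.mole(GlycerideSpecies.MAG_2),
        n_12dag=truth.mole(GlycerideSpecies.DAG_12),
        n_13dag=truth.mole(GlycerideSpecies.DAG_13),
        n_tag=truth.mole(GlycerideSpecies.TAG),
        n_fa=truth.mole(GlycerideSpecies.FFA),
    )
    mol = mole_percents(mv)
    return {"mole_percent": mol, "weight_percent": weight_percents(mol)}


def simulate_fame_table(
    fractions: dict,
    total_area: float = 1e6,
    noise_cv: float = 0.05,
    seed: int | None = None,
    detection_floor: float = 0.0,
) -> list:
    """Draw a noisy FAME peak table around true fractional composition.

    Areas are ``total_area x fraction x LogNormal`` with unit mean and
    coefficient of variation ``noise_cv``; areas below
    ``detection_floor`` become "nd" records.
    """
    from .fame import PeakRecord

    fas: dict[FattyAcidCode, float] = {}
    for k, v in fractions.items():
        fa = k if isinstance(k, FattyAcidCode) else parse_fa_code(k)
        if v < 0:
            raise ValueError(f"negative fraction for {fa.label}")
        fas[fa] = float(v)
    total = sum(fas.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got {total}")

    rng = np.random.default_rng(seed)
    records = []
    for fa, frac in fas.items():
        if noise_cv > 0:
            sigma = float(np.sqrt(np.log1p(noise_cv**2)))
            factor = float(rng.lognormal(-0.5 * sigma**2, sigma))
        else:
            factor = 1.0
        area = total_area * frac * factor
        if area <= detection_floor:
            records.append(PeakRecord(fa, area=0.0, detected=False))
        else:
            records.append(PeakRecord(fa, area=area))
    return records


# a C16/C18-dominated base composition typical of oleaginous fungi
_BASE_FA_FRACTIONS = {
    "C14:0": 0.005,
    "C15:0": 0.005,
    "C16:0": 0.24,
    "C16:1": 0.015,
    "C18:0": 0.10,
    "C18:1": 0.37,
    "C18:2": 0.24,
    "C20:0": 0.015,
    "C22:0": 0.010,
}
assert abs(sum(_BASE_FA_FRACTIONS.values()) - 1.0) < 1e-9

_STRAINS = ("S1", "S2", "S3", "S4", "S5")


def _random_truth(rng: np.random.Generator) -> GroundTruthComposition:
    """A TAG-dominated composition of the kind oleaginous fungi produce."""
    S = GlycerideSpecies
    raw = {
        S.TAG: rng.uniform(50.0, 80.0),
        S.DAG_12: rng.uniform(3.0, 12.0),
        S.DAG_13: rng.uniform(5.0, 18.0),
        S.MAG_1: rng.uniform(0.2, 1.5),
        S.MAG_2: rng.uniform(0.2, 1.5),
        S.FFA: rng.uniform(2.0, 8.0),
    }
    total = sum(raw.values())
    moles = {sp: v / total for sp, v in raw.items()}
    return GroundTruthComposition(
        moles=moles,
        mean_double_bonds=float(rng.uniform(0.7, 1.1)),
        gain=float(rng.lognormal(0.0, 0.5)),
    )


def generate_batch_fixture(
    out_dir: str | Path,
    seed: int = 0,
    params: SimulationParams = SimulationParams(),
    fame_noise_cv: float = 0.05,
) -> dict:
    """Write a complete labeled input set for five simulated strains.

    Produces ``spectra/<strain>.txt`` (two-column ppm/intensity),
    ``fame/<strain>.csv`` peak tables, ``fermentation.csv`` records and a
    ``truth.json`` manifest containing, per strain, the true composition,
    lipid yield and DAG yields.  Fully deterministic for a given seed.
    """
    from .io import write_spectrum_text
    from .yields import BiomassRecord, ExtractionRecord, cdw, dag_yields, lipid_yield

    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    (out / "fame").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "strains": {}}
    ferm_rows = []
    for strain in _STRAINS:
        truth = _random_truth(rng)
        spec_seed = int(rng.integers(0, 2**31 - 1))
        spec, record = simulate_spectrum(truth, params, seed=spec_seed)
        write_spectrum_text(out / "spectra" / f"{strain}.txt", spec)

        # jitter the base FA composition per strain
        alpha = np.array(list(_BASE_FA_FRACTIONS.values())) * 400.0
        frac_vals = rng.dirichlet(alpha)
        fractions = dict(zip(_BASE_FA_FRACTIONS.keys(), frac_vals))
        fame_seed = int(rng.integers(0, 2**31 - 1))
        peaks = simulate_fame_table(
            fractions, noise_cv=fame_noise_cv, seed=fame_seed
        )
        pd.DataFrame(
            {
                "fa": [p.fa.label for p in peaks],
                "area": [p.area if p.detected else "nd" for p in peaks],
            }
        ).to_csv(out / "fame" / f"{strain}.csv", index=False)

        # fermentation arithmetic with realistic shake-flask numbers
        m1 = float(rng.uniform(0.8, 1.8))  # g dry biomass
        v = 0.4  # L broth
        m3 = float(rng.uniform(0.5, 1.0))  # g powder extracted
        lipid_frac = float(rng.uniform(0.10, 0.30))
        m4 = m3 * lipid_frac
        c = cdw(BiomassRecord(m1=m1, v=v))
        ly = lipid_yield(ExtractionRecord(cdw=c, m3=m3, m4=m4))
        wt = record["weight_percent"]
        y12, y13, ytot = dag_yields(ly, wt["1,2-DAG"], wt["1,3-DAG"])

        ferm_rows.append(
            {"sample": strain, "m1_g": m1, "volume_L": v, "m3_g": m3, "m4_g": m4}
        )
        manifest["strains"][strain] = {
            **record,
            "spectrum_seed": spec_seed,
            "fame_seed": fame_seed,
            "fame_fractions": {k: float(v_) for k, v_ in fractions.items()},
            "cdw_g_per_L": c,
            "lipid_yield_g_per_L": ly,
            "dag12_yield_mg_per_L": y12,
            "dag13_yield_mg_per_L": y13,
            "dag_total_yield_mg_per_L": ytot,
        }

    pd.DataFrame(ferm_rows).to_csv(out / "fermentation.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
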