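"""Fermentation yield arithmetic.

CDW productivity = dry biomass / broth volume (g/L); lipid yield scales
CDW by the lipid fraction of the extracted mycelium powder (g/L); DAG
yields convert the lipid yield and the NMR-derived weight percentages of
the two DAG isomers into mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BiomassRecord",
    "ExtractionRecord",
    "YieldReport",
    "cdw",
    "lipid_yield",
    "dag_yields",
    "yield_report",
]


@dataclass(frozen=True)
class BiomassRecord:
    """Dry biomass harvested (g) from a broth volume (L)."""

    m1: float
    v: float

    def __post_init__(self) -> None:
        if self.m1 < 0:
            raise ValueError(f"dry biomass mass must be >= 0, got {self.m1}")
        if self.v <= 0:
            raise ValueError(f"broth volume must be > 0, got {self.v}")


@dataclass(frozen=True)
class ExtractionRecord:
    """Soxhlet extraction bookkeeping.

    ``cdw`` is the biomass productivity (g/L), ``m3`` the mycelium powder
    mass weighed in (g), ``m4`` the lipid mass recovered (g).
    """

    cdw: float
    m3: float
    m4: float

    def __post_init__(self) -> None:
        if self.m3 <= 0:
            raise ValueError(f"powder mass must be > 0, got {self.m3}")
        if not 0 <= self.m4 <= self.m3:
            raise ValueError(
                f"extracted lipid mass {self.m4} must lie in [0, {self.m3}]"
            )


@dataclass(frozen=True)
class YieldReport:
    """Per-sample yields: CDW and lipid in g/L, DAG yields in mg/L."""

    cdw: float
    lipid_yield: float
    dag12_yield: float
    dag13_yield: float
    dag_total_yield: float
    sample: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "cdw_g_per_L": self.cdw,
            "lipid_yield_g_per_L": self.lipid_yield,
            "dag12_yield_mg_per_L": self.dag12_yield,
            "dag13_yield_mg_per_L": self.dag13_yield,
            "dag_total_yield_mg_per_L": self.dag_total_yield,
        }


def cdw(rec: BiomassRecord) -> float:
    """Cell-dry-weight productivity, g/L."""
    return rec.m1 / rec.v


def lipid_yield(rec: ExtractionRecord) -> float:
    """Lipid yield in g/L: CDW x (lipid mass / powder mass)."""
    return rec.cdw * rec.m4 / rec.m3


def dag_yields(
    lipid_yield_g_per_l: float, wt12: float, wt13: float
) -> tuple[float, float, float]:
    """DAG yields (1,2-; 1,3-; total) in mg/L.

    Each isomer yield is lipid yield (g/L) x its weight percentage / 100
    x 1000; the total is exactly their sum.
    """
    if lipid_yield_g_per_l < 0:
        raise ValueError(f"lipid yield must be >= 0, got {lipid_yield_g_per_l}")
    for name, w in (("1,2-DAG", wt12), ("1,3-DAG", wt13)):
        if not 0 <= w <= 100:
            raise ValueError(f"{name} weight percent {w} outside [0, 100]")
    if wt12 + wt13 > 100:
        raise ValueError(f"DAG weight percentages sum to {wt12 + wt13} > 100")
    y12 = lipid_yield_g_per_l * wt12 * 1000.0 / 100.0
    y13 = lipid_yield_g_per_l * wt13 * 1000.0 / 100.0
    return y12, y13, y12 + y13


def yield_report(
    biomass: BiomassRecord,
    m3: float,
    m4: float,
    wt12: float,
    wt13: float,
    sample: str = "",
) -> YieldReport:
    """Full yield chain from fermentation record to DAG yields."""
    c = cdw(biomass)
    ly = lipid_yield(ExtractionRecord(cdw=c, m3=m3, m4=m4))
    y12, y13, ytot = dag_yields(ly, wt12, wt13)
    return YieldReport(c, ly, y12, y13, ytot, sample=sample)
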