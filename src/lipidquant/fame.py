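"""GC-MS FAME composition profiles and their saturation-class summaries.

Peak areas from a FAME chromatogram are converted to relative percentages
by area normalization (each peak's share of the total detected area), and
profiles are summarized into the standard saturation classes:

* SFA  - saturated, no double bonds
* MUFA - monounsaturated, exactly one double bond
* PUFA - polyunsaturated, two or more
* UFA  = MUFA + PUFA

plus the combined C16+C18 share, the C18 share, and the area-weighted
mean chain length.  Fatty acids reported as "nd" (not detected) stay in
the profile with value 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .model import FattyAcidCode, parse_fa_code

__all__ = [
    "PeakRecord",
    "FAProfile",
    "ClassSummary",
    "normalize_areas",
    "class_sums",
    "mean_chain_length",
    "compare_fractions",
    "profile_from_percentages",
    "EmptyProfileError",
]

FRACTION_LABELS = ("Lipids", "TAG", "1,2-DAG", "1,3-DAG")


class EmptyProfileError(ValueError):
    """No detected peak with positive area/percentage."""


@dataclass(frozen=True)
class PeakRecord:
    """One FAME peak: either a raw area or a pre-normalized percentage.

    ``detected=False`` encodes an "nd" table entry and forces the value
    to zero.
    """

    fa: FattyAcidCode
    area: float | None = None
    rel_percent: float | None = None
    detected: bool = True

    def __post_init__(self) -> None:
        if self.detected:
            if (self.area is None) == (self.rel_percent is None):
                raise ValueError(
                    f"{self.fa.label}: exactly one of area/rel_percent required"
                )
            value = self.area if self.area is not None else self.rel_percent
            if value < 0:
                raise ValueError(f"{self.fa.label}: negative value {value}")


@dataclass
class FAProfile:
    """Relative-percentage fatty-acid profile of one lipid fraction."""

    fractions: dict[FattyAcidCode, float]
    sample: str = ""
    fraction: str = "Lipids"

    def __post_init__(self) -> None:
        for fa, pct in self.fractions.items():
            if pct < 0:
                raise ValueError(f"{fa.label}: negative percentage {pct}")
        total = self.total
        if total > 0 and not (95.0 <= total <= 100.5):
            warnings.warn(
                f"profile {self.label} sums to {total:.2f}%, outside [95, 100.5]",
                stacklevel=2,
            )

    @property
    def label(self) -> str:
        return f"{self.sample}:{self.fraction}" if self.sample else self.fraction

    @property
    def total(self) -> float:
        return sum(self.fractions.values())

    def get(self, label: str) -> float:
        return self.fractions.get(parse_fa_code(label), 0.0)


def normalize_areas(
    peaks: list[PeakRecord], sample: str = "", fraction: str = "Lipids"
) -> FAProfile:
    """Area normalization: rel% = 100 * area / total detected area.

    "nd" records map to 0% but are retained so downstream sums see the
    full roster of assayed fatty acids.
    """
    detected = [p for p in peaks if p.detected]
    if detected and any(p.rel_percent is not None for p in detected):
        # already-normalized table: pass percentages through
        fractions = {
            p.fa: (p.rel_percent if p.detected and p.rel_percent else 0.0)
            for p in peaks
        }
        if sum(fractions.values()) <= 0:
            raise EmptyProfileError("all peaks are nd or zero")
        return FAProfile(fractions, sample, fraction)
    total = sum(p.area for p in detected)
    if total <= 0:
        raise EmptyProfileError("all peaks are nd or zero")
    fractions = {
        p.fa: (100.0 * p.area / total if p.detected else 0.0) for p in peaks
    }
    return FAProfile(fractions, sample, fraction)


def profile_from_percentages(
    percents: dict[str, float | None], sample: str = "", fraction: str = "Lipids"
) -> FAProfile:
    """Build a profile from printed percentages; ``None`` means nd."""
    return FAProfile(
        {parse_fa_code(k): (v if v is not None else 0.0) for k, v in percents.items()},
        sample,
        fraction,
    )


@dataclass(frozen=True)
class ClassSummary:
    """Saturation-class and chain-length summary of one FA profile."""

    sfa: float
    mufa: float
    pufa: float
    ufa: float
    c16_c18: float
    c18_share: float
    mean_chain_length: float
    label: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "SFA": self.sfa,
            "MUFA": self.mufa,
            "PUFA": self.pufa,
            "UFA": self.ufa,
            "C16+C18": self.c16_c18,
            "C18": self.c18_share,
            "mean_chain_length": self.mean_chain_length,
        }


def mean_chain_length(profile: FAProfile) -> float:
    """Percentage-weighted mean carbon chain length of the profile."""
    total = profile.total
    if total <= 0:
        raise EmptyProfileError(f"profile {profile.label} is empty")
    return sum(fa.carbons * pct for fa, pct in profile.fractions.items()) / total


def class_sums(profile: FAProfile) -> ClassSummary:
    """Sum the profile into SFA/MUFA/PUFA/UFA, C16+C18, C18 classes.

    Class membership comes solely from the Cx:y code; nd entries
    contribute 0.
    """
    sfa = mufa = pufa = c16_c18 = c18 = 0.0
    for fa, pct in profile.fractions.items():
        if fa.double_bonds == 0:
            sfa += pct
        elif fa.double_bonds == 1:
            mufa += pct
        else:
            pufa += pct
        if fa.carbons in (16, 18):
            c16_c18 += pct
        if fa.carbons == 18:
            c18 += pct
    return ClassSummary(
        sfa=sfa,
        mufa=mufa,
        pufa=pufa,
        ufa=mufa + pufa,
        c16_c18=c16_c18,
        c18_share=c18,
        mean_chain_length=mean_chain_length(profile),
        label=profile.label,
    )


def compare_fractions(profiles: list[FAProfile]) -> pd.DataFrame:
    """Cross-profile extrema of every class-summary field.

    Returns a frame indexed by field with min/max values and the labels
    of the profiles attaining them.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    summaries = [class_sums(p) for p in profiles]
    rows = []
    for key in ("SFA", "MUFA", "PUFA", "UFA", "C16+C18", "C18", "mean_chain_length"):
        vals = [(s.as_dict()[key], s.label) for s in summaries]
        vmin, lmin = min(vals, key=lambda t: t[0])
        vmax, lmax = max(vals, key=lambda t: t[0])
        rows.append(
            {
                "field": key,
                "min": vmin,
                "min_label": lmin,
                "max": vmax,
                "max_label": lmax,
                "range": vmax - vmin,
            }
        )
    return pd.DataFrame(rows).set_index("field")
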