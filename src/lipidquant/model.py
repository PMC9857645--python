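"""Chemical domain model for acylglycerol quantification.

The quantification rests on three pieces of chemistry that this module
encodes:

* glyceride species (mono-, di-, triacylglycerols and free fatty acids)
  with their fixed acyl-chain counts;
* the proton-assignment table mapping chemical-shift windows of a 600 MHz
  1H spectrum to species and to the number of protons each molecule of
  that species contributes in the window — this is the design matrix of
  the stoichiometric deconvolution;
* average molecular masses of the lipid classes, referenced to an oleoyl
  (C18:1) chain, used to convert mole percentages into weight percentages.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "FattyAcidCode",
    "GlycerideSpecies",
    "ProtonAssignment",
    "AssignmentTable",
    "MolecularMasses",
    "parse_fa_code",
    "species_mass",
    "default_assignment_table",
    "DEFAULT_MASSES",
]


class LipidModelError(ValueError):
    """Invalid domain input (malformed code, inconsistent table, ...)."""


_FA_RE = re.compile(r"^\s*[Cc]\s*(\d+)\s*:\s*(\d+)\s*$")


@dataclass(frozen=True, order=True)
class FattyAcidCode:
    """A fatty acid in shorthand Cx:y notation.

    ``carbons`` is the chain length x, ``double_bonds`` the number of C=C
    bonds y.  ``C16:0`` is palmitic acid, ``C18:1`` oleic acid, etc.
    """

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if not (4 <= self.carbons <= 30):
            raise LipidModelError(
                f"chain length {self.carbons} outside the supported range 4-30"
            )
        if not (0 <= self.double_bonds <= 6):
            raise LipidModelError(
                f"double bond count {self.double_bonds} outside 0-6"
            )

    @property
    def label(self) -> str:
        return f"C{self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def parse_fa_code(label: str) -> FattyAcidCode:
    """Parse a ``Cx:y`` fatty-acid label (case/whitespace tolerant)."""
    m = _FA_RE.match(label)
    if m is None:
        raise LipidModelError(f"cannot parse fatty-acid code {label!r}")
    return FattyAcidCode(int(m.group(1)), int(m.group(2)))


class GlycerideSpecies(enum.Enum):
    """The closed set of lipid species resolved by the 1H NMR method.

    ``acyl_count`` is the number of acyl chains per molecule; the free
    fatty acid carries 1 for alpha-CH2 bookkeeping only (it has no
    glyceryl protons).
    """

    MAG_1 = ("1-MAG", 1)
    MAG_2 = ("2-MAG", 1)
    DAG_12 = ("1,2-DAG", 2)
    DAG_13 = ("1,3-DAG", 2)
    TAG = ("TAG", 3)
    FFA = ("FFA", 1)

    def __init__(self, label: str, acyl_count: int) -> None:
        self.label = label
        self.acyl_count = acyl_count

    @classmethod
    def from_label(cls, label: str) -> "GlycerideSpecies":
        for sp in cls:
            if sp.label == label:
                return sp
        raise LipidModelError(f"unknown glyceride species {label!r}")


@dataclass(frozen=True)
class ProtonAssignment:
    """One row of the proton-assignment table.

    A row says: in the chemical-shift window ``[window_lo, window_hi]``
    (ppm, closed interval), every molecule of ``species`` contributes
    ``protons_per_molecule`` protons.  Rows with ``quantify=False`` are
    observed but excluded from the deconvolution (acyl-chain envelope
    signals, undetermined peaks, phospholipid signal).
    """

    code: str
    window_lo: float
    window_hi: float
    multiplicity: str
    species: GlycerideSpecies | None
    protons_per_molecule: int
    quantify: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if not self.window_lo < self.window_hi:
            raise LipidModelError(
                f"assignment {self.code}: window_lo must be < window_hi "
                f"({self.window_lo} >= {self.window_hi})"
            )
        if self.quantify:
            if self.species is None:
                raise LipidModelError(
                    f"assignment {self.code}: quantifiable row needs a species"
                )
            if self.protons_per_molecule <= 0:
                raise LipidModelError(
                    f"assignment {self.code}: quantifiable row needs protons > 0"
                )

    @property
    def window(self) -> tuple[float, float]:
        return (self.window_lo, self.window_hi)

    @property
    def center(self) -> float:
        return 0.5 * (self.window_lo + self.window_hi)


# Window keys used throughout: the ppm bounds as printed.
W_1MAG = "3.91-3.95"
W_2MAG = "3.82-3.84"
W_12DAG = "3.72-3.74"
W_13DAG = "4.05-4.10"
W_ESTER = "4.11-4.38"
W_ALPHA = "2.28-2.38"

QUANT_WINDOW_ORDER = (W_1MAG, W_2MAG, W_12DAG, W_13DAG, W_ESTER, W_ALPHA)


def _window_key(lo: float, hi: float) -> str:
    return f"{lo:.2f}-{hi:.2f}"


@dataclass
class AssignmentTable:
    """A validated proton-assignment table.

    Exposes the quantification design: the ordered set of disjoint
    integration windows and, per window, the per-species proton counts.
    """

    rows: list[ProtonAssignment]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        windows = sorted(self.quant_windows().values())
        for (alo, ahi), (blo, bhi) in zip(windows, windows[1:]):
            if blo < ahi:  # interiors of the closed intervals intersect
                raise LipidModelError(
                    f"quantification windows [{alo},{ahi}] and "
                    f"[{blo},{bhi}] overlap"
                )

    def quant_rows(self) -> list[ProtonAssignment]:
        return [r for r in self.rows if r.quantify]

    def quant_windows(self) -> dict[str, tuple[float, float]]:
        """Ordered mapping window key -> (lo, hi) over quantifiable rows."""
        out: dict[str, tuple[float, float]] = {}
        for r in self.quant_rows():
            key = _window_key(r.window_lo, r.window_hi)
            prev = out.setdefault(key, r.window)
            if prev != r.window:  # pragma: no cover - defensive
                raise LipidModelError(f"inconsistent bounds for window {key}")
        return out

    def proton_counts(self) -> dict[str, dict[GlycerideSpecies, int]]:
        """Design matrix: window key -> {species: protons per molecule}."""
        out: dict[str, dict[GlycerideSpecies, int]] = {}
        for r in self.quant_rows():
            key = _window_key(r.window_lo, r.window_hi)
            counts = out.setdefault(key, {})
            counts[r.species] = counts.get(r.species, 0) + r.protons_per_molecule
        return out

    def to_records(self) -> list[dict]:
        return [
            {
                "code": r.code,
                "window_lo": r.window_lo,
                "window_hi": r.window_hi,
                "multiplicity": r.multiplicity,
                "species": r.species.label if r.species else None,
                "protons_per_molecule": r.protons_per_molecule,
                "quantify": r.quantify,
                "note": r.note,
            }
            for r in self.rows
        ]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "AssignmentTable":
        rows = []
        for rec in records:
            sp = rec.get("species")
            rows.append(
                ProtonAssignment(
                    code=str(rec["code"]),
                    window_lo=float(rec["window_lo"]),
                    window_hi=float(rec["window_hi"]),
                    multiplicity=str(rec.get("multiplicity", "m")),
                    species=GlycerideSpecies.from_label(sp) if sp else None,
                    protons_per_molecule=int(rec.get("protons_per_molecule", 0)),
                    quantify=bool(rec.get("quantify", True)),
                    note=str(rec.get("note", "")),
                )
            )
        return cls(rows)


def default_assignment_table() -> AssignmentTable:
    """The default 600 MHz assignment table for glyceride quantification.

    Quantifiable rows carry the six disjoint integration windows; the
    glyceryl CHOH / CH2OH signals isolate 1-MAG, 2-MAG, 1,2-DAG and
    1,3-DAG, the 4.11-4.38 ppm ester CH2OCO envelope mixes TAG with the
    partial glycerides, and the 2.28-2.38 ppm alpha-CH2 signal counts two
    protons per acyl chain of every species including free fatty acids.
    Non-quantified rows describe the remaining observed signals.
    """
    S = GlycerideSpecies
    q = [
        # glyceryl CHOH of 1-MAG (1 proton)
        ProtonAssignment("J", 3.91, 3.95, "m", S.MAG_1, 1),
        # glyceryl CH2OH of 2-MAG (two CH2OH groups, 4 protons)
        ProtonAssignment("I", 3.82, 3.84, "m", S.MAG_2, 4),
        # glyceryl CH2OH of 1,2-DAG (2 protons)
        ProtonAssignment("H", 3.72, 3.74, "m", S.DAG_12, 2),
        # glyceryl CHOH of 1,3-DAG (1 proton)
        ProtonAssignment("K", 4.05, 4.10, "m", S.DAG_13, 1),
        # ester CH2OCO envelope: TAG sn-1/sn-3 (4H), 1-MAG (2H),
        # 1,2-DAG (2H), 1,3-DAG two CH2OCO (4H)
        ProtonAssignment("M/P", 4.11, 4.38, "dd", S.TAG, 4),
        ProtonAssignment("N", 4.11, 4.38, "dd", S.MAG_1, 2),
        ProtonAssignment("O", 4.11, 4.38, "dd", S.DAG_12, 2),
        ProtonAssignment("L", 4.11, 4.38, "dd", S.DAG_13, 4),
    ]
    # alpha-CH2: 2 protons per acyl chain of every species, FFA included
    for sp in S:
        q.append(
            ProtonAssignment("E", 2.28, 2.38, "m", sp, 2 * sp.acyl_count)
        )
    cosmetic = [
        ProtonAssignment("A", 0.84, 0.92, "t", None, 0, False, "terminal CH3"),
        ProtonAssignment("B", 1.25, 1.35, "m", None, 0, False, "(CH2)n envelope"),
        ProtonAssignment("C", 1.56, 1.66, "m", None, 0, False, "beta CH2"),
        ProtonAssignment("D", 2.00, 2.04, "m", None, 0, False, "allylic CH2"),
        ProtonAssignment("F", 2.74, 2.78, "m", None, 0, False, "bis-allylic CH2"),
        ProtonAssignment("G", 3.59, 3.71, "dd", None, 0, False, "1-MAG CH2OH"),
        ProtonAssignment("Q", 5.06, 5.10, "m", None, 0, False, "1,2-DAG CH(OCOR')"),
        ProtonAssignment("R", 5.24, 5.28, "m", None, 0, False, "TAG CH(OCOR')"),
        ProtonAssignment("S", 5.30, 5.40, "m", None, 0, False, "olefinic CH=CH"),
        ProtonAssignment("T", 3.985, 3.995, "dd", None, 0, False, "undetermined"),
        ProtonAssignment("U", 3.975, 3.985, "dd", None, 0, False, "undetermined"),
        ProtonAssignment("V", 3.65, 3.69, "m", None, 0, False, "phospholipid-like"),
    ]
    return AssignmentTable(q + cosmetic)


@dataclass(frozen=True)
class MolecularMasses:
    """Average molecular masses (g/mol) of the lipid classes.

    Referenced to an oleoyl (C18:1) acyl chain throughout; the stored
    constants are the conventional rounded values and are used verbatim
    rather than recomputed from atomic weights.  ``esterification_mass``
    provides the mass-balance cross-check m_MAG + (n-1)(m_FA - m_H2O).
    """

    m_mag: float = 356.54
    m_dag: float = 620.98
    m_tag: float = 885.43
    m_fa: float = 282.46
    m_water: float = 18.02
    reference_chain: FattyAcidCode = field(
        default_factory=lambda: FattyAcidCode(18, 1)
    )

    def esterification_mass(self, acyl_count: int) -> float:
        """Mass of an n-acyl glyceride from the esterification balance."""
        if acyl_count not in (1, 2, 3):
            raise LipidModelError(f"acyl_count must be 1, 2 or 3, got {acyl_count}")
        return self.m_mag + (acyl_count - 1) * (self.m_fa - self.m_water)

    def check_balance(self, tol: float = 0.02) -> None:
        for n, stored in ((2, self.m_dag), (3, self.m_tag)):
            if abs(self.esterification_mass(n) - stored) > tol:
                raise LipidModelError(
                    f"stored {n}-acyl mass {stored} inconsistent with "
                    f"esterification balance {self.esterification_mass(n):.2f}"
                )

    def to_dict(self) -> dict:
        return {
            "m_mag": self.m_mag,
            "m_dag": self.m_dag,
            "m_tag": self.m_tag,
            "m_fa": self.m_fa,
            "m_water": self.m_water,
            "reference_chain": self.reference_chain.label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MolecularMasses":
        kwargs = {k: float(d[k]) for k in ("m_mag", "m_dag", "m_tag", "m_fa") if k in d}
        if "m_water" in d:
            kwargs["m_water"] = float(d["m_water"])
        if "reference_chain" in d:
            kwargs["reference_chain"] = parse_fa_code(d["reference_chain"])
        return cls(**kwargs)


DEFAULT_MASSES = MolecularMasses()


def species_mass(acyl_count: int, masses: MolecularMasses = DEFAULT_MASSES) -> float:
    """Average molecular mass of a glyceride with ``acyl_count`` chains.

    Returns the stored class constant (MAG, DAG or TAG); the
    esterification balance is available separately as a cross-check.
    """
    if acyl_count == 1:
        return masses.m_mag
    if acyl_count == 2:
        return masses.m_dag
    if acyl_count == 3:
        return masses.m_tag
    raise LipidModelError(f"acyl_count must be 1, 2 or 3, got {acyl_count}")
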