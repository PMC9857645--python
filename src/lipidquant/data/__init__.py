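"""Packaged reference data.

``fame_reference.csv`` transcribes the published GC-MS fatty-acid
compositions (relative %, area normalization) of crude lipids and their
TLC-separated TAG, 1,2-DAG and 1,3-DAG fractions from five DAG-producing
endophytic fungal strains (MLP41, MLG23, MLY23, MLY31W, MLGP11); "nd"
marks fatty acids not detected in a fraction.
``fame_reference_printed_sums.csv`` transcribes the class-summary rows as
printed alongside that table; a few printed cells disagree with the sums
recomputable from the FA rows (see ``printed_sum_discrepancies``).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..fame import FAProfile, profile_from_percentages

__all__ = [
    "load_reference_table",
    "load_reference_printed_sums",
    "reference_profiles",
    "printed_sum_discrepancies",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh, index_col=0)


def load_reference_table() -> pd.DataFrame:
    """The 20-column reference FA table; 'nd' cells become NaN."""
    df = _read("fame_reference.csv")
    return df.apply(pd.to_numeric, errors="coerce")


def load_reference_printed_sums() -> pd.DataFrame:
    """The printed C16+C18 / SFA / MUFA / PUFA / UFA rows, as printed."""
    return _read("fame_reference_printed_sums.csv").astype(float)


def reference_profiles() -> list[FAProfile]:
    """All 20 reference columns as FAProfile objects (nd -> 0)."""
    df = load_reference_table()
    out = []
    for col in df.columns:
        sample, fraction = col.split(" ", 1)
        percents = {
            fa: (None if pd.isna(v) else float(v)) for fa, v in df[col].items()
        }
        out.append(profile_from_percentages(percents, sample, fraction))
    return out


def printed_sum_discrepancies(tol: float = 0.02) -> pd.DataFrame:
    """Printed class-sum cells that differ from recomputation by > ``tol``.

    These are transcription/rounding errata in the printed table itself;
    the recomputed values are the authoritative ones.
    """
    from ..fame import class_sums

    printed = load_reference_printed_sums()
    rows = []
    for prof in reference_profiles():
        col = f"{prof.sample} {prof.fraction}"
        summary = class_sums(prof).as_dict()
        for fld in ("C16+C18", "SFA", "MUFA", "PUFA", "UFA"):
            recomputed = summary["C18" if fld == "C18" else fld]
            diff = recomputed - printed.loc[fld, col]
            if abs(diff) > tol:
                rows.append(
                    {
                        "column": col,
                        "field": fld,
                        "printed": printed.loc[fld, col],
                        "recomputed": recomputed,
                        "diff": diff,
                    }
                )
    return pd.DataFrame(rows, columns=["column", "field", "printed", "recomputed", "diff"])
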