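"""Readers, writers, configuration and the umbrella pipeline.

Spectra are exchanged as two-column ppm/intensity text (comma, tab or
space delimited, ``#`` comments) or as single-block JCAMP-DX files with
AFFN-encoded ``(X++(Y..Y))`` data.  Reports are written as JSON (full
precision) and CSV (two decimals, the conventional reporting precision
for percentages and mg/L yields).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fame import PeakRecord, class_sums, normalize_areas
from .model import (
    AssignmentTable,
    DEFAULT_MASSES,
    MolecularMasses,
    default_assignment_table,
    parse_fa_code,
)
from .nmr import DEFAULT_TMS_WINDOW, CompositionReport, Spectrum, quantify
from .yields import BiomassRecord, ExtractionRecord, cdw, dag_yields, lipid_yield

__all__ = [
    "SpectrumFormatError",
    "PipelineError",
    "PipelineConfig",
    "read_spectrum",
    "write_spectrum_text",
    "write_spectrum_jcamp",
    "read_fame_csv",
    "default_config_dict",
    "dump_config",
    "load_config",
    "write_composition_report",
    "run_pipeline",
]

log = logging.getLogger("lipidquant")


class SpectrumFormatError(ValueError):
    """Unparseable or structurally invalid spectrum file."""


class PipelineError(RuntimeError):
    """A pipeline stage failed for a named sample."""


# ---------------------------------------------------------------------------
# spectrum I/O


def _parse_two_column(path: Path) -> Spectrum:
    ppm: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected two columns, got {raw.strip()!r}"
                )
            try:
                ppm.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric row {raw.strip()!r}"
                ) from None
    return _build_spectrum(np.array(ppm), np.array(inten), path)


def _build_spectrum(ppm: np.ndarray, inten: np.ndarray, path: Path) -> Spectrum:
    if ppm.size != np.unique(ppm).size:
        raise SpectrumFormatError(f"{path}: duplicate ppm values")
    try:
        return Spectrum(ppm, inten)
    except ValueError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc


def _parse_jcamp(path: Path) -> Spectrum:
    """Minimal JCAMP-DX reader: one XYDATA=(X++(Y..Y)) block, AFFN only."""
    headers: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XYDATA":
                    if "(X++(Y..Y))" not in value.replace(" ", ""):
                        raise SpectrumFormatError(
                            f"{path}:{lineno}: only (X++(Y..Y)) XYDATA supported"
                        )
                    in_data = True
                    continue
                if key == "END":
                    in_data = False
                    continue
                headers[key] = value
                continue
            if in_data:
                tokens = line.replace(",", " ").split()
                try:
                    vals = [float(t) for t in tokens]
                except ValueError:
                    raise SpectrumFormatError(
                        f"{path}:{lineno}: non-AFFN token in XYDATA: {line!r}"
                    ) from None
                # first token is the line's abscissa check value
                ys.extend(vals[1:])
    try:
        firstx = float(headers["FIRSTX"])
        lastx = float(headers["LASTX"])
        npoints = int(float(headers["NPOINTS"]))
    except KeyError as exc:
        raise SpectrumFormatError(f"{path}: missing JCAMP header ##{exc.args[0]}=")
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    if len(ys) != npoints:
        raise SpectrumFormatError(
            f"{path}: NPOINTS={npoints} but {len(ys)} ordinates read"
        )
    x = np.linspace(firstx, lastx, npoints) * xfactor
    y = np.array(ys) * yfactor
    return _build_spectrum(x, y, path)


def read_spectrum(path: str | Path, dialect: str = "auto") -> Spectrum:
    """Read a spectrum file (``two-column``, ``jcamp`` or ``auto``)."""
    path = Path(path)
    if dialect == "auto":
        with open(path) as fh:
            head = fh.read(2)
        dialect = "jcamp" if head == "##" else "two-column"
    if dialect == "two-column":
        return _parse_two_column(path)
    if dialect == "jcamp":
        return _parse_jcamp(path)
    raise ValueError(f"unknown spectrum dialect {dialect!r}")


def write_spectrum_text(path: str | Path, spec: Spectrum) -> None:
    """Write two-column ppm/intensity text at full float precision."""
    with open(path, "w") as fh:
        fh.write("# ppm intensity\n")
        for p, v in zip(spec.ppm.tolist(), spec.intensity.tolist()):
            fh.write(f"{p!r} {v!r}\n")


def write_spectrum_jcamp(path: str | Path, spec: Spectrum, title: str = "") -> None:
    """Write a single-block AFFN JCAMP-DX file (X++(Y..Y), factors 1)."""
    n = spec.ppm.size
    with open(path, "w") as fh:
        fh.write(f"##TITLE={title}\n##JCAMP-DX=4.24\n##DATA TYPE=NMR SPECTRUM\n")
        fh.write("##XUNITS=PPM\n##YUNITS=ARBITRARY UNITS\n")
        fh.write(f"##FIRSTX={float(spec.ppm[0])!r}\n##LASTX={float(spec.ppm[-1])!r}\n")
        fh.write(f"##NPOINTS={n}\n##XFACTOR=1\n##YFACTOR=1\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        per_line = 4
        xs = spec.ppm.tolist()
        ivals = spec.intensity.tolist()
        for i in range(0, n, per_line):
            ys = " ".join(repr(v) for v in ivals[i : i + per_line])
            fh.write(f"{xs[i]!r} {ys}\n")
        fh.write("##END=\n")


# ---------------------------------------------------------------------------
# FAME table I/O


def read_fame_csv(path: str | Path) -> list[PeakRecord]:
    """Read a FAME peak table CSV with columns ``fa,area`` or
    ``fa,rel_percent``; the value ``nd`` marks undetected fatty acids."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "fa" not in cols or not ({"area", "rel_percent"} & set(cols)):
        raise ValueError(
            f"{path}: need columns 'fa' and one of 'area'/'rel_percent'"
        )
    value_col = "area" if "area" in cols else "rel_percent"
    records = []
    for _, row in df.iterrows():
        fa = parse_fa_code(row["fa"])
        raw = str(row[value_col]).strip().lower()
        if raw in ("nd", "", "nan"):
            records.append(PeakRecord(fa, area=0.0, detected=False))
        else:
            records.append(PeakRecord(fa, **{value_col: float(raw)}))
    return records


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Validated pipeline settings with embedded defaults."""

    table: AssignmentTable = field(default_factory=default_assignment_table)
    masses: MolecularMasses = DEFAULT_MASSES
    tms_window: tuple[float, float] = DEFAULT_TMS_WINDOW
    baseline: str = "none"
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "assignments": self.table.to_records(),
            "masses": self.masses.to_dict(),
            "tms_window": list(self.tms_window),
            "baseline": self.baseline,
            "verbosity": self.verbosity,
        }


def default_config_dict() -> dict:
    return PipelineConfig().to_dict()


def dump_config(config: PipelineConfig | None = None) -> str:
    """Byte-stable YAML dump of the (default) configuration."""
    cfg = config or PipelineConfig()
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True, default_flow_style=False)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML/JSON config; omitted keys keep their defaults.

    Overrides are validated against the domain invariants (window
    disjointness, mass balance) at load time.
    """
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    if "assignments" in raw:
        cfg.table = AssignmentTable.from_records(raw["assignments"])
    if "masses" in raw:
        cfg.masses = MolecularMasses.from_dict(raw["masses"])
        cfg.masses.check_balance()
    if "tms_window" in raw:
        lo, hi = (float(v) for v in raw["tms_window"])
        cfg.tms_window = (lo, hi)
    if "baseline" in raw:
        if raw["baseline"] not in ("none", "linear"):
            raise ValueError(f"unknown baseline mode {raw['baseline']!r}")
        cfg.baseline = raw["baseline"]
    if "verbosity" in raw:
        cfg.verbosity = str(raw["verbosity"])
    return cfg


# ---------------------------------------------------------------------------
# report writers


def _round2(d: dict[str, float]) -> dict[str, float]:
    return {k: round(v, 2) for k, v in d.items()}


def write_composition_report(
    report: CompositionReport, out_prefix: str | Path
) -> None:
    """Write a composition report as JSON (full precision) and CSV (2 dp)."""
    out_prefix = Path(out_prefix)
    with open(out_prefix.with_suffix(".json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    rows = [
        {"class": k, "mole_percent": f"{report.mole_percent[k]:.2f}",
         "weight_percent": f"{report.weight_percent[k]:.2f}"}
        for k in ("MAG", "1,2-DAG", "1,3-DAG", "DAG", "TAG", "FA")
    ]
    pd.DataFrame(rows).to_csv(out_prefix.with_suffix(".csv"), index=False)


# ---------------------------------------------------------------------------
# umbrella pipeline


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run quantification, FAME summary and yield arithmetic per sample.

    ``input_dir`` follows the batch-fixture layout: ``fermentation.csv``
    (sample,m1_g,volume_L,m3_g,m4_g), ``spectra/<sample>.txt`` (or .jdx)
    and optional ``fame/<sample>.csv``.  Writes per-sample reports plus
    ``yields.csv``, ``fame_summary.csv`` and ``run_manifest.json`` to
    ``out_dir`` and returns everything as a dict.
    """
    cfg = config or PipelineConfig()
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ferm_path = input_dir / "fermentation.csv"
    if not ferm_path.exists():
        raise PipelineError(f"missing fermentation records: {ferm_path}")
    ferm = pd.read_csv(ferm_path)

    results: dict = {}
    yield_rows = []
    fame_rows = []
    for _, row in ferm.iterrows():
        sample = str(row["sample"])
        spec_path = None
        for ext in (".txt", ".csv", ".jdx", ".dx"):
            cand = input_dir / "spectra" / f"{sample}{ext}"
            if cand.exists():
                spec_path = cand
                break
        if spec_path is None:
            raise PipelineError(
                f"sample {sample}: no spectrum file under {input_dir / 'spectra'}"
            )
        log.info("quantifying sample %s from %s", sample, spec_path)
        spec = read_spectrum(spec_path)
        report = quantify(
            spec,
            table=cfg.table,
            masses=cfg.masses,
            baseline=cfg.baseline,
            tms_window=cfg.tms_window,
        )
        write_composition_report(report, out_dir / f"{sample}_composition")

        c = cdw(BiomassRecord(m1=float(row["m1_g"]), v=float(row["volume_L"])))
        ly = lipid_yield(
            ExtractionRecord(cdw=c, m3=float(row["m3_g"]), m4=float(row["m4_g"]))
        )
        y12, y13, ytot = dag_yields(
            ly, report.weight_percent["1,2-DAG"], report.weight_percent["1,3-DAG"]
        )
        yield_rows.append(
            {
                "sample": sample,
                "cdw_g_per_L": f"{c:.2f}",
                "lipid_yield_g_per_L": f"{ly:.2f}",
                "dag12_yield_mg_per_L": f"{y12:.2f}",
                "dag13_yield_mg_per_L": f"{y13:.2f}",
                "dag_total_yield_mg_per_L": f"{ytot:.2f}",
            }
        )

        fame_path = input_dir / "fame" / f"{sample}.csv"
        summary = None
        if fame_path.exists():
            profile = normalize_areas(read_fame_csv(fame_path), sample=sample)
            summary = class_sums(profile)
            fame_rows.append(
                {"sample": sample, **{k: f"{v:.2f}" for k, v in summary.as_dict().items()}}
            )

        results[sample] = {
            "composition": report,
            "fame_summary": summary,
            "yields": {
                "cdw_g_per_L": c,
                "lipid_yield_g_per_L": ly,
                "dag12_yield_mg_per_L": y12,
                "dag13_yield_mg_per_L": y13,
                "dag_total_yield_mg_per_L": ytot,
            },
        }

    pd.DataFrame(yield_rows).to_csv(out_dir / "yields.csv", index=False)
    if fame_rows:
        pd.DataFrame(fame_rows).to_csv(out_dir / "fame_summary.csv", index=False)

    cfg_yaml = dump_config(cfg)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "samples": sorted(results),
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def setup_logging(verbosity: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, verbosity.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
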