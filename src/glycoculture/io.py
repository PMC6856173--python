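"""Readers and writers for the package's file formats.

Delimited tables (CSV/TSV, delimiter auto-detected) carry glycopeptide
identifications, culture time courses and droplet assays; MGF carries MS2
peak lists for oxonium-ion checks; reports round-trip through either a
human-oriented table (rounded display precision) or a loss-less structured
JSON document.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import pandas as pd
from pyteomics import mgf as _mgf

from .bioprocess import CultureTimeSeries
from .composition import (
    CompositionError,
    MonosaccharideCounts,
    format_composition,
    parse_composition,
)
from .ddpcr import DropletAssay
from .quant import (
    AggregateMetrics,
    AntennaPercentages,
    GlycoReport,
    GlycopeptideRecord,
    SiteGlycoProfile,
)

__all__ = [
    "TableError",
    "GLYCO_COLUMNS",
    "read_glycopeptide_table",
    "write_glycopeptide_table",
    "read_culture_table",
    "read_droplet_table",
    "read_mgf",
    "write_report",
    "read_report",
    "report_to_frame",
]

REPORT_SCHEMA_VERSION = 1

#: canonical column names of a glycopeptide table
GLYCO_COLUMNS = (
    "site",
    "site_kind",
    "peptide",
    "missed_cleavages",
    "composition",
    "abundance",
)


class TableError(ValueError):
    """A delimited input table is malformed; messages cite row numbers."""


def _read_table(path, delimiter: str | None) -> pd.DataFrame:
    # sep=None lets pandas sniff comma vs tab
    return pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")


def read_glycopeptide_table(
    path,
    column_map: dict[str, str] | None = None,
    aliases: bool = True,
    delimiter: str | None = None,
) -> list[GlycopeptideRecord]:
    """Read a glycopeptide identification table into records.

    Required columns (after applying ``column_map``, a mapping from file
    column names to canonical ones): site, site_kind, peptide,
    missed_cleavages, composition, abundance.  A blank composition cell
    marks the unglycosylated peptide.
    """
    frame = _read_table(path, delimiter)
    if column_map:
        frame = frame.rename(columns=column_map)
    missing = [c for c in GLYCO_COLUMNS if c not in frame.columns]
    if missing:
        raise TableError(f"missing column(s): {', '.join(missing)}")
    records = []
    for idx, row in frame.iterrows():
        rownum = idx + 2  # 1-based, after the header line
        raw_comp = row["composition"]
        blank = pd.isna(raw_comp) or not str(raw_comp).strip()
        try:
            comp = None if blank else parse_composition(str(raw_comp), aliases=aliases)
        except CompositionError as exc:
            raise TableError(f"row {rownum}: {exc}") from exc
        abundance = float(row["abundance"])
        if not abundance >= 0:
            raise TableError(f"row {rownum}: negative abundance {abundance}")
        records.append(
            GlycopeptideRecord(
                site=str(row["site"]),
                site_kind=str(row["site_kind"]).strip().upper(),
                peptide=str(row["peptide"]),
                missed_cleavages=int(row["missed_cleavages"]),
                composition=comp,
                abundance=abundance,
            )
        )
    return records


def write_glycopeptide_table(
    records: list[GlycopeptideRecord], path, delimiter: str = ","
) -> None:
    """Write records in the same layout :func:`read_glycopeptide_table`
    consumes."""
    rows = [
        {
            "site": r.site,
            "site_kind": r.site_kind,
            "peptide": r.peptide,
            "missed_cleavages": r.missed_cleavages,
            "composition": "" if r.composition is None else format_composition(r.composition),
            "abundance": repr(r.abundance),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(GLYCO_COLUMNS)).to_csv(
        path, sep=delimiter, index=False
    )


def read_culture_table(path, delimiter: str | None = None) -> CultureTimeSeries:
    """Read a culture time course: columns time_h, vcd, optional
    viability_pct and titer; remaining numeric columns become metabolite
    series."""
    frame = _read_table(path, delimiter)
    for col in ("time_h", "vcd"):
        if col not in frame.columns:
            raise TableError(f"missing column(s): {col}")
    known = {"time_h", "vcd", "viability_pct", "titer"}
    metabolites = {
        col: frame[col].to_numpy(dtype=float)
        for col in frame.columns
        if col not in known
    }
    return CultureTimeSeries(
        t=frame["time_h"].to_numpy(dtype=float),
        vcd=frame["vcd"].to_numpy(dtype=float),
        titer=frame["titer"].to_numpy(dtype=float) if "titer" in frame else None,
        viability=frame["viability_pct"].to_numpy(dtype=float)
        if "viability_pct" in frame
        else None,
        metabolites=metabolites,
    )


def read_droplet_table(path, delimiter: str | None = None) -> dict[str, DropletAssay]:
    """Read droplet assays, one per row: columns well, target,
    droplets_total, droplets_positive, input_ng.  Keyed by target name."""
    frame = _read_table(path, delimiter)
    required = ("target", "droplets_total", "droplets_positive", "input_ng")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableError(f"missing column(s): {', '.join(missing)}")
    assays = {}
    for idx, row in frame.iterrows():
        assays[str(row["target"])] = DropletAssay(
            droplets_total=int(row["droplets_total"]),
            droplets_positive=int(row["droplets_positive"]),
            input_mass_ng=float(row["input_ng"]),
        )
    return assays


def read_mgf(path) -> dict[str, list[tuple[float, float]]]:
    """Read an MGF peak-list file into {spectrum title: [(m/z, intensity)]}.

    Raises ``TableError`` on unbalanced BEGIN/END IONS blocks or
    non-numeric peak lines.
    """
    text = Path(path).read_text()
    begins = text.count("BEGIN IONS")
    ends = text.count("END IONS")
    if begins != ends:
        raise TableError(
            f"truncated MGF: {begins} BEGIN IONS but {ends} END IONS"
        )
    spectra: dict[str, list[tuple[float, float]]] = {}
    try:
        with _mgf.MGF(str(path)) as reader:
            for i, spectrum in enumerate(reader):
                title = spectrum["params"].get("title", f"spectrum_{i}")
                peaks = list(
                    zip(
                        (float(x) for x in spectrum["m/z array"]),
                        (float(x) for x in spectrum["intensity array"]),
                    )
                )
                spectra[title] = peaks
    except Exception as exc:  # pyteomics raises various parse errors
        raise TableError(f"malformed MGF {path}: {exc}") from exc
    return spectra


# ---------------------------------------------------------------------------
# report serialization


def _round(x: float | None, ndigits: int) -> float | None:
    return None if x is None else round(x, ndigits)


def report_to_frame(
    report: GlycoReport, ratio_dp: int = 4, pct_dp: int = 2
) -> pd.DataFrame:
    """Report as a display table: one row per site plus total-N and overall
    rows; mole ratios at 4 decimals, percentages at 2 (display only)."""

    def antenna_str(a: AntennaPercentages | None) -> str:
        if a is None:
            return "n/a"
        return f"{a.bi:.{pct_dp}f}/{a.tri:.{pct_dp}f}/{a.tetra:.{pct_dp}f}"

    rows = []
    for p in report.profiles:
        rows.append(
            {
                "site": f"{p.site} {p.site_kind}-glycan",
                "mol_core_fuc": _round(p.mol_core_fuc, ratio_dp),
                "mol_neuac": round(p.mol_neuac, ratio_dp),
                "antennae_bi_tri_tetra_pct": antenna_str(p.antenna_pct),
                "occupancy_pct": round(p.occupancy_pct, pct_dp),
            }
        )
    rows.append(
        {
            "site": "Total N-glycosylation",
            "mol_core_fuc": _round(report.total_n.mol_core_fuc, ratio_dp),
            "mol_neuac": round(report.total_n.mol_neuac, ratio_dp),
            "antennae_bi_tri_tetra_pct": antenna_str(report.total_n.antenna_pct),
            "occupancy_pct": round(report.total_n.occupancy_pct, pct_dp),
        }
    )
    rows.append(
        {
            "site": "Overall glycosylation",
            "mol_core_fuc": None,
            "mol_neuac": round(report.overall.mol_neuac, ratio_dp),
            "antennae_bi_tri_tetra_pct": "n/a",
            "occupancy_pct": round(report.overall.occupancy_pct, pct_dp),
        }
    )
    return pd.DataFrame(rows)


def _antenna_dict(a: AntennaPercentages | None):
    return None if a is None else dataclasses.asdict(a)


def _profile_dict(p: SiteGlycoProfile) -> dict:
    return {
        "site": p.site,
        "site_kind": p.site_kind,
        "fractions": [
            {
                "composition": None if comp is None else format_composition(comp),
                "fraction": frac,
            }
            for comp, frac in sorted(
                p.fractions.items(),
                key=lambda kv: "" if kv[0] is None else format_composition(kv[0]),
            )
        ],
        "occupancy_pct": p.occupancy_pct,
        "mol_neuac": p.mol_neuac,
        "mol_total_fuc": p.mol_total_fuc,
        "mol_core_fuc": p.mol_core_fuc,
        "antenna_pct": _antenna_dict(p.antenna_pct),
    }


def write_report(report: GlycoReport, path, fmt: str = "structured") -> None:
    """Write a report: ``structured`` (loss-less JSON, versioned schema) or
    ``table`` (Table-style CSV at display precision)."""
    path = Path(path)
    if fmt == "table":
        report_to_frame(report).to_csv(path, index=False)
        return
    if fmt != "structured":
        raise ValueError(f"unknown report format {fmt!r}")
    doc = {
        "schema": "glycoculture/report",
        "version": REPORT_SCHEMA_VERSION,
        "profiles": [_profile_dict(p) for p in report.profiles],
        "total_n": dataclasses.asdict(report.total_n),
        "overall": dataclasses.asdict(report.overall),
    }
    path.write_text(json.dumps(doc, indent=2))


def _antenna_from(d) -> AntennaPercentages | None:
    return None if d is None else AntennaPercentages(**d)


def read_report(path) -> GlycoReport:
    """Read a structured report back; inverse of
    ``write_report(fmt='structured')`` at full precision."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "glycoculture/report":
        raise TableError(f"not a report document: {path}")
    profiles = []
    for p in doc["profiles"]:
        fractions = {
            (None if e["composition"] is None else parse_composition(e["composition"])):
            e["fraction"]
            for e in p["fractions"]
        }
        profiles.append(
            SiteGlycoProfile(
                site=p["site"],
                site_kind=p["site_kind"],
                fractions=fractions,
                occupancy_pct=p["occupancy_pct"],
                mol_neuac=p["mol_neuac"],
                mol_total_fuc=p["mol_total_fuc"],
                mol_core_fuc=p["mol_core_fuc"],
                antenna_pct=_antenna_from(p["antenna_pct"]),
            )
        )
    total_n = doc["total_n"]
    overall = doc["overall"]
    return GlycoReport(
        profiles=tuple(profiles),
        total_n=AggregateMetrics(
            occupancy_pct=total_n["occupancy_pct"],
            mol_neuac=total_n["mol_neuac"],
            mol_core_fuc=total_n["mol_core_fuc"],
            mol_total_fuc=total_n["mol_total_fuc"],
            antenna_pct=_antenna_from(total_n["antenna_pct"]),
        ),
        overall=AggregateMetrics(
            occupancy_pct=overall["occupancy_pct"],
            mol_neuac=overall["mol_neuac"],
            mol_core_fuc=overall["mol_core_fuc"],
            mol_total_fuc=overall["mol_total_fuc"],
            antenna_pct=_antenna_from(overall["antenna_pct"]),
        ),
    )
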