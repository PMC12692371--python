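"""Delimited-text readers/writers for peak tables, gel lanes, subject
tables and genotype calls, plus YAML config handling.

File schemas (CSV, one record per row):

* ``peaks.csv``    — sample_id, assay (STR|TP), dye, size_bp, height
* ``gel.csv``      — sample_id, band_size_bp, intensity
* ``subjects.csv`` — subject_id, status (case|control), sex, age,
  allele1_repeats, allele2_repeats, snp_genotype (TT|GT|GG)
* ``genotypes.csv``— sample_id, genotype_class, allele1_repeats,
  allele2_repeats, allele1_censored, allele2_censored, needs_sequencing,
  status, warnings

Schema violations are reported with the offending row numbers instead of a
bare pandas traceback.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .peaks import Assay, GelLane, Peak, PeakTable
from .simulate import AssayData, Subject
from .workflow import WorkflowResult

__all__ = [
    "SchemaError",
    "read_peak_tables",
    "write_peak_tables",
    "read_gel_lanes",
    "write_gel_lanes",
    "read_subjects",
    "write_subjects",
    "write_genotypes",
    "read_yaml",
    "write_yaml",
]


class SchemaError(ValueError):
    """An input file does not match its documented schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _bad_rows(mask: pd.Series) -> list[int]:
    # +2: header line plus 1-based numbering
    return [int(i) + 2 for i in mask[mask].index[:10]]


def read_peak_tables(path: str | Path) -> dict[tuple[str, Assay], PeakTable]:
    """Read a long-form peak file into one PeakTable per sample x assay."""
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "assay", "size_bp", "height"], path)
    if "dye" not in df.columns:
        df["dye"] = "FAM"
    bad = ~df["assay"].isin([a.value for a in Assay])
    if bad.any():
        raise SchemaError(f"{path}: unknown assay at row(s) {_bad_rows(bad)}")
    for col in ("size_bp", "height"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) if col == "height" else vals.isna() | (vals <= 0)
        if bad.any():
            raise SchemaError(f"{path}: invalid {col} at row(s) {_bad_rows(bad)}")
        df[col] = vals
    tables: dict[tuple[str, Assay], PeakTable] = {}
    for (sid, assay), grp in df.groupby(["sample_id", "assay"], sort=False):
        peaks = [Peak(r.size_bp, r.height) for r in grp.itertuples()]
        tables[(str(sid), Assay(assay))] = PeakTable(
            sample_id=str(sid), assay=Assay(assay), peaks=peaks,
            dye=str(grp["dye"].iloc[0]),
        )
    return tables


def write_peak_tables(cohort: list[AssayData], path: str | Path) -> None:
    rows = []
    for data in cohort:
        for table in (data.str_table, data.tp_table):
            for p in table.peaks:
                rows.append((table.sample_id, table.assay.value, table.dye,
                             round(p.size_bp, 3), round(p.height, 2)))
    pd.DataFrame(
        rows, columns=["sample_id", "assay", "dye", "size_bp", "height"]
    ).to_csv(path, index=False)


def read_gel_lanes(path: str | Path) -> dict[str, GelLane]:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "band_size_bp", "intensity"], path)
    sizes = pd.to_numeric(df["band_size_bp"], errors="coerce")
    bad = sizes.isna() | (sizes <= 0)
    if bad.any():
        raise SchemaError(f"{path}: invalid band_size_bp at row(s) {_bad_rows(bad)}")
    lanes: dict[str, GelLane] = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        lanes[str(sid)] = GelLane(
            sample_id=str(sid),
            bands=[(float(r.band_size_bp), float(r.intensity)) for r in grp.itertuples()],
        )
    return lanes


def write_gel_lanes(cohort: list[AssayData], path: str | Path) -> None:
    rows = [
        (d.subject_id, round(s, 1), round(h, 2))
        for d in cohort
        for s, h in d.gel_lane.bands
    ]
    pd.DataFrame(rows, columns=["sample_id", "band_size_bp", "intensity"]).to_csv(
        path, index=False
    )


_SUBJECT_COLS = [
    "subject_id", "status", "sex", "age",
    "allele1_repeats", "allele2_repeats", "snp_genotype",
]


def read_subjects(path: str | Path) -> list[Subject]:
    df = pd.read_csv(path)
    _require_columns(df, _SUBJECT_COLS, path)
    bad = ~df["status"].isin(["case", "control"])
    if bad.any():
        raise SchemaError(f"{path}: status must be case|control at row(s) {_bad_rows(bad)}")
    bad = ~df["snp_genotype"].isin(["TT", "GT", "GG"])
    if bad.any():
        raise SchemaError(f"{path}: bad snp_genotype at row(s) {_bad_rows(bad)}")
    return [
        Subject(
            subject_id=str(r.subject_id),
            status=str(r.status),
            sex=str(r.sex),
            age=int(r.age),
            expansion_repeats=(int(r.allele1_repeats), int(r.allele2_repeats)),
            snp_genotype=str(r.snp_genotype),
        )
        for r in df.itertuples()
    ]


def write_subjects(subjects: list[Subject], path: str | Path) -> None:
    rows = [
        (s.subject_id, s.status, s.sex, s.age,
         s.expansion_repeats[0], s.expansion_repeats[1], s.snp_genotype)
        for s in subjects
    ]
    pd.DataFrame(rows, columns=_SUBJECT_COLS).to_csv(path, index=False)


def write_genotypes(results: list[WorkflowResult], path: str | Path) -> None:
    rows = []
    for r in results:
        g = r.genotype
        a1 = g.allele1 if g else None
        a2 = g.allele2 if g else None
        rows.append({
            "sample_id": r.sample_id,
            "genotype_class": g.genotype_class.value if g else "",
            "allele1_repeats": a1.repeat_count if a1 else "",
            "allele2_repeats": a2.repeat_count if a2 else "",
            "allele1_censored": bool(a1.censored) if a1 else "",
            "allele2_censored": bool(a2.censored) if a2 else "",
            "needs_sequencing": g.needs_sequencing if g else "",
            "status": r.status,
            "cost_units": r.cost_units,
            "warnings": "; ".join((g.warnings if g else []) + r.notes),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_yaml(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def write_yaml(obj: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
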