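"""Cohort-table input/output.

The cohort file is a UTF-8 comma-delimited table, one row per patient.
Header matching is order-free and case-insensitive. Required columns:

    id, age, sex, genotype, cg17330251_1 .. cg17330251_12,
    neut, lymph, mono, plt, pct

plus either the raw visit components

    tjc28_baseline, sjc28_baseline, esr_baseline, vas_baseline,
    tjc28_month6,   sjc28_month6,   esr_month6,   vas_month6

or precomputed scores ``das28_baseline, das28_month6`` (both pairs may
be present; raw components take precedence downstream).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .clinical import ClinicalVisit
from .simulate import CPG_IDS, PatientRecord

_VISIT_COLS = [
    f"{part}_{visit}"
    for visit in ("baseline", "month6")
    for part in ("tjc28", "sjc28", "esr", "vas")
]
_DAS28_COLS = ["das28_baseline", "das28_month6"]
REQUIRED_COLS = (
    ["id", "age", "sex", "genotype"]
    + list(CPG_IDS)
    + ["neut", "lymph", "mono", "plt", "pct"]
)
ALL_COLS = REQUIRED_COLS + _VISIT_COLS + _DAS28_COLS

_SEX_ALIASES = {"female": "female", "f": "female", "male": "male", "m": "male"}


def _cell_error(row: int, col: str, msg: str) -> ValueError:
    return ValueError(f"row {row}, column {col!r}: {msg}")


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort table into typed patient records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    has_visits = all(c in df.columns for c in _VISIT_COLS)
    has_das28 = all(c in df.columns for c in _DAS28_COLS)
    if not has_visits and not has_das28:
        raise ValueError(
            "need either the eight visit component columns "
            f"{_VISIT_COLS} or precomputed {_DAS28_COLS}"
        )
    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based with header line
        genotype = str(row["genotype"]).strip().upper()
        if genotype not in ("CC", "CT", "TT"):
            raise _cell_error(rownum, "genotype", f"invalid genotype {row['genotype']!r}")
        sex_raw = str(row["sex"]).strip().lower()
        if sex_raw not in _SEX_ALIASES:
            raise _cell_error(rownum, "sex", f"invalid sex {row['sex']!r}")
        meth = []
        for cpg in CPG_IDS:
            v = float(row[cpg])
            if math.isfinite(v) and not 0.0 <= v <= 1.0:
                raise _cell_error(rownum, cpg, f"methylation {v} outside [0, 1]")
            meth.append(v)
        visits: dict[str, Optional[ClinicalVisit]] = {"baseline": None, "month6": None}
        if has_visits:
            for visit in ("baseline", "month6"):
                try:
                    visits[visit] = ClinicalVisit(
                        tjc28=int(row[f"tjc28_{visit}"]),
                        sjc28=int(row[f"sjc28_{visit}"]),
                        esr=float(row[f"esr_{visit}"]),
                        vas=float(row[f"vas_{visit}"]),
                    )
                except ValueError as exc:
                    raise _cell_error(rownum, f"*_{visit}", str(exc)) from exc
        das28_pair = {}
        for col in _DAS28_COLS:
            val = float(row[col]) if col in df.columns and pd.notna(row[col]) else None
            das28_pair[col] = val
        try:
            records.append(
                PatientRecord(
                    id=str(row["id"]),
                    age=float(row["age"]),
                    sex=_SEX_ALIASES[sex_raw],
                    genotype=genotype,
                    methylation=meth,
                    baseline=visits["baseline"],
                    month6=visits["month6"],
                    neut=float(row["neut"]),
                    lymph=float(row["lymph"]),
                    mono=float(row["mono"]),
                    plt=float(row["plt"]),
                    pct=float(row["pct"]),
                    das28_baseline=das28_pair["das28_baseline"],
                    das28_month6=das28_pair["das28_month6"],
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
    return records


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into the cohort-table schema."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "id": r.id, "age": r.age, "sex": r.sex, "genotype": r.genotype,
        }
        for cpg, v in zip(CPG_IDS, r.methylation):
            row[cpg] = v
        for visit_name, visit in (("baseline", r.baseline), ("month6", r.month6)):
            if visit is not None:
                row[f"tjc28_{visit_name}"] = visit.tjc28
                row[f"sjc28_{visit_name}"] = visit.sjc28
                row[f"esr_{visit_name}"] = visit.esr
                row[f"vas_{visit_name}"] = visit.vas
        if r.das28_baseline is not None:
            row["das28_baseline"] = r.das28_baseline
        if r.das28_month6 is not None:
            row["das28_month6"] = r.das28_month6
        row.update(neut=r.neut, lymph=r.lymph, mono=r.mono, plt=r.plt, pct=r.pct)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write patient records as a comma-delimited cohort table."""
    cohort_to_frame(records).to_csv(path, index=False)
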