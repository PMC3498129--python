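"""CSV input/output for sample tables and interpretation reports."""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .context import ProteinStatus, SampleContext
from .pipeline import IdentificationReport
from .reconcile import summarize
from .refdata import GUMS
from .sugars import DIALECTS, SUGARS, SugarProfile

__all__ = ["SampleRow", "read_samples", "write_report", "SampleTableError"]


class SampleTableError(ValueError):
    """Malformed sample table, with row/column in the message."""


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    profile: SugarProfile
    context: SampleContext


_BOOL = {"1": True, "true": True, "yes": True,
         "0": False, "false": False, "no": False}


def _parse_float(cell: str, row_no: int, col: str) -> float | None:
    cell = cell.strip()
    if cell in ("", "-"):
        return None
    try:
        return float(cell.replace(",", ""))
    except ValueError:
        raise SampleTableError(
            f"row {row_no}, column {col!r}: cannot parse number {cell!r}"
        ) from None


def read_samples(path: str | Path) -> list[SampleRow]:
    """Read a sample table: one row per sample, sugar columns in relative %.

    "-" or an empty cell means *not recorded* (missing), not zero.
    Context columns (protein_analysed, protein_detected, protein_sources,
    support, dyes, fungal, plausible_gums) are optional and default to an
    uninformative context.
    """
    rows: list[SampleRow] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise SampleTableError("header must contain sample_id")
        for row_no, row in enumerate(reader, start=2):
            sid = (row.get("sample_id") or "").strip()
            if not sid:
                raise SampleTableError(f"row {row_no}: empty sample_id")
            if sid in seen:
                raise SampleTableError(f"duplicate sample_id {sid!r}")
            seen.add(sid)
            dialect_name = (row.get("dialect") or "DCCI").strip()
            if dialect_name not in DIALECTS:
                raise SampleTableError(
                    f"row {row_no}: unknown dialect {dialect_name!r}"
                )
            dialect = DIALECTS[dialect_name]
            values: dict[str, float] = {}
            missing: set[str] = set()
            for s in dialect.quantified_sugars:
                v = _parse_float(row.get(s, ""), row_no, s)
                if v is None:
                    missing.add(s)
                else:
                    values[s] = v
            if not values or sum(values.values()) <= 0:
                raise SampleTableError(
                    f"row {row_no} ({sid}): empty chromatogram"
                )
            total = _parse_float(row.get("total_sugar", ""), row_no, "total_sugar")
            profile = SugarProfile(
                values, dialect=dialect, total_sugar=total,
                missing=frozenset(missing),
            )
            analysed = _BOOL.get((row.get("protein_analysed") or "no").lower())
            detected_cell = (row.get("protein_detected") or "").strip().lower()
            detected = _BOOL.get(detected_cell) if analysed else None
            sources = frozenset(
                s for s in (row.get("protein_sources") or "").split(";") if s
            )
            gums_cell = (row.get("plausible_gums") or "all").strip()
            context = SampleContext(
                protein=ProteinStatus(
                    analysed=bool(analysed),
                    detected=detected,
                    sources=sources,
                ),
                support=(row.get("support") or "none").strip() or "none",
                dyes=frozenset(
                    d for d in (row.get("dyes") or "").split(";") if d
                ),
                fungal_growth=_BOOL.get(
                    (row.get("fungal") or "no").lower(), False
                ),
                plausible_gums=(
                    frozenset(GUMS)
                    if gums_cell == "all"
                    else frozenset(g for g in gums_cell.split(";") if g)
                ),
            )
            rows.append(SampleRow(sid, profile, context))
    return rows


def _report_rows(
    ids: Sequence[str], reports: Sequence[IdentificationReport]
) -> list[dict[str, object]]:
    out = []
    for sid, rep in zip(ids, reports):
        matches = {}
        if rep.match_result is not None:
            for gm in rep.match_result.per_gum:
                matches[gm.gum] = (
                    None if gm.correlation != gm.correlation  # NaN
                    else gm.correlation
                )
        out.append(
            {
                "sample_id": sid,
                **{s: rep.profile.get(s) for s in SUGARS
                   if s in rep.profile.recorded_sugars},
                "scheme": rep.scheme,
                "verdict": rep.scheme_result.verdict,
                "final_call": rep.final_call,
                "category": rep.interpretation.category,
                "correlations": matches,
                "evidence": list(rep.interpretation.evidence),
            }
        )
    return out


def write_report(
    ids: Sequence[str],
    reports: Sequence[IdentificationReport],
    path: str | Path,
    fmt: str = "csv",
) -> None:
    """Write per-sample interpretations plus the category summary footer."""
    if not reports:
        raise ValueError("nothing to report")
    rows = _report_rows(ids, reports)
    pct = summarize([r.interpretation for r in reports])
    path = Path(path)
    if fmt == "json":
        path.write_text(
            json.dumps({"samples": rows, "summary_pct": pct}, indent=2)
        )
    elif fmt == "csv":
        cols = [
            "sample_id", "scheme", "verdict", "final_call", "category",
            "correlations", "evidence",
        ]
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for r in rows:
                w.writerow(
                    [
                        r["sample_id"], r["scheme"], r["verdict"],
                        r["final_call"], r["category"],
                        json.dumps(r["correlations"]),
                        " | ".join(r["evidence"]),
                    ]
                )
            w.writerow([])
            w.writerow(
                ["summary_pct"]
                + [f"{k}={v}" for k, v in pct.items()]
            )
    elif fmt == "markdown":
        lines = ["| sample | scheme | final call | category |",
                 "|---|---|---|---|"]
        for r in rows:
            lines.append(
                f"| {r['sample_id']} | {r['scheme']} | {r['final_call']} "
                f"| {r['category']} |"
            )
        lines.append("")
        lines.append(
            "Summary (%): "
            + ", ".join(f"{k} {v}" for k, v in pct.items())
        )
        for r in rows:
            lines.append("")
            lines.append(f"### {r['sample_id']}")
            for e in r["evidence"]:
                lines.append(f"- {e}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
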