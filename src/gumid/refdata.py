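"""Packaged reference database.

Two fixture tables ship with the package:

* 105 laboratory paint replicas of known gum (arabic, tragacanth, fruit
  tree), pigment and ageing regime, each with its relative sugar
  composition, the correlation coefficient printed for it in the source
  tables and the outcome of the older literature decision scheme (data
  only, never recomputed).
* 53 historical case samples, each with its sugar profile, analytical
  dialect, protein result, support/provenance context, the correlation
  entries printed for it, and the published scheme result and final
  conclusion.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Sequence

from .context import ProteinStatus, SampleContext
from .sugars import DIALECTS, GUM_SUGARS, SugarProfile

__all__ = [
    "GUMS",
    "ReplicaRecord",
    "CaseSample",
    "RangeSummary",
    "FixtureIntegrityError",
    "load_replicas",
    "load_cases",
    "marker_range",
]

GUMS: tuple[str, ...] = ("arabic", "tragacanth", "fruit_tree")

_GUM_LETTER = {"A": "arabic", "T": "tragacanth", "F": "fruit_tree"}


class FixtureIntegrityError(RuntimeError):
    """The packaged fixture does not match its expected shape."""


@dataclass(frozen=True)
class ReplicaRecord:
    """One reference paint-replica row."""

    gum: str
    pigment_element: str
    pigment: str
    ageing: str
    profile: SugarProfile
    printed_correlation: float
    literature_scheme_outcome: str

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.gum, self.pigment, self.ageing, self.profile.dialect.name)


@dataclass(frozen=True)
class CaseSample:
    """One historical paint sample with its published interpretation."""

    sample_id: str
    case: str
    origin: str
    artwork: str
    profile: SugarProfile
    context: SampleContext
    glucose_flag: bool | None
    printed_correlations: tuple[tuple[str, float], ...]
    printed_scheme: str
    printed_conclusion: str
    notes: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.sample_id, self.profile.dialect.name)


@dataclass(frozen=True)
class RangeSummary:
    sugar: str
    description: str
    min_pct: float
    max_pct: float


def _read_fixture(name: str) -> list[dict[str, str]]:
    with resources.files("gumid.data").joinpath(name).open(newline="") as fh:
        return list(csv.DictReader(fh))


def _profile_from_row(
    row: dict[str, str], dialect_field: str = "dialect"
) -> SugarProfile:
    dialect = DIALECTS[row[dialect_field]]
    values: dict[str, float] = {}
    missing: set[str] = set()
    for s in dialect.quantified_sugars:
        cell = row.get(s, "").strip()
        if cell in ("", "-"):
            missing.add(s)
        else:
            values[s] = float(cell.replace(",", ""))
    total = row.get("total_sugar", "").strip()
    return SugarProfile(
        values=values,
        dialect=dialect,
        total_sugar=float(total) if total else None,
        missing=frozenset(missing),
    )


def load_replicas() -> list[ReplicaRecord]:
    """All 105 reference replicas, in fixture order."""
    records = []
    for row in _read_fixture("replicas.csv"):
        records.append(
            ReplicaRecord(
                gum=row["gum"],
                pigment_element=row["pigment_element"],
                pigment=row["pigment"],
                ageing=row["ageing"],
                profile=_profile_from_row(row),
                printed_correlation=float(row["printed_correlation"]),
                literature_scheme_outcome=row["literature_scheme_outcome"],
            )
        )
    _check_replicas(records)
    return records


def _check_replicas(records: Sequence[ReplicaRecord]) -> None:
    if len(records) != 105:
        raise FixtureIntegrityError(f"expected 105 replicas, got {len(records)}")
    per_gum = {g: sum(1 for r in records if r.gum == g) for g in GUMS}
    if set(per_gum.values()) != {35}:
        raise FixtureIntegrityError(f"per-gum counts off: {per_gum}")
    if len({r.key for r in records}) != 105:
        raise FixtureIntegrityError("replica keys are not unique")
    for r in records:
        tot = r.profile.total()
        # one published row (arabic, unpigmented, SB2, DCCI) sums to 113.6
        # as printed; kept verbatim rather than rescaled
        if r.key == ("arabic", "none", "SB2", "DCCI"):
            continue
        if not tot <= 101.5:
            raise FixtureIntegrityError(
                f"replica {r.key} sums to {tot:.1f} > 101.5"
            )
        if r.profile.dialect.name == "GCI" and (
            {"galacturonic_acid", "glucuronic_acid"} & r.profile.recorded_sugars
        ):
            raise FixtureIntegrityError(f"GCI replica {r.key} has uronic acids")


def _parse_correlations(cell: str) -> tuple[tuple[str, float], ...]:
    cell = cell.strip()
    if not cell:
        return ()
    out = []
    for part in cell.split(";"):
        letter, value = part.split(":")
        out.append((_GUM_LETTER[letter.strip()], float(value)))
    return tuple(out)


def _parse_protein(cell: str) -> ProteinStatus:
    cell = cell.strip()
    if cell == "NA":
        return ProteinStatus(analysed=False, detected=None)
    if cell == "no":
        return ProteinStatus(analysed=True, detected=False)
    if cell.lower().startswith("yes"):
        return ProteinStatus(analysed=True, detected=True, sources=frozenset())
    src_map = {"E": "egg", "G": "animal_glue", "M": "milk"}
    sources = frozenset(src_map[p] for p in cell.split("+"))
    return ProteinStatus(analysed=True, detected=True, sources=sources)


def load_cases() -> list[CaseSample]:
    """All 53 encoded case samples, in fixture order."""
    samples = []
    for row in _read_fixture("cases.csv"):
        gums = row["plausible_gums"].strip()
        plausible = (
            frozenset(GUMS)
            if gums == "all"
            else frozenset(g for g in gums.split(";") if g)
        )
        flag = row["glucose_flag"].strip()
        context = SampleContext(
            protein=_parse_protein(row["protein"]),
            support=row["support"].strip() or "none",
            dyes=frozenset(d for d in row["dyes"].split(";") if d),
            fungal_growth=row["fungal"].strip() == "1",
            plausible_gums=plausible,
            glucose_detected={"yes": True, "no": False}.get(flag),
            notes=row["notes"],
        )
        samples.append(
            CaseSample(
                sample_id=row["sample_id"],
                case=row["case"],
                origin=row["origin"],
                artwork=row["artwork"],
                profile=_profile_from_row(row),
                context=context,
                glucose_flag=context.glucose_detected,
                printed_correlations=_parse_correlations(
                    row["printed_correlations"]
                ),
                printed_scheme=row["printed_scheme"],
                printed_conclusion=row["printed_conclusion"],
                notes=row["notes"],
            )
        )
    _check_cases(samples)
    return samples


def _check_cases(samples: Sequence[CaseSample]) -> None:
    if len(samples) != 53:
        raise FixtureIntegrityError(f"expected 53 case samples, got {len(samples)}")
    counts = {c: sum(1 for s in samples if s.case == c) for c in "abcd"}
    if counts != {"a": 7, "b": 10, "c": 8, "d": 28}:
        raise FixtureIntegrityError(f"per-case counts off: {counts}")
    if len({s.key for s in samples}) != 53:
        raise FixtureIntegrityError("case sample (id, dialect) keys not unique")


def marker_range(
    records: Iterable[ReplicaRecord],
    sugar: str,
    predicate: Callable[[ReplicaRecord], bool] | None = None,
    description: str = "",
) -> RangeSummary:
    """Min/max of a sugar's stored one-decimal value over selected replicas."""
    values = [
        r.profile.get(sugar)
        for r in records
        if (predicate is None or predicate(r)) and sugar in r.profile.recorded_sugars
    ]
    if not values:
        raise ValueError("predicate selects no record with that sugar")
    return RangeSummary(sugar, description, min(values), max(values))
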