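"""Correlation matching of a sample against the replica database.

A sample profile is compared with every reference replica by Pearson
product-moment correlation over the sugars both measurements quantify,
excluding glucose (references never report it; it is a contamination
indicator, not a gum component).  Both vectors are renormalized over the
shared sugar set before correlating, so the comparison is scale-free.

Correlation is auxiliary evidence only: pigments and ageing distort the
quantitative profiles enough that 31 of the 105 reference replicas
correlate poorly with their own gum, which is why the decisional schemes,
not the correlation, carry the identification.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .refdata import GUMS, ReplicaRecord
from .sugars import GUM_SUGARS, SugarProfile, restrict_renormalize

__all__ = [
    "MatchResult",
    "profile_correlation",
    "bin_quality",
    "best_matches",
    "match_from_printed",
]

#: Minimum number of shared sugars for a meaningful correlation.
MIN_SHARED_SUGARS = 3

#: Default correlation below which a gum is reported as "no" match.
DEFAULT_REPORT_THRESHOLD = 0.85


@dataclass(frozen=True)
class GumMatch:
    gum: str
    correlation: float  # rounded to two decimals
    replica_key: tuple[str, str, str, str] | None
    quality: str
    reportable: bool


@dataclass(frozen=True)
class MatchResult:
    """Best correlation per gum, with quality bin and report flag."""

    per_gum: tuple[GumMatch, ...]

    def best(self, gum: str) -> GumMatch:
        for gm in self.per_gum:
            if gm.gum == gum:
                return gm
        raise KeyError(gum)

    def excellent_gums(self) -> frozenset[str]:
        return frozenset(
            gm.gum for gm in self.per_gum if gm.quality == "excellent"
        )

    def reportable_gums(self) -> frozenset[str]:
        return frozenset(gm.gum for gm in self.per_gum if gm.reportable)


def _shared_sugars(a: SugarProfile, b: SugarProfile) -> list[str]:
    usable = (
        a.recorded_sugars & b.recorded_sugars & set(GUM_SUGARS)
    ) - a.missing - b.missing
    return [s for s in GUM_SUGARS if s in usable]


def profile_correlation(a: SugarProfile, b: SugarProfile) -> float:
    """Pearson correlation of two profiles over their shared sugar set."""
    shared = _shared_sugars(a, b)
    if len(shared) < MIN_SHARED_SUGARS:
        raise ValueError(
            f"only {len(shared)} shared sugars; need ≥ {MIN_SHARED_SUGARS}"
        )
    va = np.asarray(restrict_renormalize(a, shared).vector(shared))
    vb = np.asarray(restrict_renormalize(b, shared).vector(shared))
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("zero-variance composition vector")
    return float(np.corrcoef(va, vb)[0, 1])


def bin_quality(r: float) -> str:
    """Quality bin of a correlation, at two-decimal precision."""
    r = round(r, 2)
    if r >= 0.99:
        return "excellent"
    if r >= 0.96:
        return "good"
    return "poor"


def best_matches(
    sample: SugarProfile,
    db: Sequence[ReplicaRecord],
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> MatchResult:
    """Highest correlation per gum over all comparable replicas.

    Ties on the two-decimal correlation are broken by the lexicographically
    smallest replica key, so the result is independent of database order.
    """
    if not db:
        raise ValueError("empty replica database")
    best: dict[str, tuple[float, tuple]] = {}
    computed = 0
    for rec in db:
        try:
            r = profile_correlation(sample, rec.profile)
        except ValueError:
            continue
        computed += 1
        cand = (round(r, 2), rec.key)
        prev = best.get(rec.gum)
        if prev is None or cand[0] > prev[0] or (
            cand[0] == prev[0] and cand[1] < prev[1]
        ):
            best[rec.gum] = cand
    if computed == 0:
        raise ValueError("no replica shares a computable sugar set with sample")
    matches = []
    for gum in GUMS:
        if gum in best:
            r, key = best[gum]
            matches.append(
                GumMatch(gum, r, key, bin_quality(r), r >= report_threshold)
            )
        else:
            matches.append(GumMatch(gum, float("nan"), None, "poor", False))
    return MatchResult(per_gum=tuple(matches))


def match_from_printed(
    printed: Iterable[tuple[str, float]],
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> MatchResult:
    """Build a MatchResult from published per-gum correlation entries.

    Used for the encoded case samples, whose tabulated correlations were
    computed against reference vectors from a prior campaign that is not
    part of the packaged database; they are trusted as data.
    """
    printed = dict(printed)
    matches = []
    for gum in GUMS:
        if gum in printed:
            r = round(printed[gum], 2)
            matches.append(
                GumMatch(gum, r, None, bin_quality(r), r >= report_threshold)
            )
        else:
            matches.append(GumMatch(gum, float("nan"), None, "poor", False))
    return MatchResult(per_gum=tuple(matches))
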