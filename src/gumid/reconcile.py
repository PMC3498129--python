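"""Reconciliation: from scheme verdict to final interpretation.

The scheme verdict is combined with the auxiliary evidence — best
reference correlations, uronic-acid content, provenance plausibility,
fungal growth — to produce the final call, the analogue of the
"conclusions" column of a report table.  Rules, in order:

1. a single-gum or no-saccharide-binder verdict stands;
2. a *not identified* verdict with exactly one gum correlating excellently
   (≥ 0.99) is promoted to that gum, provided the uronic acids do not
   contradict it (glucuronic acid above 1 % fits arabic/fruit tree,
   galacturonic acid above 1 % fits tragacanth — measurable only in
   uronic-quantifying data);
3. a *fruit-or-arabic* suggestion with little mannose (attributable to a
   degraded plant support) and an excellent arabic correlation is promoted
   to arabic;
4. a suggestion in a sample overrun by fungal growth (glucose, mannose and
   galactose flood the profile) is demoted to *not identified*;
5. a call for a gum that is implausible for the provenance becomes
   *uncertain*;
6. otherwise the scheme verdict stands.

Final calls fall into three categories: *identified* (a single gum, or a
positive "no saccharide binder" reading), *suggestion* (fruit-or-arabic,
uncertain) and *not identified*.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import floor

from .context import ContaminationEvidence, SampleContext
from .matching import MatchResult
from .schemes import (
    ARABIC,
    FRUIT_OR_ARABIC,
    FRUIT_TREE,
    NO_SACCHARIDE_BINDER,
    NOT_IDENTIFIED,
    SINGLE_GUMS,
    SchemeResult,
    TRAGACANTH,
)
from .sugars import MarkerThresholds, SugarProfile

__all__ = [
    "UNCERTAIN",
    "Interpretation",
    "reconcile",
    "reconcile_object",
    "summarize",
    "category_of",
]

UNCERTAIN = "uncertain"

FINAL_CALLS = SINGLE_GUMS | {
    FRUIT_OR_ARABIC,
    UNCERTAIN,
    NOT_IDENTIFIED,
    NO_SACCHARIDE_BINDER,
}

IDENTIFIED = "identified"
SUGGESTION = "suggestion"

#: Report-table cell for each scheme verdict (the scheme vocabulary has no
#: cell for "no saccharide binder"; it prints as N/I, the distinction being
#: made in the conclusions column).
SCHEME_CELLS = {
    ARABIC: "A",
    TRAGACANTH: "T",
    FRUIT_TREE: "F",
    FRUIT_OR_ARABIC: "F or A",
    NOT_IDENTIFIED: "N/I",
    NO_SACCHARIDE_BINDER: "N/I",
}

#: Conclusions-column phrasing for each final call.
CONCLUSION_LABELS = {
    ARABIC: "arabic gum",
    TRAGACANTH: "tragacanth gum",
    FRUIT_TREE: "fruit tree gum",
    FRUIT_OR_ARABIC: "fruit tree gum or arabic gum",
    NOT_IDENTIFIED: "not identified",
    NO_SACCHARIDE_BINDER: "no polysaccharide binder",
    UNCERTAIN: "uncertain",
}

#: Gums a fruit-or-arabic suggestion keeps open.
_SUGGESTED = {FRUIT_OR_ARABIC: frozenset({FRUIT_TREE, ARABIC})}


def category_of(final_call: str) -> str:
    if final_call in SINGLE_GUMS or final_call == NO_SACCHARIDE_BINDER:
        return IDENTIFIED
    if final_call in (FRUIT_OR_ARABIC, UNCERTAIN):
        return SUGGESTION
    return NOT_IDENTIFIED


@dataclass(frozen=True)
class Interpretation:
    final_call: str
    category: str
    evidence: tuple[str, ...]
    scheme_result: SchemeResult
    match_result: MatchResult | None = None
    contamination: ContaminationEvidence | None = None

    def __post_init__(self) -> None:
        if self.final_call not in FINAL_CALLS:
            raise ValueError(f"unknown final call {self.final_call!r}")
        if self.category != category_of(self.final_call):
            raise ValueError("category inconsistent with final call")


def _uronic_support(p: SugarProfile, gum: str, th: MarkerThresholds) -> bool | None:
    """Do the uronic acids support this gum?  None = no usable evidence.

    Glucuronic acid is abundant in arabic and fruit tree gums; tragacanth
    instead carries galacturonic acid.  Only uronic-quantifying (DCCI)
    profiles can testify.
    """
    glca, gala = p.get("glucuronic_acid"), p.get("galacturonic_acid")
    if {"glucuronic_acid", "galacturonic_acid"} & p.missing:
        return None
    glca_hi, gala_hi = th.above(glca), th.above(gala)
    if not glca_hi and not gala_hi:
        return None
    if gum == TRAGACANTH:
        return gala_hi
    return glca_hi


def reconcile(
    sr: SchemeResult,
    mr: MatchResult | None,
    p: SugarProfile,
    ctx: SampleContext,
    th: MarkerThresholds = MarkerThresholds(),
    contamination: ContaminationEvidence | None = None,
) -> Interpretation:
    """Combine scheme verdict and auxiliary evidence into the final call."""
    call = sr.verdict
    ev = list(sr.evidence)
    excellent = mr.excellent_gums() if mr is not None else frozenset()

    if call == NOT_IDENTIFIED and len(excellent) == 1:
        (cand,) = excellent
        support = _uronic_support(p, cand, th)
        if support is not False:
            call = cand
            ev.append(
                f"unique excellent correlation (≥0.99) with {cand} replicas"
                + (
                    "; uronic acids concordant" if support else ""
                )
            )

    if call == FRUIT_OR_ARABIC:
        man = p.get("mannose")
        if (
            man <= th.attributable_mannose_ceiling
            and mr is not None
            and ARABIC in excellent
        ):
            call = ARABIC
            ev.append(
                f"mannose {man:.1f}% ≤ {th.attributable_mannose_ceiling}% "
                "attributable to degraded support; excellent arabic "
                "correlation → arabic gum"
            )

    if call == FRUIT_OR_ARABIC and ctx.fungal_growth:
        call = NOT_IDENTIFIED
        ev.append(
            "fungal growth floods the profile with glucose/mannose/"
            "galactose; suggestion withdrawn"
        )

    if call in SINGLE_GUMS or call == FRUIT_OR_ARABIC:
        open_gums = _SUGGESTED.get(call, frozenset({call}))
        if not open_gums & ctx.plausible_gums:
            ev.append(
                "no candidate gum is plausible for the provenance → uncertain"
            )
            call = UNCERTAIN

    return Interpretation(
        final_call=call,
        category=category_of(call),
        evidence=tuple(ev),
        scheme_result=sr,
        match_result=mr,
        contamination=contamination,
    )


def reconcile_object(interps: list[Interpretation]) -> list[str]:
    """Per-object view: promote suggestions consistent with sibling calls.

    If some layers of one object identify a single gum G and other layers
    only suggest a set containing G, the suggestions are promoted to G.
    Conflicting single-gum calls (multi-layer objects with different
    binders) are left side by side.
    """
    if not interps:
        raise ValueError("no interpretations for object")
    singles = {i.final_call for i in interps if i.final_call in SINGLE_GUMS}
    out = []
    for i in interps:
        suggested = _SUGGESTED.get(i.final_call)
        if suggested is not None and len(singles & suggested) == 1:
            (g,) = singles & suggested
            out.append(g)
        else:
            out.append(i.final_call)
    return out


def summarize(interps: list[Interpretation]) -> dict[str, int]:
    """Truncated integer percentages of the three categories."""
    if not interps:
        raise ValueError("nothing to summarize")
    n = len(interps)
    counts = {IDENTIFIED: 0, SUGGESTION: 0, NOT_IDENTIFIED: 0}
    for i in interps:
        counts[i.category] += 1
    return {k: floor(100 * v / n) for k, v in counts.items()}
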