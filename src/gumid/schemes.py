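"""Presence gate and the four decisional schemes.

All three modeled gums release arabinose and galactose on hydrolysis, so a
profile lacking either cannot be called a gum (the *presence gate*).  Past
the gate, three markers at a strict 1.0 %-relative cutoff do the work:

* X — xylose above 1.0 %: rules out arabic gum (unless contaminated);
* FU — fucose above 1.0 %: points to tragacanth;
* M — mannose above 1.0 %: points to fruit tree gum, *unless* another
  mannose-bearing material (egg, milk, cochineal, fungal growth, softwood
  support tissue) can explain it.

Marker comparisons are made on values rounded to one decimal, the precision
at which reference and sample compositions are tabulated, so exactly 1.0
falls on the trace side.
"""
from __future__ import annotations

from dataclasses import dataclass

from .context import (
    BINDER_MANNOSE_SOURCES,
    GALACTOSE_PROTEINS,
    SampleContext,
    mannose_sources,
)
from .sugars import MarkerThresholds, SugarProfile

__all__ = [
    "ARABIC",
    "TRAGACANTH",
    "FRUIT_TREE",
    "FRUIT_OR_ARABIC",
    "NOT_IDENTIFIED",
    "NO_SACCHARIDE_BINDER",
    "SchemeResult",
    "gate",
    "apply_scheme",
    "run_scheme",
]

ARABIC = "arabic"
TRAGACANTH = "tragacanth"
FRUIT_TREE = "fruit_tree"
FRUIT_OR_ARABIC = "fruit_or_arabic"
NOT_IDENTIFIED = "not_identified"
NO_SACCHARIDE_BINDER = "no_saccharide_binder"

VERDICTS = (
    ARABIC,
    TRAGACANTH,
    FRUIT_TREE,
    FRUIT_OR_ARABIC,
    NOT_IDENTIFIED,
    NO_SACCHARIDE_BINDER,
)

SINGLE_GUMS = frozenset({ARABIC, TRAGACANTH, FRUIT_TREE})


@dataclass(frozen=True)
class SchemeResult:
    verdict: str
    scheme_used: str
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if not self.evidence:
            raise ValueError("evidence trail must be non-empty")


def gate(
    p: SugarProfile,
    ctx: SampleContext,
    th: MarkerThresholds = MarkerThresholds(),
) -> tuple[bool, SchemeResult | None]:
    """Arabinose/galactose presence gate.

    Returns ``(True, None)`` when both gate sugars are present.  On
    failure, returns the verdict for the sample: *no saccharide binder*
    when arabinose — present in every gum and stable — is absent and a
    detected protein source that accounts for galactose (animal glue or
    milk) is on hand, so that every observed sugar has a non-gum origin
    (xylose/glucose from plant contamination, mannose from egg or milk);
    otherwise *not identified*.
    """
    ara_ok = th.above(p.get("arabinose"), th.presence_pct)
    gal_ok = th.above(p.get("galactose"), th.presence_pct)
    if ara_ok and gal_ok:
        return True, None
    evidence = []
    if not ara_ok:
        evidence.append("gate: arabinose absent (present in all gums)")
    if not gal_ok:
        evidence.append("gate: galactose absent (present in all gums)")
    if not ara_ok and ctx.protein.sources & GALACTOSE_PROTEINS:
        evidence.append(
            "observed sugars attributable to detected proteins "
            f"({'+'.join(sorted(ctx.protein.sources))}) and contamination"
        )
        verdict = NO_SACCHARIDE_BINDER
    else:
        evidence.append("sugars present not fully attributable; no gum call")
        verdict = NOT_IDENTIFIED
    return False, SchemeResult(verdict, "gate", tuple(evidence))


def _markers(p: SugarProfile, th: MarkerThresholds) -> tuple[bool, bool, bool]:
    return (
        th.above(p.get("xylose")),
        th.above(p.get("fucose")),
        th.above(p.get("mannose")),
    )


def apply_scheme(
    p: SugarProfile,
    scheme: str,
    ctx: SampleContext | None = None,
    th: MarkerThresholds = MarkerThresholds(),
) -> SchemeResult:
    """Apply one decisional scheme to a gate-passing profile.

    ``ctx`` is required for schemes c and d, whose mannose handling
    depends on the co-occurring materials.
    """
    ctx = ctx if ctx is not None else SampleContext()
    x, fu, m = _markers(p, th)
    ev = [
        f"markers: xylose {'>' if x else '≤'} {th.marker_pct}%, "
        f"fucose {'>' if fu else '≤'} {th.marker_pct}%, "
        f"mannose {'>' if m else '≤'} {th.marker_pct}%"
    ]
    sources = mannose_sources(ctx)
    binder_sources = sources & BINDER_MANNOSE_SOURCES

    def result(verdict: str, why: str) -> SchemeResult:
        return SchemeResult(verdict, scheme, tuple(ev + [why]))

    if scheme == "a":
        if not x and not fu and not m:
            return result(ARABIC, "no marker above cutoff → arabic gum")
        if x and fu and not m:
            return result(TRAGACANTH, "xylose+fucose, trace mannose → tragacanth")
        if x and not fu and m:
            return result(FRUIT_TREE, "xylose+mannose, trace fucose → fruit tree")
        return result(NOT_IDENTIFIED, "marker combination matches no single gum")

    if scheme == "b":
        # Protein presence unknown: mannose may be egg-derived, so it can
        # neither support a fruit-tree call nor be ignored.
        if not x and not fu and not m:
            return result(ARABIC, "no marker above cutoff → arabic gum")
        if x and fu and not m:
            return result(TRAGACANTH, "xylose+fucose, trace mannose → tragacanth")
        return result(
            NOT_IDENTIFIED,
            "mannose uninterpretable with protein status unknown",
        )

    if scheme == "c":
        if not x:
            return result(ARABIC, "trace xylose → arabic gum")
        if fu:
            if not m or binder_sources:
                why = (
                    "xylose+fucose → tragacanth"
                    if not m
                    else "mannose explained by "
                    + "+".join(sorted(binder_sources))
                    + " → tragacanth"
                )
                return result(TRAGACANTH, why)
            return result(NOT_IDENTIFIED, "fucose with unexplained mannose")
        if m:
            return result(FRUIT_TREE, "xylose+mannose, trace fucose → fruit tree")
        return result(NOT_IDENTIFIED, "xylose without fucose or mannose")

    if scheme == "d":
        # Contamination: xylose uninformative.
        if fu:
            if not m:
                return result(TRAGACANTH, "fucose, trace mannose → tragacanth")
            if binder_sources:
                return result(
                    TRAGACANTH,
                    "mannose explained by "
                    + "+".join(sorted(binder_sources))
                    + " → tragacanth",
                )
            return result(NOT_IDENTIFIED, "fucose with unexplained mannose")
        if not m:
            return result(ARABIC, "trace fucose and mannose → arabic gum")
        if sources:
            return result(
                FRUIT_OR_ARABIC,
                "mannose attributable to "
                + "+".join(sorted(sources))
                + " → fruit tree or arabic gum",
            )
        return result(FRUIT_TREE, "unexplained mannose → fruit tree")

    raise ValueError(f"unknown scheme {scheme!r}")


def run_scheme(
    p: SugarProfile,
    scheme: str,
    ctx: SampleContext | None = None,
    th: MarkerThresholds = MarkerThresholds(),
) -> SchemeResult:
    """Gate, then scheme: the verdict for one sample under one scheme."""
    ctx = ctx if ctx is not None else SampleContext()
    passed, failure = gate(p, ctx, th)
    if not passed:
        assert failure is not None
        return SchemeResult(failure.verdict, scheme, failure.evidence)
    return apply_scheme(p, scheme, ctx, th)
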