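"""Sample context, contamination evidence and decisional-scheme selection.

The decisional model is conditional: which rule tree applies to a sugar
profile depends on what else is known about the sample — whether proteins
were analysed and found, whether their source is identified, and whether
saccharides from plant tissue (wood, paper, cartonnage, straw, airborne
particulate) can have contaminated the paint.  The four situations are
labelled a-d:

a. proteins analysed and absent, no contamination;
b. protein presence unknown (not analysed, or detected without an
   identified source), no contamination;
c. proteins present with identified source(s), no contamination;
d. contamination evidence — plant-derived support, straw, or a
   xylose/arabinose ratio above 1 — which overrides everything else and
   makes xylose uninformative.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .sugars import MarkerThresholds, SugarProfile, xyl_ara_ratio

__all__ = [
    "PLANT_SUPPORTS",
    "SUPPORTS",
    "ProteinStatus",
    "SampleContext",
    "ContaminationEvidence",
    "detect_contamination",
    "mannose_sources",
    "select_scheme",
]

SUPPORTS: frozenset[str] = frozenset(
    {"none", "wood", "paper", "cartonnage", "straw_containing",
     "clay", "stone", "plaster", "canvas"}
)

#: Supports made of plant tissue, whose degradation sugars reach the paint.
PLANT_SUPPORTS: frozenset[str] = frozenset(
    {"wood", "paper", "cartonnage", "straw_containing"}
)

PROTEIN_SOURCES: frozenset[str] = frozenset({"egg", "animal_glue", "milk"})

#: Protein sources that carry galactose (collagen glycosides, lactose).
GALACTOSE_PROTEINS: frozenset[str] = frozenset({"animal_glue", "milk"})


@dataclass(frozen=True)
class ProteinStatus:
    """Outcome of the (upstream) proteinaceous-binder analysis.

    ``detected`` is ``None`` when unknown (not analysed); ``sources`` may
    be empty with ``detected=True`` (protein found, source unidentified).
    """

    analysed: bool
    detected: bool | None
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sources <= PROTEIN_SOURCES:
            raise ValueError(f"unknown protein sources: {set(self.sources)}")
        if self.sources and self.detected is not True:
            raise ValueError("sources given but protein not detected")
        if not self.analysed and self.detected is not None:
            raise ValueError("protein not analysed but detection recorded")

    @property
    def source_known(self) -> bool:
        return self.detected is True and bool(self.sources)

    @property
    def egg_possible(self) -> bool:
        """Egg present, or not excludable (unanalysed / unidentified)."""
        if "egg" in self.sources:
            return True
        if self.detected is False:
            return False
        return not self.source_known  # unknown presence or unknown source


@dataclass(frozen=True)
class SampleContext:
    """Everything the decisional schemes condition on besides the profile."""

    protein: ProteinStatus = ProteinStatus(analysed=False, detected=None)
    support: str = "none"
    dyes: frozenset[str] = field(default_factory=frozenset)
    fungal_growth: bool = False
    plausible_gums: frozenset[str] = frozenset(
        {"arabic", "tragacanth", "fruit_tree"}
    )
    glucose_detected: bool | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.support not in SUPPORTS:
            raise ValueError(f"unknown support: {self.support!r}")


@dataclass(frozen=True)
class ContaminationEvidence:
    flagged: bool
    reasons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.flagged != bool(self.reasons):
            raise ValueError("flagged must mirror non-empty reasons")


def detect_contamination(
    p: SugarProfile,
    ctx: SampleContext,
    th: MarkerThresholds = MarkerThresholds(),
) -> ContaminationEvidence:
    """Plant-tissue contamination evidence for a sample.

    Fires on a xylose/arabinose ratio above threshold (xylose is abundant
    in plant tissue and never exceeds arabinose in any reference gum), on
    plant-derived supports, and on straw.  The ratio rule needs a measurable
    arabinose; arabinose-absent profiles are the presence gate's business,
    not a contamination call.  Glucose is corroborating only: it is recorded
    as a reason when some other reason already fired.
    """
    reasons: set[str] = set()
    ratio = xyl_ara_ratio(p)
    if ratio is not None and ratio > th.xyl_ara_contamination_ratio:
        reasons.add("xyl_ara_ratio_exceeded")
    if ctx.support in PLANT_SUPPORTS:
        reasons.add("plant_support")
    if ctx.support == "straw_containing":
        reasons.add("straw")
    if reasons and (
        p.get("glucose") > 0 or ctx.glucose_detected is True
    ):
        reasons.add("glucose_present")
    return ContaminationEvidence(flagged=bool(reasons), reasons=frozenset(reasons))


def mannose_sources(
    ctx: SampleContext,
    contamination: ContaminationEvidence | None = None,
) -> frozenset[str]:
    """Non-gum materials in the sample that can contribute mannose.

    Egg is counted whenever it cannot be excluded (present, unidentified
    protein, or protein never analysed); milk and cochineal when present;
    plant tissue when the sample physically sits on a plant-derived support
    (softwood glucomannan).  Animal glue contributes none.  Fungal growth
    also contributes mannose (with glucose and galactose) and is tagged
    separately.
    """
    sources: set[str] = set()
    if ctx.protein.egg_possible:
        sources.add("egg")
    if "milk" in ctx.protein.sources:
        sources.add("milk")
    if "cochineal" in ctx.dyes:
        sources.add("cochineal")
    if ctx.support in PLANT_SUPPORTS:
        sources.add("plant_tissue")
    if ctx.fungal_growth:
        sources.add("fungus")
    return frozenset(sources)


#: Sources usable to explain mannose in the tragacanth branch: materials
#: mixed into the paint itself (binders, dyes), not support tissue.
BINDER_MANNOSE_SOURCES: frozenset[str] = frozenset({"egg", "milk", "cochineal"})


def select_scheme(
    ctx: SampleContext, contamination: ContaminationEvidence
) -> str:
    """Choose the decisional scheme (a-d) for a sample.

    Contamination evidence always wins (d); otherwise the protein status
    decides: identified source(s) → c, analysed-and-absent → a, anything
    unknown → b.
    """
    if contamination.flagged:
        return "d"
    if ctx.protein.source_known:
        return "c"
    if ctx.protein.analysed and ctx.protein.detected is False:
        return "a"
    return "b"
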