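"""Sugar vocabulary, composition profiles and marker thresholds.

A hydrolysed paint micro-sample yields a set of monosaccharides and uronic
acids whose *relative* composition (percent of total detected sugar) is the
fingerprint used to recognise a plant gum.  Two analytical dialects are
modelled: a neutral-sugar procedure (``GCI``) that does not quantify the
uronic acids, and a mercaptalation procedure (``DCCI``) that does.  Glucose
is quantified by both but is never a gum marker — it is ubiquitous in
supports, plant tissue and microbial growth — so it is excluded from
marker logic and correlation vectors and kept only as contamination
evidence.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "SUGARS",
    "GUM_SUGARS",
    "Sugar",
    "MethodDialect",
    "GCI",
    "DCCI",
    "SugarProfile",
    "MarkerThresholds",
    "EmptyChromatogramError",
    "normalize_profile",
    "restrict_renormalize",
    "xyl_ara_ratio",
]

Sugar = str

#: Canonical ordering used for vectorisation everywhere in the package.
SUGARS: tuple[Sugar, ...] = (
    "xylose",
    "arabinose",
    "rhamnose",
    "fucose",
    "galacturonic_acid",
    "glucuronic_acid",
    "mannose",
    "galactose",
    "glucose",
)

#: Sugars that may carry gum-diagnostic information (glucose excluded).
GUM_SUGARS: tuple[Sugar, ...] = tuple(s for s in SUGARS if s != "glucose")

_ABBREV = {
    "xyl": "xylose", "ara": "arabinose", "rha": "rhamnose", "fuc": "fucose",
    "gala": "galacturonic_acid", "glca": "glucuronic_acid",
    "man": "mannose", "gal": "galactose", "glc": "glucose",
}


def canonical_sugar(name: str) -> Sugar:
    """Resolve a full or abbreviated sugar name to its canonical form."""
    key = name.strip().lower().replace(" ", "_")
    if key in SUGARS:
        return key
    if key in _ABBREV:
        return _ABBREV[key]
    raise ValueError(f"unknown sugar: {name!r}")


class EmptyChromatogramError(ValueError):
    """Raised when a profile carries no sugar signal at all."""


@dataclass(frozen=True)
class MethodDialect:
    """An analytical procedure, defined by the sugars it quantifies."""

    name: str
    quantified_sugars: frozenset[Sugar]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Neutral-sugar procedure: no uronic acids.
GCI = MethodDialect(
    "GCI",
    frozenset(s for s in SUGARS if not s.endswith("_acid")),
)
#: Mercaptalation procedure: neutral sugars plus uronic acids.
DCCI = MethodDialect("DCCI", frozenset(SUGARS))

DIALECTS: dict[str, MethodDialect] = {"GCI": GCI, "DCCI": DCCI}


@dataclass(frozen=True)
class SugarProfile:
    """Relative sugar composition of one sample or reference layer.

    ``values`` maps sugar name to relative percent (0-100).  Sugars the
    dialect quantifies but which were not recorded for this sample are in
    ``missing`` (e.g. uronic acids shown as "-" in neutral-sugar data),
    which is distinct from a measured 0.0.  ``total_sugar`` is the raw
    quantified amount (µg for DCCI, percent of sample weight for GCI) when
    known.
    """

    values: Mapping[Sugar, float]
    dialect: MethodDialect = DCCI
    total_sugar: float | None = None
    missing: frozenset[Sugar] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        vals = {canonical_sugar(k): float(v) for k, v in self.values.items()}
        for s, v in vals.items():
            if v < 0:
                raise ValueError(f"negative value for {s}: {v}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "missing", frozenset(self.missing) - set(vals))

    def get(self, sugar: Sugar, default: float = 0.0) -> float:
        return self.values.get(canonical_sugar(sugar), default)

    @property
    def recorded_sugars(self) -> set[Sugar]:
        return set(self.values)

    def vector(self, sugars: Iterable[Sugar]) -> list[float]:
        """Values over ``sugars`` in the given order (missing as 0)."""
        return [self.get(s) for s in sugars]

    def total(self) -> float:
        return float(sum(self.values.values()))

    def rounded(self, ndigits: int = 1) -> "SugarProfile":
        """Profile with values rounded to table precision."""
        return replace(
            self, values={s: round(v, ndigits) for s, v in self.values.items()}
        )


@dataclass(frozen=True)
class MarkerThresholds:
    """Cutoffs of the decisional model.

    marker_pct
        Relative-% cutoff separating an "abundant" marker from a trace;
        comparisons are strict (exactly 1.0 counts as trace).
    presence_pct
        Cutoff for the arabinose/galactose presence gate (0.0 = strictly
        positive).
    xyl_ara_contamination_ratio
        xylose/arabinose ratio above which plant-tissue contamination is
        assumed.
    attributable_mannose_ceiling
        Largest relative mannose (%) that may be written off to a degraded
        plant support when promoting a fruit-or-arabic suggestion to arabic.
    """

    marker_pct: float = 1.0
    presence_pct: float = 0.0
    xyl_ara_contamination_ratio: float = 1.0
    attributable_mannose_ceiling: float = 3.0

    def __post_init__(self) -> None:
        for f in (
            self.marker_pct,
            self.presence_pct,
            self.xyl_ara_contamination_ratio,
            self.attributable_mannose_ceiling,
        ):
            if f < 0:
                raise ValueError("thresholds must be non-negative")

    def above(self, value: float, cutoff: float | None = None) -> bool:
        """Strict marker comparison at stored (one-decimal) precision."""
        cutoff = self.marker_pct if cutoff is None else cutoff
        return round(value, 1) > cutoff


def normalize_profile(
    raw: Mapping[str, float],
    dialect: MethodDialect = DCCI,
    total_sugar: float | None = None,
) -> SugarProfile:
    """Convert raw per-sugar amounts to a relative-% profile summing to 100.

    Sugars the dialect quantifies but absent from ``raw`` are marked
    missing.  An all-zero input signals an empty chromatogram.
    """
    vals = {canonical_sugar(k): float(v) for k, v in raw.items()}
    if any(v < 0 for v in vals.values()):
        raise ValueError("raw amounts must be non-negative")
    tot = sum(vals.values())
    if tot <= 0:
        raise EmptyChromatogramError("no sugar signal in input")
    return SugarProfile(
        values={s: 100.0 * v / tot for s, v in vals.items()},
        dialect=dialect,
        total_sugar=total_sugar,
        missing=dialect.quantified_sugars - set(vals),
    )


def restrict_renormalize(p: SugarProfile, sugars: Iterable[Sugar]) -> SugarProfile:
    """Restrict a profile to ``sugars`` and rescale to sum 100.

    Needed when comparing profiles measured with different dialects (e.g.
    a sample reporting glucose against references that never do).
    """
    keep = {canonical_sugar(s) for s in sugars}
    vals = {s: v for s, v in p.values.items() if s in keep}
    tot = sum(vals.values())
    if tot <= 0:
        raise EmptyChromatogramError(
            "restriction removes all sugar signal from profile"
        )
    return SugarProfile(
        values={s: 100.0 * v / tot for s, v in vals.items()},
        dialect=p.dialect,
        total_sugar=p.total_sugar,
        missing=frozenset(p.missing & keep),
    )


def xyl_ara_ratio(p: SugarProfile) -> float | None:
    """Xylose/arabinose ratio; ``None`` (undefined) when arabinose is 0."""
    ara = p.get("arabinose")
    if ara == 0:
        return None
    return p.get("xylose") / ara
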