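"""Theoretical sugar profiles of binder mixtures and contaminated gums.

A paint layer mixing a gum with other organic materials yields a sugar
profile that is the saccharide-weighted average of its components: a
component contributes in proportion to its mass fraction *times* its
saccharide content (the fraction of its mass that is sugar).  Egg, for
example, is only ~1 % saccharide, yet in a 1:1 mass mixture with a gum its
mannose measurably shifts the profile.
"""
from __future__ import annotations

from dataclasses import dataclass

from .sugars import SugarProfile, normalize_profile

__all__ = ["MixtureComponent", "mix_profiles", "contaminate", "EGG_SACCHARIDE_CONTENT"]

#: Approximate saccharide mass fraction of whole egg.
EGG_SACCHARIDE_CONTENT = 0.01


@dataclass(frozen=True)
class MixtureComponent:
    profile: SugarProfile
    mass_fraction: float
    saccharide_content: float

    def __post_init__(self) -> None:
        if not 0 <= self.mass_fraction <= 1:
            raise ValueError("mass_fraction must be in [0, 1]")
        if not 0 <= self.saccharide_content <= 1:
            raise ValueError("saccharide_content must be in [0, 1]")


def mix_profiles(components: list[MixtureComponent]) -> SugarProfile:
    """Sugar profile of a mixture, on the saccharide basis.

    Per sugar s: sum_i w_i * c_i * p_i(s) / sum_i w_i * c_i, renormalized
    to 100.  Missing sugars count as zero; the output covers the union of
    the component sugar sets.
    """
    if not components:
        raise ValueError("at least one component required")
    total_w = sum(c.mass_fraction for c in components)
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"mass fractions sum to {total_w}, not 1")
    weights = [c.mass_fraction * c.saccharide_content for c in components]
    denom = sum(weights)
    if denom <= 0:
        raise ValueError("mixture contains no saccharide mass")
    sugars = set()
    for c in components:
        sugars |= c.profile.recorded_sugars
    raw = {
        s: sum(w * c.profile.get(s) for w, c in zip(weights, components))
        for s in sugars
    }
    dialect = components[0].profile.dialect
    return normalize_profile(raw, dialect=dialect)


def contaminate(
    gum: SugarProfile, contaminant: SugarProfile, f: float
) -> SugarProfile:
    """Gum contaminated by fraction ``f`` of its saccharide content.

    Linear blend (1-f)*gum + f*contaminant on the saccharide basis.
    """
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    return mix_profiles(
        [
            MixtureComponent(gum, mass_fraction=1 - f, saccharide_content=1.0),
            MixtureComponent(contaminant, mass_fraction=f, saccharide_content=1.0),
        ]
        if 0 < f < 1
        else [
            MixtureComponent(
                contaminant if f == 1 else gum,
                mass_fraction=1.0,
                saccharide_content=1.0,
            )
        ]
    )
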