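"""Reconciliation of scheme verdicts with auxiliary evidence."""
import pytest

from gumid.context import ProteinStatus, SampleContext
from gumid.matching import match_from_printed
from gumid.reconcile import (
    UNCERTAIN,
    Interpretation,
    category_of,
    reconcile,
    reconcile_object,
    summarize,
)
from gumid.schemes import (
    ARABIC,
    FRUIT_OR_ARABIC,
    FRUIT_TREE,
    NOT_IDENTIFIED,
    TRAGACANTH,
    SchemeResult,
)
from gumid.sugars import DCCI, MarkerThresholds, SugarProfile

TH = MarkerThresholds()
CTX = SampleContext(protein=ProteinStatus(False, None))


def sr(verdict, scheme="b"):
    return SchemeResult(verdict, scheme, ("test",))


def test_single_gum_verdict_stands():
    p = SugarProfile({"arabinose": 60, "galactose": 40})
    out = reconcile(sr(ARABIC), match_from_printed([("fruit_tree", 0.99)]),
                    p, CTX, TH)
    assert out.final_call == ARABIC
    assert out.category == "identified"


def test_unique_excellent_correlation_promotes_not_identified():
    # high glucuronic acid corroborates a fruit-tree (or arabic) source
    p = SugarProfile(
        {"xylose": 8.2, "arabinose": 61.6, "rhamnose": 2.6, "fucose": 0.7,
         "galacturonic_acid": 0.7, "glucuronic_acid": 5.9, "mannose": 0.8,
         "galactose": 19.5},
        dialect=DCCI,
    )
    out = reconcile(sr(NOT_IDENTIFIED), match_from_printed([("fruit_tree", 0.99)]),
                    p, CTX, TH)
    assert out.final_call == FRUIT_TREE


def test_two_equal_matches_stay_not_identified():
    p = SugarProfile({"arabinose": 43.8, "galactose": 44.9})
    mr = match_from_printed([("arabic", 0.95), ("fruit_tree", 0.95)])
    out = reconcile(sr(NOT_IDENTIFIED), mr, p, CTX, TH)
    assert out.final_call == NOT_IDENTIFIED


def test_contradicting_uronic_acids_block_promotion():
    # galacturonic acid high, glucuronic trace → tragacanth-like chemistry,
    # so an excellent fruit-tree correlation alone may not promote
    p = SugarProfile(
        {"xylose": 20, "arabinose": 40, "fucose": 0.5,
         "galacturonic_acid": 14.1, "glucuronic_acid": 0.6,
         "mannose": 0.5, "galactose": 25},
        dialect=DCCI,
    )
    out = reconcile(sr(NOT_IDENTIFIED), match_from_printed([("fruit_tree", 0.99)]),
                    p, CTX, TH)
    assert out.final_call == NOT_IDENTIFIED


def test_low_mannose_suggestion_with_excellent_arabic_promotes():
    p = SugarProfile({"xylose": 13.6, "arabinose": 56.4, "mannose": 1.4,
                      "galactose": 27.4})
    mr = match_from_printed([("arabic", 0.99), ("fruit_tree", 0.99)])
    out = reconcile(sr(FRUIT_OR_ARABIC, "d"), mr, p, CTX, TH)
    assert out.final_call == ARABIC


def test_high_mannose_suggestion_not_promoted():
    p = SugarProfile({"xylose": 84.5, "arabinose": 1.1, "mannose": 4.0,
                      "galactose": 5.8})
    mr = match_from_printed([("arabic", 0.99)])
    out = reconcile(sr(FRUIT_OR_ARABIC, "d"), mr, p, CTX, TH)
    assert out.final_call == FRUIT_OR_ARABIC
    assert out.category == "suggestion"


def test_implausible_provenance_becomes_uncertain():
    p = SugarProfile({"xylose": 17.5, "arabinose": 12.5, "mannose": 9.5,
                      "galactose": 46.1})
    ctx = SampleContext(protein=ProteinStatus(False, None),
                        plausible_gums=frozenset())
    out = reconcile(sr(FRUIT_OR_ARABIC, "d"),
                    match_from_printed([("fruit_tree", 0.84)]), p, ctx, TH)
    assert out.final_call == UNCERTAIN
    assert out.category == "suggestion"


def test_fungal_growth_withdraws_suggestion():
    p = SugarProfile({"xylose": 69.8, "arabinose": 5.2, "mannose": 20.9,
                      "galactose": 3.9})
    ctx = SampleContext(protein=ProteinStatus(False, None), fungal_growth=True)
    out = reconcile(sr(FRUIT_OR_ARABIC, "d"), None, p, ctx, TH)
    assert out.final_call == NOT_IDENTIFIED


def interp(call):
    p = SugarProfile({"arabinose": 50, "galactose": 50})
    return Interpretation(call, category_of(call), ("t",), sr(call))


def test_object_promotion():
    calls = reconcile_object([interp(ARABIC), interp(ARABIC),
                              interp(FRUIT_OR_ARABIC)])
    assert calls == [ARABIC, ARABIC, ARABIC]


def test_object_conflicting_layers_preserved():
    calls = reconcile_object([interp(TRAGACANTH), interp(FRUIT_TREE),
                              interp(ARABIC)])
    assert calls == [TRAGACANTH, FRUIT_TREE, ARABIC]
    # both fruit and arabic among singles → ambiguous, suggestion stays
    calls = reconcile_object([interp(FRUIT_TREE), interp(ARABIC),
                              interp(FRUIT_OR_ARABIC)])
    assert calls[-1] == FRUIT_OR_ARABIC


def test_object_singleton_identity_and_empty_error():
    assert reconcile_object([interp(NOT_IDENTIFIED)]) == [NOT_IDENTIFIED]
    with pytest.raises(ValueError):
        reconcile_object([])


def test_summarize_truncates():
    interps = [interp(ARABIC)] * 28 + [interp(FRUIT_OR_ARABIC)] * 12 + \
        [interp(NOT_IDENTIFIED)] * 13
    pct = summarize(interps)
    assert pct == {"identified": 52, "suggestion": 22, "not_identified": 24}
    assert summarize([interp(ARABIC)]) == {
        "identified": 100, "suggestion": 0, "not_identified": 0
    }


def test_category_consistency_enforced():
    with pytest.raises(ValueError):
        Interpretation(ARABIC, "suggestion", ("t",), sr(ARABIC))
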