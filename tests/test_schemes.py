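"""Presence gate and decisional schemes a-d."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gumid.context import ProteinStatus, SampleContext
from gumid.schemes import (
    ARABIC,
    FRUIT_OR_ARABIC,
    FRUIT_TREE,
    NO_SACCHARIDE_BINDER,
    NOT_IDENTIFIED,
    TRAGACANTH,
    VERDICTS,
    apply_scheme,
    gate,
    run_scheme,
)
from gumid.sugars import MarkerThresholds, SugarProfile

TH = MarkerThresholds()


def profile(xyl=0.0, fuc=0.0, man=0.0, ara=40.0, gal=40.0, **kw):
    vals = {"xylose": xyl, "fucose": fuc, "mannose": man,
            "arabinose": ara, "galactose": gal}
    vals.update(kw)
    return SugarProfile(vals)


def ctx_with(sources=(), analysed=True, detected=None, support="none",
             dyes=()):
    if sources:
        protein = ProteinStatus(True, True, frozenset(sources))
    elif detected is None:
        protein = ProteinStatus(analysed, False if analysed else None)
    else:
        protein = ProteinStatus(analysed, detected)
    return SampleContext(protein=protein, support=support,
                         dyes=frozenset(dyes))


def test_gate_passes_with_both_sugars():
    ok, failure = gate(profile(ara=87.7, gal=12.3), ctx_with(), TH)
    assert ok and failure is None


def test_gate_fail_no_arabinose_with_glue_is_no_binder():
    # egg+glue: mannose from egg, galactose from glue, xylose from
    # contamination — every sugar accounted for without a gum
    p = profile(xyl=51.6, man=36.3, ara=0.0, gal=12.1)
    ok, failure = gate(p, ctx_with(sources=("egg", "animal_glue")), TH)
    assert not ok and failure.verdict == NO_SACCHARIDE_BINDER


def test_gate_fail_no_arabinose_egg_only_is_not_identified():
    # egg does not account for galactose
    p = profile(xyl=58.9, ara=0.0, gal=41.1)
    ok, failure = gate(p, ctx_with(sources=("egg",)), TH)
    assert not ok and failure.verdict == NOT_IDENTIFIED


def test_gate_fail_no_galactose_is_not_identified():
    p = profile(xyl=67.6, ara=13.9, gal=0.0, glucose=18.5)
    ok, failure = gate(p, ctx_with(sources=("milk",)), TH)
    assert not ok and failure.verdict == NOT_IDENTIFIED


@pytest.mark.parametrize(
    "scheme, p, context, expected",
    [
        # scheme a: three markers, all required
        ("a", profile(xyl=0.5, fuc=0.0, man=0.5), ctx_with(), ARABIC),
        ("a", profile(xyl=29.2, fuc=11.1, man=0.0), ctx_with(), TRAGACANTH),
        ("a", profile(xyl=11.8, fuc=0.1, man=2.2), ctx_with(), FRUIT_TREE),
        ("a", profile(xyl=11.1, fuc=11.1, man=3.7), ctx_with(), NOT_IDENTIFIED),
        # scheme b: unexplained mannose blocks every positive call
        ("b", profile(xyl=0.0, fuc=0.0, man=0.0), ctx_with(analysed=False),
         ARABIC),
        ("b", profile(xyl=0.6, fuc=1.2, man=0.6), ctx_with(analysed=False),
         NOT_IDENTIFIED),
        ("b", profile(xyl=3.8, fuc=1.0, man=8.1), ctx_with(analysed=False),
         NOT_IDENTIFIED),
        # scheme c: known protein sources explain mannose
        ("c", profile(xyl=2.4, fuc=1.3, man=29.9),
         ctx_with(sources=("egg",), dyes=("cochineal",)), TRAGACANTH),
        ("c", profile(xyl=15.6, fuc=0.0, man=19.3),
         ctx_with(sources=("egg", "animal_glue")), FRUIT_TREE),
        ("c", profile(xyl=0.0, fuc=0.0, man=54.8), ctx_with(sources=("egg",)),
         ARABIC),
        # scheme d: xylose uninformative
        ("d", profile(xyl=51.3, fuc=0.0, man=16.2),
         ctx_with(sources=("animal_glue",)), FRUIT_TREE),
        ("d", profile(xyl=35.2, fuc=6.0, man=13.4),
         ctx_with(sources=("animal_glue",), support="wood"), NOT_IDENTIFIED),
        ("d", profile(xyl=29.6, fuc=0.9, man=22.8), ctx_with(sources=("egg",)),
         FRUIT_OR_ARABIC),
        ("d", profile(xyl=0.0, fuc=0.0, man=0.0), ctx_with(detected=True),
         ARABIC),
        ("d", profile(xyl=84.5, fuc=0.4, man=4.0),
         ctx_with(support="wood"), FRUIT_OR_ARABIC),  # wood explains mannose
        ("d", profile(xyl=27.7, fuc=3.1, man=43.9), ctx_with(sources=("egg",)),
         TRAGACANTH),
    ],
)
def test_apply_scheme_examples(scheme, p, context, expected):
    assert apply_scheme(p, scheme, context, TH).verdict == expected


def test_unknown_scheme_rejected():
    with pytest.raises(ValueError):
        apply_scheme(profile(), "e", ctx_with(), TH)


def test_exactly_one_point_zero_is_trace():
    # a stored 1.0 is not "higher than 1.0 %": stays on the arabic side
    assert apply_scheme(profile(xyl=1.0), "a", ctx_with(), TH).verdict == ARABIC
    assert (
        apply_scheme(profile(xyl=1.1), "a", ctx_with(), TH).verdict
        != ARABIC
    )


def test_replica_self_test_under_scheme_a(replicas):
    """Scheme a recovers the true gum for all replicas except the three
    malachite fruit-tree rows, whose mannose was wiped to 0.0."""
    wrong = [
        r.key
        for r in replicas
        if apply_scheme(r.profile, "a", SampleContext(), TH).verdict != r.gum
    ]
    assert wrong == [
        ("fruit_tree", "malachite", "n", "GCI"),
        ("fruit_tree", "malachite", "W", "GCI"),
        ("fruit_tree", "malachite", "O", "GCI"),
    ]


marker_floats = st.floats(0, 60, allow_nan=False)


@settings(derandomize=True, max_examples=300)
@given(st.sampled_from("abcd"), marker_floats, marker_floats, marker_floats,
       st.floats(0, 80), st.floats(0, 80),
       st.sets(st.sampled_from(["egg", "animal_glue", "milk"])))
def test_scheme_totality(scheme, xyl, fuc, man, ara, gal, sources):
    """Every profile/context lands on exactly one verdict, never an error."""
    c = ctx_with(sources=tuple(sources)) if sources else ctx_with()
    res = run_scheme(profile(xyl=xyl, fuc=fuc, man=man, ara=ara, gal=gal),
                     scheme, c, TH)
    assert res.verdict in VERDICTS
    assert res.evidence


@settings(derandomize=True, max_examples=200)
@given(marker_floats, marker_floats, marker_floats)
def test_arabic_calls_stable_under_raising_threshold(xyl, fuc, man):
    """Raising the marker cutoff only switches markers off, so an arabic
    verdict (all markers trace) can never be lost."""
    p = profile(xyl=xyl, fuc=fuc, man=man)
    lo = apply_scheme(p, "a", ctx_with(), MarkerThresholds(marker_pct=1.0))
    hi = apply_scheme(p, "a", ctx_with(), MarkerThresholds(marker_pct=3.0))
    if lo.verdict == ARABIC:
        assert hi.verdict == ARABIC
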