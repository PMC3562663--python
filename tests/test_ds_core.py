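"""Mass-function algebra: construction, Bel/Pl, combination, pignistic."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from topper.ds_core import (
    CLASSES,
    OMEGA,
    MassFunction,
    MassFunctionError,
    TotalConflictError,
    belief,
    combine_dempster,
    combine_many,
    make_mass,
    pignistic,
    plausibility,
    vacuous,
)

from _oracle import brute_belief, brute_pignistic, brute_plausibility

F = frozenset


# --- strategies -----------------------------------------------------------

_NONEMPTY = [F(s) for s in ("i", "M", "o", "iM", "io", "Mo", "iMo")]


@st.composite
def bpas(draw):
    k = draw(st.integers(1, len(_NONEMPTY)))
    focal = draw(st.permutations(_NONEMPTY))[:k]
    raw = [draw(st.floats(0.01, 1.0)) for _ in range(k)]
    total = sum(raw)
    return make_mass({a: w / total for a, w in zip(focal, raw)})


# --- construction ---------------------------------------------------------

def test_make_mass_accepts_valid_bpas():
    vac = make_mass({OMEGA: 1.0})
    assert vac[OMEGA] == 1.0 and len(vac) == 1
    two = make_mass({F("M"): 0.7869, F("io"): 0.2131})
    assert two[F("M")] == pytest.approx(0.7869)
    assert two.focal_elements == {F("M"), F("io")}


@pytest.mark.parametrize(
    "assignments",
    [
        {F("M"): 0.5, F(): 0.5},           # mass on the empty set
        {F("M"): 0.5, F("io"): 0.4},       # does not sum to 1
        {F("M"): 1.2, F("io"): -0.2},      # negative mass
        {F("Mx"): 1.0},                    # label outside the frame
    ],
)
def test_make_mass_rejects_invalid_bpas(assignments):
    with pytest.raises(MassFunctionError):
        make_mass(assignments)


def test_zero_mass_entries_are_dropped():
    m = make_mass({F("M"): 1.0, F("io"): 0.0, F(): 0.0})
    assert m.focal_elements == {F("M")}


def test_serialization_uses_canonical_subset_strings():
    m = make_mass({F("oi"): 0.25, F("M"): 0.75})
    assert m.to_dict() == {"M": 0.75, "i|o": 0.25}


# --- belief / plausibility ------------------------------------------------

def test_belief_and_plausibility_hand_examples():
    m = make_mass({F("M"): 0.9, F("io"): 0.1})
    assert belief(m, OMEGA) == pytest.approx(1.0)
    assert plausibility(m, OMEGA) == pytest.approx(1.0)
    assert belief(m, F("i")) == 0.0
    assert belief(m, F("Mo")) == pytest.approx(0.9)   # {M} is the only focal subset
    assert plausibility(m, F("i")) == pytest.approx(0.1)


@settings(max_examples=200, derandomize=True)
@given(bpas(), st.sampled_from(_NONEMPTY))
def test_belief_plausibility_bounds_and_duality(m, a):
    bel, pl = belief(m, a), plausibility(m, a)
    assert 0.0 <= bel <= pl <= 1.0 + 1e-12
    assert pl == pytest.approx(1.0 - belief(m, OMEGA - a), abs=1e-12)
    assert bel == pytest.approx(brute_belief(dict(m.items()), a), abs=1e-12)
    assert pl == pytest.approx(brute_plausibility(dict(m.items()), a), abs=1e-12)


# --- Dempster combination -------------------------------------------------

def test_combine_two_agreeing_bpas():
    m1 = make_mass({F("M"): 0.8, F("io"): 0.2})
    m2 = make_mass({F("M"): 0.7, F("io"): 0.3})
    # K = 0.8*0.3 + 0.2*0.7 = 0.38; products 0.56 -> {M}, 0.06 -> {i,o}
    out = combine_dempster(m1, m2)
    assert out[F("M")] == pytest.approx(0.56 / 0.62)
    assert out[F("io")] == pytest.approx(0.06 / 0.62)


def test_combine_two_disagreeing_bpas():
    m1 = make_mass({F("i"): 0.8, F("Mo"): 0.2})
    m2 = make_mass({F("M"): 0.7, F("io"): 0.3})
    # K = 0.8*0.7 = 0.56; {i}: 0.24, {M}: 0.14, {o}: 0.06
    out = combine_dempster(m1, m2)
    assert out[F("i")] == pytest.approx(6 / 11)
    assert out[F("M")] == pytest.approx(7 / 22)
    assert out[F("o")] == pytest.approx(3 / 22)


def test_total_conflict_raises():
    with pytest.raises(TotalConflictError):
        combine_dempster(make_mass({F("i"): 1.0}), make_mass({F("M"): 1.0}))


def test_combine_many_requires_input_and_reports_failing_step():
    with pytest.raises(ValueError):
        combine_many([])
    m = make_mass({F("M"): 0.8, F("io"): 0.2})
    assert combine_many([m]) is m
    with pytest.raises(TotalConflictError, match="#2"):
        combine_many([m, make_mass({F("i"): 1.0}), make_mass({F("M"): 1.0})])


def test_repeated_self_combination_reinforces_the_singleton():
    m = make_mass({F("M"): 0.8, F("io"): 0.2})
    prev = 0.8
    acc = m
    for _ in range(4):
        acc = combine_dempster(acc, m)
        assert acc[F("M")] > prev
        prev = acc[F("M")]
    assert combine_many([m] * 5)[F("M")] == pytest.approx(prev)


@settings(max_examples=150, derandomize=True)
@given(bpas(), bpas())
def test_combination_is_valid_and_commutative(m1, m2):
    try:
        out = combine_dempster(m1, m2)
    except TotalConflictError:
        assume(False)
    assert sum(w for _, w in out.items()) == pytest.approx(1.0, abs=1e-9)
    assert all(a for a in out)  # no empty focal element
    assert out.allclose(combine_dempster(m2, m1), tol=1e-9)


@settings(max_examples=100, derandomize=True)
@given(bpas(), bpas(), bpas())
def test_combination_is_associative_and_order_invariant(m1, m2, m3):
    try:
        a = combine_dempster(combine_dempster(m1, m2), m3)
        b = combine_dempster(m1, combine_dempster(m2, m3))
    except TotalConflictError:
        assume(False)
    assert a.allclose(b, tol=1e-9)
    assert combine_many([m1, m2, m3]).allclose(combine_many([m3, m1, m2]), tol=1e-9)


@settings(max_examples=100, derandomize=True)
@given(bpas())
def test_vacuous_is_the_neutral_element(m):
    assert combine_dempster(m, vacuous()).allclose(m, tol=1e-12)


# --- pignistic transformation ---------------------------------------------

def test_pignistic_hand_examples():
    assert pignistic(vacuous()) == pytest.approx({"i": 1 / 3, "M": 1 / 3, "o": 1 / 3})
    singletons = make_mass({F("i"): 0.2, F("M"): 0.5, F("o"): 0.3})
    assert pignistic(singletons) == pytest.approx({"i": 0.2, "M": 0.5, "o": 0.3})
    assert pignistic(make_mass({F("M"): 0.6, F("io"): 0.4})) == pytest.approx(
        {"i": 0.2, "M": 0.6, "o": 0.2}
    )


@settings(max_examples=200, derandomize=True)
@given(bpas())
def test_pignistic_is_a_distribution_between_bel_and_pl(m):
    betp = pignistic(m)
    assert all(v >= 0 for v in betp.values())
    assert sum(betp.values()) == pytest.approx(1.0, abs=1e-9)
    for c in CLASSES:
        assert belief(m, F(c)) - 1e-12 <= betp[c] <= plausibility(m, F(c)) + 1e-12
    assert betp == pytest.approx(brute_pignistic(dict(m.items())))
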