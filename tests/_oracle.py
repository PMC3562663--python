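"""Independent brute-force oracles for the Dempster-Shafer machinery.

Everything here is deliberately written from first principles over the
explicit 2^3 power set, without importing any production combination
code, so it can serve as an independent cross-check.
"""

from itertools import chain, combinations

CLASSES = ("i", "M", "o")

#: every subset of {i, M, o}, including the empty set
POWER_SET = [
    frozenset(s) for s in chain.from_iterable(combinations(CLASSES, r) for r in range(4))
]


def brute_combine(m1: dict, m2: dict) -> dict:
    """Orthogonal sum by explicit double loop over the full power set."""
    unnorm = {a: 0.0 for a in POWER_SET}
    for b in POWER_SET:
        for c in POWER_SET:
            unnorm[b & c] += m1.get(b, 0.0) * m2.get(c, 0.0)
    conflict = unnorm[frozenset()]
    if conflict >= 1.0:
        raise ZeroDivisionError("total conflict")
    return {
        a: w / (1.0 - conflict)
        for a, w in unnorm.items()
        if a and w > 0.0
    }


def brute_combine_many(masses: list[dict]) -> dict:
    acc = masses[0]
    for m in masses[1:]:
        acc = brute_combine(acc, m)
    return acc


def brute_belief(m: dict, a: frozenset) -> float:
    return sum(w for b, w in m.items() if b <= a)


def brute_plausibility(m: dict, a: frozenset) -> float:
    return sum(w for b, w in m.items() if b & a)


def brute_pignistic(m: dict) -> dict:
    betp = {c: 0.0 for c in CLASSES}
    for a, w in m.items():
        for c in a:
            betp[c] += w / len(a)
    return betp


def brute_decide(labels: tuple[str, ...], rc: float) -> str:
    """Fuse unanimous-rate BPAs for a label pattern and decide by max BetP.

    One two-focal BPA per predictor: mass ``rc`` on the predicted
    singleton, ``1 - rc`` on the complement pair.  Ties break in
    canonical (i, M, o) order.
    """
    masses = [
        {frozenset({lab}): rc, frozenset(CLASSES) - {lab}: 1.0 - rc} for lab in labels
    ]
    betp = brute_pignistic(brute_combine_many(masses))
    best = CLASSES[0]
    for c in CLASSES[1:]:
        if betp[c] > betp[best] + 1e-12:  # drift-safe canonical tie-break
            best = c
    return best


def random_bpa(rng) -> dict:
    """A random valid BPA over a random nonempty focal set.

    The full frame is always a focal element, which guarantees every
    pair of generated BPAs has conflict K < 1.
    """
    proper = [a for a in POWER_SET if a and a != frozenset(CLASSES)]
    k = int(rng.integers(0, len(proper) + 1))
    chosen = [proper[j] for j in rng.choice(len(proper), size=k, replace=False)]
    chosen.append(frozenset(CLASSES))
    weights = rng.dirichlet([1.0] * len(chosen))
    return dict(zip(chosen, weights.tolist()))
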