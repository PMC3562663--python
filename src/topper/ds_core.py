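"""Dempster-Shafer algebra over the three-class residue frame.

The frame of discernment is the fixed set of residue classes
Omega = {i, M, o} (intracellular, transmembrane, extracellular).
Propositions are subsets of Omega represented as ``frozenset`` of the
single-character class labels; a mass function (basic probability
assignment, BPA) maps propositions to masses in [0, 1] with zero mass
on the empty set and total mass one.

The internals work for any finite frame, but only the three-class
frame is part of the supported API and the only one exercised by the
test suite.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

__all__ = [
    "CLASSES",
    "OMEGA",
    "Proposition",
    "MassFunction",
    "MassFunctionError",
    "TotalConflictError",
    "make_mass",
    "belief",
    "plausibility",
    "combine_dempster",
    "combine_many",
    "pignistic",
]

#: Canonical residue-class order, used for every matrix layout,
#: serialization and tie-break in the package.
CLASSES: tuple[str, ...] = ("i", "M", "o")

Proposition = frozenset

#: The full frame {i, M, o}.
OMEGA: Proposition = frozenset(CLASSES)

#: Tolerance for "masses sum to one" on construction.
MASS_TOL = 1e-9

#: Conflict this close to 1 is treated as total conflict.
CONFLICT_TOL = 1e-12


class MassFunctionError(ValueError):
    """Raised for an invalid basic probability assignment."""


class TotalConflictError(ArithmeticError):
    """Dempster's rule is undefined: the two BPAs are in total conflict (K = 1)."""


def _as_proposition(subset: Iterable[str]) -> Proposition:
    prop = frozenset(subset)
    unknown = prop - OMEGA
    if unknown:
        raise MassFunctionError(
            f"proposition {sorted(prop)} contains labels outside the frame "
            f"{CLASSES}: {sorted(unknown)}"
        )
    return prop


def _format_proposition(prop: Proposition) -> str:
    return "|".join(c for c in CLASSES if c in prop) if prop else "EMPTY"


class MassFunction:
    """A validated basic probability assignment on the frame {i, M, o}.

    Immutable mapping from propositions (frozensets of class labels) to
    masses.  Zero-mass entries are dropped, so ``focal_elements`` is
    exactly the support.
    """

    __slots__ = ("_masses",)

    def __init__(self, masses: Mapping[Iterable[str], float]):
        cleaned: dict[Proposition, float] = {}
        for subset, mass in masses.items():
            prop = _as_proposition(subset)
            mass = float(mass)
            if mass < 0:
                raise MassFunctionError(f"negative mass {mass} on {_format_proposition(prop)}")
            if mass == 0.0:
                continue
            if not prop:
                raise MassFunctionError("nonzero mass on the empty set")
            cleaned[prop] = cleaned.get(prop, 0.0) + mass
        total = sum(cleaned.values())
        if abs(total - 1.0) > MASS_TOL:
            raise MassFunctionError(f"masses sum to {total!r}, not 1 (tolerance {MASS_TOL})")
        self._masses = cleaned

    def __getitem__(self, subset: Iterable[str]) -> float:
        return self._masses.get(frozenset(subset), 0.0)

    def __iter__(self):
        return iter(self._masses)

    def __len__(self) -> int:
        return len(self._masses)

    def items(self):
        return self._masses.items()

    @property
    def focal_elements(self) -> frozenset[Proposition]:
        return frozenset(self._masses)

    def allclose(self, other: "MassFunction", tol: float = MASS_TOL) -> bool:
        props = self.focal_elements | other.focal_elements
        return all(abs(self[p] - other[p]) <= tol for p in props)

    def to_dict(self) -> dict[str, float]:
        """Serialize as {"i|M|o-joined subset": mass} in canonical order."""
        ordered = sorted(self._masses, key=lambda p: (len(p), [CLASSES.index(c) for c in sorted(p, key=CLASSES.index)]))
        return {_format_proposition(p): self._masses[p] for p in ordered}

    def __repr__(self) -> str:
        body = ", ".join(f"{{{k}}}: {v:.6g}" for k, v in self.to_dict().items())
        return f"MassFunction({body})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, MassFunction):
            return NotImplemented
        return self._masses == other._masses

    def __hash__(self):
        return hash(frozenset(self._masses.items()))


def make_mass(assignments: Mapping[Iterable[str], float]) -> MassFunction:
    """Build a validated mass function from ``{subset: mass}``.

    Raises :class:`MassFunctionError` if any mass is negative, the empty
    set carries nonzero mass, or the masses do not sum to one within
    ``1e-9``.
    """
    return MassFunction(assignments)


def vacuous() -> MassFunction:
    """The vacuous BPA m(Omega) = 1: total ignorance, neutral element of Dempster's rule."""
    return MassFunction({OMEGA: 1.0})


def belief(m: MassFunction, a: Iterable[str]) -> float:
    """Bel(A) = sum of m(B) over focal elements B that are subsets of A."""
    prop = _as_proposition(a)
    return sum(mass for b, mass in m.items() if b <= prop)


def plausibility(m: MassFunction, a: Iterable[str]) -> float:
    """Pl(A) = sum of m(B) over focal elements B intersecting A = 1 - Bel(not A)."""
    prop = _as_proposition(a)
    return sum(mass for b, mass in m.items() if b & prop)


def combine_dempster(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's rule of combination (orthogonal sum) of two BPAs.

    The conflict K is the total product mass on empty intersections;
    the combined mass on each nonempty A is the product mass over pairs
    intersecting to A, renormalized by 1 - K.  Raises
    :class:`TotalConflictError` when K >= 1 - 1e-12, where the rule is
    not applicable.
    """
    combined: dict[Proposition, float] = {}
    conflict = 0.0
    for b, mb in m1.items():
        for c, mc in m2.items():
            inter = b & c
            w = mb * mc
            if inter:
                combined[inter] = combined.get(inter, 0.0) + w
            else:
                conflict += w
    if conflict >= 1.0 - CONFLICT_TOL:
        raise TotalConflictError(
            f"total conflict between BPAs (K = {conflict!r}); Dempster's rule requires K < 1"
        )
    # Normalize by the realized nonempty product mass rather than 1 - K:
    # identical in exact arithmetic, but keeps the result summing to 1
    # to machine precision.
    total = sum(combined.values())
    return MassFunction({a: w / total for a, w in combined.items()})


def combine_many(ms: Sequence[MassFunction]) -> MassFunction:
    """Left fold of :func:`combine_dempster` over one or more BPAs.

    The orthogonal sum is commutative and associative, so the result is
    independent of input order up to floating-point drift.  A total
    conflict at any pairwise step raises :class:`TotalConflictError`
    reporting the failing step.
    """
    if not ms:
        raise ValueError("combine_many requires at least one mass function")
    acc = ms[0]
    for step, m in enumerate(ms[1:], start=1):
        try:
            acc = combine_dempster(acc, m)
        except TotalConflictError as exc:
            raise TotalConflictError(
                f"total conflict while folding in mass function #{step} "
                f"(0-based index {step}): {exc}"
            ) from exc
    return acc


def pignistic(m: MassFunction) -> dict[str, float]:
    """Pignistic probability transformation BetP of a valid BPA.

    Each focal element's mass is split equally among its members:
    BetP(x) = sum over focal A containing x of m(A) / |A|.  For a valid
    BPA m(empty) = 0, so no further renormalization is needed.  Returns
    a dict over the classes in canonical order.
    """
    betp = {c: 0.0 for c in CLASSES}
    for a, mass in m.items():
        share = mass / len(a)
        for c in a:
            betp[c] += share
    return betp
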