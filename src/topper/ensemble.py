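"""Per-residue fusion of multiple predictors' label tracks.

Each predictor's label at a residue is looked up in its profile to get
the matched BPA; the BPAs are fused with Dempster's rule, turned into
a probability distribution by the pignistic transformation, and the
residue class is decided by argmax (ties broken in canonical
(i, M, o) order).  Residues are fused independently — any smoothing
over positions happens only later, in topology decoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from topper.bpa import PredictorProfile, lookup_bpa
from topper.ds_core import CLASSES, MassFunction, TotalConflictError, combine_many, pignistic

__all__ = ["PredictionTrack", "CombinedResidue", "combine_residue", "combine_tracks"]

ENSEMBLE_ID = "ensemble"


@dataclass(frozen=True)
class PredictionTrack:
    """One predictor's per-residue labels for one sequence."""

    predictor_id: str
    sequence_id: str
    labels: str

    def __post_init__(self):
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(
                f"track {self.predictor_id!r}/{self.sequence_id!r} contains "
                f"labels outside {CLASSES}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class CombinedResidue:
    """Fused evidence for one residue: mass, pignistic triple, decision."""

    mass: MassFunction
    betp: dict[str, float]
    decided: str


#: Probabilities within this distance are a tie (broken canonically);
#: guards symmetric patterns against floating-point drift.
TIE_TOL = 1e-12


def _argmax_canonical(betp: Mapping[str, float]) -> str:
    # ties (within TIE_TOL) break to the earliest class in canonical order
    best = CLASSES[0]
    for c in CLASSES[1:]:
        if betp[c] > betp[best] + TIE_TOL:
            best = c
    return best


def combine_residue(
    predicted_labels: Mapping[str, str],
    profiles: Mapping[str, PredictorProfile],
) -> CombinedResidue:
    """Fuse one residue's predicted labels from several predictors.

    ``predicted_labels`` maps predictor id to its i/M/o label; every
    predictor must have a profile.  Raises
    :class:`~topper.ds_core.TotalConflictError` (naming the predictors)
    if the matched BPAs are in total conflict, which can only happen
    with categorical BPAs (Rc exactly 0 or 1).
    """
    if not predicted_labels:
        raise ValueError("combine_residue requires at least one predictor")
    ids = sorted(predicted_labels)
    missing = [p for p in ids if p not in profiles]
    if missing:
        raise ValueError(f"no profile for predictors {missing}")
    masses = [lookup_bpa(profiles[p], predicted_labels[p]) for p in ids]
    try:
        fused = combine_many(masses)
    except TotalConflictError as exc:
        raise TotalConflictError(
            f"total conflict fusing predictors {ids} with labels "
            f"{[predicted_labels[p] for p in ids]}: {exc}"
        ) from exc
    betp = pignistic(fused)
    return CombinedResidue(mass=fused, betp=betp, decided=_argmax_canonical(betp))


def combine_tracks(
    tracks: Sequence[PredictionTrack],
    profiles: Mapping[str, PredictorProfile],
    ensemble_id: str = ENSEMBLE_ID,
    details: bool = False,
) -> PredictionTrack | tuple[PredictionTrack, list[CombinedResidue]]:
    """Fuse whole label tracks position by position.

    All tracks must share the sequence id and length.  Returns the
    fused track, plus the per-residue :class:`CombinedResidue` list
    when ``details`` is true.
    """
    if not tracks:
        raise ValueError("combine_tracks requires at least one track")
    seq_id = tracks[0].sequence_id
    length = len(tracks[0])
    for t in tracks[1:]:
        if t.sequence_id != seq_id:
            raise ValueError(f"sequence id mismatch: {t.sequence_id!r} vs {seq_id!r}")
        if len(t) != length:
            raise ValueError(
                f"track length mismatch for {seq_id!r}: {t.predictor_id!r} has "
                f"{len(t)} labels, expected {length}"
            )
    per_residue: list[CombinedResidue] = []
    decided = []
    # Profiles are fixed across positions, so the fusion depends only on
    # the label pattern: memoize over the at most 3^N distinct patterns.
    cache: dict[tuple[str, ...], CombinedResidue] = {}
    for pos in range(length):
        pattern = tuple(t.labels[pos] for t in tracks)
        combined = cache.get(pattern)
        if combined is None:
            combined = combine_residue(
                {t.predictor_id: lab for t, lab in zip(tracks, pattern)}, profiles
            )
            cache[pattern] = combined
        decided.append(combined.decided)
        if details:
            per_residue.append(combined)
    fused_track = PredictionTrack(predictor_id=ensemble_id, sequence_id=seq_id, labels="".join(decided))
    return (fused_track, per_residue) if details else fused_track
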