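"""Basic probability assignments built from predictor confusion matrices.

A predictor's reliability is summarized by its 3x3 confusion matrix
(rows = true class, columns = predicted class, both in canonical
(i, M, o) order).  Its overall recognition rate Rc — the trace over the
grand total — turns each abstract-level prediction into a two-focal
BPA: when the predictor outputs class p, mass Rc goes to {p} and the
remaining 1 - Rc goes to the complement doubleton Omega \\ {p} (not to
the whole frame; the complement carries the information "if the
predictor is wrong, the truth is one of the other two classes").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from topper.ds_core import CLASSES, OMEGA, MassFunction

__all__ = [
    "ConfusionMatrix",
    "PredictorProfile",
    "recognition_rate",
    "build_profile",
    "lookup_bpa",
    "smooth_matrix",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 residue confusion counts for one predictor.

    ``counts[p, q]`` is the number of residues of true class
    ``CLASSES[p]`` predicted as ``CLASSES[q]``.
    """

    counts: np.ndarray
    predictor_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3):
            raise ValueError(f"confusion matrix must be 3x3, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("confusion matrix counts must be nonnegative")
        arr = arr.astype(np.int64) if np.issubdtype(arr.dtype, np.integer) else arr.astype(float)
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConfusionMatrix):
            return NotImplemented
        return self.predictor_id == other.predictor_id and np.array_equal(self.counts, other.counts)


@dataclass(frozen=True)
class PredictorProfile:
    """The per-class BPA set of one predictor.

    ``bpas[p]`` is the mass function used whenever the predictor
    outputs class ``p``; ``recognition_rate`` is the predictor's
    overall accuracy Rc that parameterizes all three BPAs.
    """

    predictor_id: str
    bpas: dict[str, MassFunction]
    recognition_rate: float = field(default=0.0)

    def __post_init__(self):
        missing = set(CLASSES) - set(self.bpas)
        if missing:
            raise ValueError(f"profile {self.predictor_id!r} lacks BPAs for classes {sorted(missing)}")


def recognition_rate(cm: ConfusionMatrix) -> float:
    """Overall recognition rate Rc: trace of the matrix over the grand total."""
    total = cm.total
    if total <= 0:
        raise ValueError(f"confusion matrix {cm.predictor_id!r} has zero total count")
    return float(np.trace(cm.counts)) / total


def build_profile(cm: ConfusionMatrix) -> PredictorProfile:
    """Construct the class-conditioned BPA set from a confusion matrix.

    For each class p the BPA has focal elements {p} with mass Rc and
    the complement Omega \\ {p} with mass 1 - Rc.  At Rc = 0 or Rc = 1
    the BPA degenerates to a single focal element (and a categorical
    BPA can produce total conflict downstream; see
    :func:`smooth_matrix`).
    """
    rc = recognition_rate(cm)
    bpas = {
        p: MassFunction({frozenset({p}): rc, OMEGA - {p}: 1.0 - rc})
        for p in CLASSES
    }
    return PredictorProfile(predictor_id=cm.predictor_id, bpas=bpas, recognition_rate=rc)


def lookup_bpa(profile: PredictorProfile, predicted: str) -> MassFunction:
    """Return the matched BPA for an abstract-level predicted label."""
    try:
        return profile.bpas[predicted]
    except KeyError:
        raise ValueError(
            f"unknown predicted label {predicted!r} for predictor "
            f"{profile.predictor_id!r}; expected one of {CLASSES}"
        ) from None


def smooth_matrix(cm: ConfusionMatrix, pseudocount: float) -> ConfusionMatrix:
    """Add a Laplace pseudocount to every cell.

    ``pseudocount=0`` is the identity and the default everywhere in the
    package; a positive value keeps Rc strictly inside (0, 1) so the
    resulting BPAs can never be categorical.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be nonnegative, got {pseudocount}")
    if pseudocount == 0:
        return cm
    return ConfusionMatrix(counts=np.asarray(cm.counts) + pseudocount, predictor_id=cm.predictor_id)
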