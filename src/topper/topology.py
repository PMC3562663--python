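"""Decoding label strings into topology models and comparing them.

A topology model is the ordered list of transmembrane helix segments
(1-based inclusive residue coordinates) plus the membrane side of the
N-terminus ("in" or "out").  Decoding keeps every maximal run of 'M'
whose length reaches a configurable minimum (default 5 residues);
shorter runs are merged into the adjacent loop, preserving residue
count.  The orientation is read off the first non-M label.
"""

from __future__ import annotations

from dataclasses import dataclass
from topper.ds_core import CLASSES

__all__ = [
    "Segment",
    "TopologyModel",
    "DEFAULT_MIN_TM_LENGTH",
    "decode_labels",
    "labels_from_topology",
    "same_topology",
    "segment_overlap",
]

#: Default minimum TM segment length (residues) for decoding; a run of
#: 'M' shorter than this is treated as noise and folded into the loop.
DEFAULT_MIN_TM_LENGTH = 5

_SIDE_OF_LABEL = {"i": "in", "o": "out"}
_LABEL_OF_SIDE = {"in": "i", "out": "o"}


@dataclass(frozen=True, order=True)
class Segment:
    """One TM helix: 1-based inclusive start/end residue indices."""

    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid segment ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1


def segment_overlap(a: Segment, b: Segment) -> int:
    """Number of residues shared by two segments (0 if disjoint)."""
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


@dataclass(frozen=True)
class TopologyModel:
    """Decoded topology: N-terminal side plus ordered TM segments.

    ``n_term_side`` is ``None`` only for the degenerate all-M sequence,
    where the orientation is undefined.
    """

    sequence_id: str
    n_term_side: str | None
    segments: tuple[Segment, ...]
    length: int

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.n_term_side not in ("in", "out", None):
            raise ValueError(f"n_term_side must be 'in', 'out' or None, got {self.n_term_side!r}")
        prev_end = 0
        for seg in self.segments:
            if seg.start <= prev_end:
                raise ValueError(f"segments overlap or are out of order at ({seg.start}, {seg.end})")
            prev_end = seg.end
        if self.segments and self.segments[-1].end > self.length:
            raise ValueError("segment extends past sequence length")

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def _m_runs(labels: str) -> list[tuple[int, int]]:
    """Maximal runs of 'M' as 0-based [start, end) pairs."""
    runs = []
    start = None
    for idx, lab in enumerate(labels):
        if lab == "M":
            if start is None:
                start = idx
        elif start is not None:
            runs.append((start, idx))
            start = None
    if start is not None:
        runs.append((start, len(labels)))
    return runs


def decode_labels(
    labels: str,
    min_tm_length: int = DEFAULT_MIN_TM_LENGTH,
    sequence_id: str = "",
) -> TopologyModel:
    """Decode an i/M/o label string into a :class:`TopologyModel`.

    Maximal runs of 'M' at least ``min_tm_length`` long become TM
    segments; shorter runs are relabeled to the preceding loop class
    (the following loop class when the run starts the sequence).  The
    N-terminal side is "in"/"out" according to the first non-M label;
    an all-M sequence has no defined orientation (``n_term_side=None``).
    """
    if not labels:
        raise ValueError("cannot decode an empty label sequence")
    bad = set(labels) - set(CLASSES)
    if bad:
        raise ValueError(f"labels contain symbols outside {CLASSES}: {sorted(bad)}")
    if min_tm_length < 1:
        raise ValueError("min_tm_length must be a positive integer")

    segments = [
        Segment(start + 1, end)  # to 1-based inclusive
        for start, end in _m_runs(labels)
        if end - start >= min_tm_length
    ]
    first_non_m = next((lab for lab in labels if lab != "M"), None)
    n_term_side = _SIDE_OF_LABEL[first_non_m] if first_non_m is not None else None
    return TopologyModel(
        sequence_id=sequence_id,
        n_term_side=n_term_side,
        segments=tuple(segments),
        length=len(labels),
    )


def labels_from_topology(topo: TopologyModel) -> str:
    """Inverse of :func:`decode_labels` for clean topologies.

    TM segments become 'M'; loops alternate sides starting from the
    N-terminal side.
    """
    if topo.n_term_side is None:
        if topo.n_segments == 1 and topo.segments[0] == Segment(1, topo.length):
            return "M" * topo.length
        raise ValueError("cannot reconstruct labels without an N-terminal side")
    side = _LABEL_OF_SIDE[topo.n_term_side]
    other = "o" if side == "i" else "i"
    out = []
    pos = 1
    for seg in topo.segments:
        out.append(side * (seg.start - pos))
        out.append("M" * len(seg))
        pos = seg.end + 1
        side, other = other, side
    out.append(side * (topo.length - pos + 1))
    return "".join(out)


def same_topology(
    predicted: TopologyModel,
    observed: TopologyModel,
    min_overlap: int = 9,
) -> bool:
    """Whether a predicted topology reproduces the observed one.

    True iff the two models have the same number of TM segments, the
    in-order pairing overlaps by at least ``min_overlap`` residues for
    every pair, and the N-terminal sides agree (an undefined side never
    matches).
    """
    if predicted.n_segments != observed.n_segments:
        return False
    if predicted.n_term_side is None or predicted.n_term_side != observed.n_term_side:
        return False
    return all(
        segment_overlap(p, o) >= min_overlap
        for p, o in zip(predicted.segments, observed.segments)
    )
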