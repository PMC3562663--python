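"""Synthetic membrane-protein topologies and noisy predictor tracks.

The generator emulates the statistical structure the fusion method
assumes: each protein is an alternating loop/helix architecture
(labels i/M/o), and each simulated predictor corrupts the true labels
with a known row-stochastic confusion matrix, optionally preceded by
structural noise (whole-helix deletions, boundary jitter).  Because the
corruption law is known exactly, every downstream estimate — confusion
matrices, recognition rates, fusion gains — can be checked against
analytic values.

Defaults mirror the scale of a typical curated benchmark: 125
proteins with 1-14 TM helices of 15-30 residues separated by loops of
1-60 residues (about 4 helices per protein on average).  Amino-acid
content is uniform random; sequence content never enters any
downstream computation, only the labels do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from topper.ds_core import CLASSES
from topper.ensemble import PredictionTrack
from topper.evaluation import confusion_from_predictions
from topper.io_formats import SequenceRecord, write_confusion, write_fasta, write_labels
from topper.topology import Segment, TopologyModel

__all__ = [
    "SimSpec",
    "SimulatedDataset",
    "DEFAULT_PREDICTOR_PROBS",
    "simulate_truth",
    "corrupt_track",
    "simulate_dataset",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_IDX = {c: k for k, c in enumerate(CLASSES)}


def _default_probs() -> dict[str, np.ndarray]:
    # Five predictors at ~78% residue accuracy with loop/helix error
    # structure (loops are mostly confused with the membrane class and
    # with each other, helices with both loop sides).
    base = np.array(
        [
            [0.84, 0.05, 0.11],
            [0.14, 0.74, 0.12],
            [0.14, 0.07, 0.79],
        ]
    )
    return {f"P{k + 1}": base.copy() for k in range(5)}


#: Default simulated predictor bank: five conditionally independent
#: predictors with per-residue accuracy around 0.78.
DEFAULT_PREDICTOR_PROBS = _default_probs()


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic benchmark generator."""

    n_proteins: int = 125
    helix_count: tuple[int, int] = (1, 14)
    helix_length: tuple[int, int] = (15, 30)
    loop_length: tuple[int, int] = (1, 60)
    predictors: dict[str, np.ndarray] = field(default_factory=_default_probs)
    deletion_prob: float = 0.0
    jitter: int = 0
    min_tm_length: int = 5
    seed: int = 0

    def __post_init__(self):
        for name, (lo, hi) in (
            ("helix_count", self.helix_count),
            ("helix_length", self.helix_length),
            ("loop_length", self.loop_length),
        ):
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} range ({lo}, {hi}) must satisfy 1 <= lo <= hi")
        if self.helix_length[0] < self.min_tm_length:
            raise ValueError(
                f"minimum helix length {self.helix_length[0]} is below the TM "
                f"decoding threshold {self.min_tm_length}: generated helices "
                "would not survive decoding"
            )
        if not 0.0 <= self.deletion_prob <= 1.0:
            raise ValueError("deletion_prob must be in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")
        for pid, probs in self.predictors.items():
            _check_stochastic(probs, pid)


def _check_stochastic(probs: np.ndarray, pid: str) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if arr.shape != (3, 3) or np.any(arr < 0) or np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError(f"confusion probabilities for {pid!r} must be 3x3 row-stochastic")
    return arr


@dataclass(frozen=True)
class SimulatedDataset:
    """Everything one simulation run produces."""

    spec: SimSpec
    sequences: list[SequenceRecord]
    truths: list[TopologyModel]
    observed: list[PredictionTrack]
    predictions: dict[str, list[PredictionTrack]]


def _simulate_protein(rng: np.random.Generator, spec: SimSpec, seq_id: str):
    n_helix = int(rng.integers(spec.helix_count[0], spec.helix_count[1] + 1))
    side = "in" if rng.integers(2) == 0 else "out"
    loop_lens = rng.integers(spec.loop_length[0], spec.loop_length[1] + 1, size=n_helix + 1)
    helix_lens = rng.integers(spec.helix_length[0], spec.helix_length[1] + 1, size=n_helix)

    labels = []
    segments = []
    loop_lab = "i" if side == "in" else "o"
    pos = 1
    for k in range(n_helix):
        labels.append(loop_lab * int(loop_lens[k]))
        pos += int(loop_lens[k])
        segments.append(Segment(pos, pos + int(helix_lens[k]) - 1))
        labels.append("M" * int(helix_lens[k]))
        pos += int(helix_lens[k])
        loop_lab = "o" if loop_lab == "i" else "i"
    labels.append(loop_lab * int(loop_lens[n_helix]))
    label_str = "".join(labels)

    residues = "".join(
        _AMINO_ACIDS[k] for k in rng.integers(len(_AMINO_ACIDS), size=len(label_str))
    )
    topo = TopologyModel(
        sequence_id=seq_id, n_term_side=side, segments=tuple(segments), length=len(label_str)
    )
    return (
        SequenceRecord(id=seq_id, residues=residues),
        topo,
        PredictionTrack(predictor_id="observed", sequence_id=seq_id, labels=label_str),
    )


def simulate_truth(spec: SimSpec) -> tuple[list[SequenceRecord], list[TopologyModel], list[PredictionTrack]]:
    """Generate ground-truth sequences, topologies and label tracks.

    Deterministic under ``spec.seed``; all discrete draws use the
    integer machinery of numpy's PCG64 generator.
    """
    rng = np.random.default_rng(spec.seed)
    seqs, topos, tracks = [], [], []
    for n in range(spec.n_proteins):
        seq, topo, track = _simulate_protein(rng, spec, f"sim{n + 1:04d}")
        seqs.append(seq)
        topos.append(topo)
        tracks.append(track)
    return seqs, topos, tracks


def _structural_corruption(
    labels: str, rng: np.random.Generator, deletion_prob: float, jitter: int
) -> str:
    if deletion_prob == 0.0 and jitter == 0:
        return labels
    chars = list(labels)
    n = len(chars)
    # maximal M runs as 0-based inclusive (start, end)
    runs: list[tuple[int, int]] = []
    start = None
    for k, ch in enumerate(labels):
        if ch == "M" and start is None:
            start = k
        elif ch != "M" and start is not None:
            runs.append((start, k - 1))
            start = None
    if start is not None:
        runs.append((start, n - 1))

    for ridx, (s, e) in enumerate(runs):
        left_lab = labels[s - 1] if s > 0 else (labels[e + 1] if e + 1 < n else "i")
        right_lab = labels[e + 1] if e + 1 < n else left_lab
        if rng.random() < deletion_prob:
            for k in range(s, e + 1):
                chars[k] = left_lab
            continue
        if jitter:
            left_limit = runs[ridx - 1][1] + 2 if ridx > 0 else 0
            right_limit = runs[ridx + 1][0] - 2 if ridx + 1 < len(runs) else n - 1
            ns = int(np.clip(s + rng.integers(-jitter, jitter + 1), left_limit, e))
            ne = int(np.clip(e + rng.integers(-jitter, jitter + 1), ns, right_limit))
            for k in range(min(s, ns), max(e, ne) + 1):
                if ns <= k <= ne:
                    chars[k] = "M"
                elif k < ns:
                    chars[k] = left_lab
                else:
                    chars[k] = right_lab
    return "".join(chars)


def corrupt_track(
    truth: PredictionTrack,
    confusion_probs: np.ndarray,
    jitter: int = 0,
    deletion_prob: float = 0.0,
    seed: int | np.random.Generator = 0,
    predictor_id: str = "sim",
) -> PredictionTrack:
    """Produce one simulated predictor's track from a true label track.

    Structural noise first (whole-helix deletion with probability
    ``deletion_prob``, then boundary jitter of up to ``jitter``
    residues per end), then independent per-residue resampling from
    the confusion row of the (structurally corrupted) label.  With no
    structural noise this is exactly per-residue resampling from the
    truth row, so the empirical confusion of output vs. truth converges
    to ``confusion_probs``.
    """
    probs = _check_stochastic(confusion_probs, predictor_id)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = _structural_corruption(truth.labels, rng, deletion_prob, jitter)
    idx = np.array([_IDX[c] for c in base])
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(base))
    picked = (u[:, None] > cum[idx]).sum(axis=1)
    labels = "".join(CLASSES[k] for k in picked)
    return PredictionTrack(predictor_id=predictor_id, sequence_id=truth.sequence_id, labels=labels)


def simulate_dataset(spec: SimSpec, out_dir: str | Path | None = None) -> SimulatedDataset:
    """Generate a full benchmark bundle and optionally write it to disk.

    Writes (when ``out_dir`` is given): ``sequences.fasta``,
    ``observed.lab``, one ``<predictor>.lab`` per simulated predictor
    and one ``<predictor>.cm.tsv`` with its empirical confusion counts
    against the truth.
    """
    seqs, topos, observed = simulate_truth(spec)
    root = np.random.default_rng(spec.seed)
    # independent child streams: one for truth (already used), one per predictor
    predictions: dict[str, list[PredictionTrack]] = {}
    for pid in sorted(spec.predictors):
        child = np.random.default_rng(root.integers(2**31))
        predictions[pid] = [
            corrupt_track(
                t,
                spec.predictors[pid],
                jitter=spec.jitter,
                deletion_prob=spec.deletion_prob,
                seed=child,
                predictor_id=pid,
            )
            for t in observed
        ]
    dataset = SimulatedDataset(
        spec=spec, sequences=seqs, truths=topos, observed=observed, predictions=predictions
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(seqs, out / "sequences.fasta")
        write_labels(observed, out / "observed.lab")
        for pid, tracks in predictions.items():
            write_labels(tracks, out / f"{pid}.lab")
            cm = confusion_from_predictions(tracks, observed, predictor_id=pid)
            write_confusion(cm, out / f"{pid}.cm.tsv")
    return dataset
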