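"""Scoring at residue, TM-region and topology level, plus cross-validation.

Residue level: confusion matrix, per-class recall/precision/F and
overall accuracy.  TM-region level: the segment-overlap rule of
Tusnady and Simon — a predicted and an observed TM region count as a
hit when they share at least 9 residues — with coverage M =
N_cor/N_obs, precision C = N_cor/N_prd and overall prediction power
Q = 100 * sqrt(M * C) (the geometric mean of coverage and precision).
Topology level: fraction of proteins whose TM regions all match and
whose N-terminal orientation is correct.

The cross-validation harness estimates each predictor's confusion
matrix on the training folds only, fuses the held-out fold with the
resulting profiles, and pools metrics over folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from topper.bpa import ConfusionMatrix, build_profile, smooth_matrix
from topper.ds_core import CLASSES
from topper.ensemble import PredictionTrack, combine_tracks
from topper.topology import (
    DEFAULT_MIN_TM_LENGTH,
    TopologyModel,
    decode_labels,
    same_topology,
    segment_overlap,
)

__all__ = [
    "ResidueMetrics",
    "RegionScore",
    "CVResult",
    "DEFAULT_MIN_OVERLAP",
    "confusion_from_predictions",
    "residue_metrics",
    "match_regions",
    "region_scores",
    "topology_accuracy",
    "crossvalidate",
    "round_half_up",
]

#: Minimum predicted/observed TM-region overlap (residues) for a hit.
DEFAULT_MIN_OVERLAP = 9

_IDX = {c: k for k, c in enumerate(CLASSES)}

# byte-value -> class-index lookup for fast label vectorization
_BYTE_IDX = np.full(256, -1, dtype=np.int64)
for _c, _k in _IDX.items():
    _BYTE_IDX[ord(_c)] = _k


def _label_indices(labels: str) -> np.ndarray:
    """Map an i/M/o string to canonical class indices (already validated)."""
    return _BYTE_IDX[np.frombuffer(labels.encode("ascii"), dtype=np.uint8)]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed in report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ResidueMetrics:
    """Per-class recall, precision and F score plus overall accuracy.

    All values are fractions in [0, 1]; a metric whose denominator is
    zero (empty row or column) is ``None`` — undefined, not zero.
    """

    recall: dict[str, float | None]
    precision: dict[str, float | None]
    f_score: dict[str, float | None]
    accuracy: float

    def as_percentages(self) -> dict[str, dict[str, float | None]]:
        """Table-style view: percentages to 2 decimals, F to 4 decimals."""
        pct = lambda v: None if v is None else round_half_up(100.0 * v, 2)
        return {
            "recall": {c: pct(self.recall[c]) for c in CLASSES},
            "precision": {c: pct(self.precision[c]) for c in CLASSES},
            "f_score": {
                c: None if self.f_score[c] is None else round_half_up(self.f_score[c], 4)
                for c in CLASSES
            },
            "accuracy": pct(self.accuracy),
        }


@dataclass(frozen=True)
class RegionScore:
    """TM-region counts and the derived M, C, Q scores."""

    n_obs: int
    n_prd: int
    n_cor: int

    def __post_init__(self):
        if self.n_cor > min(self.n_obs, self.n_prd):
            raise ValueError("n_cor cannot exceed min(n_obs, n_prd)")

    @property
    def m_frac(self) -> float | None:
        """Coverage M = N_cor / N_obs (None when no observed regions)."""
        return self.n_cor / self.n_obs if self.n_obs else None

    @property
    def c_frac(self) -> float | None:
        """Precision C = N_cor / N_prd (None when no predicted regions)."""
        return self.n_cor / self.n_prd if self.n_prd else None

    @property
    def q(self) -> float | None:
        """Overall prediction power Q = 100 * sqrt(M * C), in percent."""
        if self.m_frac is None or self.c_frac is None:
            return None
        return 100.0 * math.sqrt(self.m_frac * self.c_frac)

    def as_percentages(self) -> dict[str, float | None]:
        pct = lambda v: None if v is None else round_half_up(100.0 * v, 2)
        return {
            "M": pct(self.m_frac),
            "C": pct(self.c_frac),
            "Q": None if self.q is None else round_half_up(self.q, 2),
        }


def confusion_from_predictions(
    predicted: Sequence[PredictionTrack],
    observed: Sequence[PredictionTrack],
    predictor_id: str = "",
) -> ConfusionMatrix:
    """Accumulate a 3x3 confusion matrix over matched tracks.

    Tracks are matched by sequence id; every predicted track must have
    an observed partner of identical length.  Rows are the true
    (observed) class, columns the predicted class.
    """
    obs_by_id = {t.sequence_id: t for t in observed}
    counts = np.zeros((3, 3), dtype=np.int64)
    for pred in predicted:
        obs = obs_by_id.get(pred.sequence_id)
        if obs is None:
            raise ValueError(f"no observed track for sequence {pred.sequence_id!r}")
        if len(obs) != len(pred):
            raise ValueError(
                f"length mismatch for {pred.sequence_id!r}: observed {len(obs)}, "
                f"predicted {len(pred)}"
            )
        pair = _label_indices(obs.labels) * 3 + _label_indices(pred.labels)
        counts += np.bincount(pair, minlength=9).reshape(3, 3)
    return ConfusionMatrix(counts=counts, predictor_id=predictor_id)


def residue_metrics(cm: ConfusionMatrix) -> ResidueMetrics:
    """Per-class recall/precision/F and overall accuracy from a confusion matrix."""
    counts = np.asarray(cm.counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot score an all-zero confusion matrix")
    recall: dict[str, float | None] = {}
    precision: dict[str, float | None] = {}
    f_score: dict[str, float | None] = {}
    for c, k in _IDX.items():
        row = counts[k].sum()
        col = counts[:, k].sum()
        r = counts[k, k] / row if row else None
        p = counts[k, k] / col if col else None
        recall[c], precision[c] = r, p
        if r is None or p is None:
            f_score[c] = None
        elif r + p == 0:
            f_score[c] = 0.0
        else:
            f_score[c] = 2.0 * p * r / (p + r)
    return ResidueMetrics(
        recall=recall,
        precision=precision,
        f_score=f_score,
        accuracy=float(np.trace(counts)) / total,
    )


def match_regions(
    predicted: TopologyModel,
    observed: TopologyModel,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> int:
    """Count matched TM regions under the overlap rule.

    Greedy in-order one-to-one matching: a predicted and an observed
    segment match when they share at least ``min_overlap`` residues;
    each segment is used at most once.  Returns the protein's N_cor
    contribution.
    """
    matched = 0
    i = j = 0
    pred, obs = predicted.segments, observed.segments
    while i < len(pred) and j < len(obs):
        if segment_overlap(pred[i], obs[j]) >= min_overlap:
            matched += 1
            i += 1
            j += 1
        elif pred[i].end < obs[j].end:
            i += 1
        else:
            j += 1
    return matched


def region_scores(
    pairs: Sequence[tuple[TopologyModel, TopologyModel]],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> RegionScore:
    """Pool N_obs / N_prd / N_cor over (predicted, observed) pairs."""
    if not pairs:
        raise ValueError("region_scores requires at least one topology pair")
    n_obs = n_prd = n_cor = 0
    for pred, obs in pairs:
        n_prd += pred.n_segments
        n_obs += obs.n_segments
        n_cor += match_regions(pred, obs, min_overlap)
    return RegionScore(n_obs=n_obs, n_prd=n_prd, n_cor=n_cor)


def topology_accuracy(
    pairs: Sequence[tuple[TopologyModel, TopologyModel]],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float:
    """Fraction of proteins whose whole topology is predicted correctly."""
    if not pairs:
        raise ValueError("topology_accuracy requires at least one topology pair")
    hits = sum(same_topology(pred, obs, min_overlap) for pred, obs in pairs)
    return hits / len(pairs)


@dataclass(frozen=True)
class CVResult:
    """Pooled and per-fold output of the cross-validation harness."""

    folds: tuple[tuple[str, ...], ...]
    ensemble_confusion: ConfusionMatrix
    predictor_confusions: dict[str, ConfusionMatrix]
    ensemble_metrics: ResidueMetrics
    predictor_metrics: dict[str, ResidueMetrics]
    region_score: RegionScore
    topology_accuracy: float
    fold_metrics: tuple[ResidueMetrics, ...]
    training_rates: dict[str, tuple[float, ...]]


def _make_folds(ids: Sequence[str], n_folds: int, seed: int) -> list[list[str]]:
    rng = np.random.default_rng(seed)
    order = [ids[k] for k in rng.permutation(len(ids))]
    # contiguous blocks of the shuffled order, sizes differing by at most 1
    return [list(chunk) for chunk in np.array_split(np.array(order, dtype=object), n_folds)]


def crossvalidate(
    observed: Mapping[str, str],
    predictions: Mapping[str, Mapping[str, str]],
    n_folds: int = 10,
    seed: int = 0,
    min_tm_length: int = DEFAULT_MIN_TM_LENGTH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    pseudocount: float = 0.0,
) -> CVResult:
    """K-fold cross-validation of the evidential ensemble.

    ``observed`` maps sequence id to the reference i/M/o label string;
    ``predictions`` maps predictor id to its per-sequence label
    strings.  For each fold, confusion matrices (and hence BPA
    profiles) are estimated from the training folds only, the held-out
    fold is fused, and residue / region / topology metrics are pooled
    over all held-out predictions.  Fully deterministic under ``seed``.
    """
    ids = sorted(observed)
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} proteins for {n_folds} folds, got {len(ids)}")
    for pid, tracks in predictions.items():
        missing = set(ids) - set(tracks)
        if missing:
            raise ValueError(f"predictor {pid!r} lacks predictions for {sorted(missing)[:3]}...")

    obs_tracks = {s: PredictionTrack("observed", s, observed[s]) for s in ids}
    pred_tracks = {
        pid: {s: PredictionTrack(pid, s, tracks[s]) for s in ids}
        for pid, tracks in predictions.items()
    }

    folds = _make_folds(ids, n_folds, seed)
    fused: dict[str, PredictionTrack] = {}
    fold_metrics: list[ResidueMetrics] = []
    training_rates: dict[str, list[float]] = {pid: [] for pid in predictions}

    for fold in folds:
        train_ids = [s for s in ids if s not in set(fold)]
        profiles = {}
        for pid in sorted(predictions):
            cm = confusion_from_predictions(
                [pred_tracks[pid][s] for s in train_ids],
                [obs_tracks[s] for s in train_ids],
                predictor_id=pid,
            )
            cm = smooth_matrix(cm, pseudocount)
            profile = build_profile(cm)
            profiles[pid] = profile
            training_rates[pid].append(profile.recognition_rate)
        fold_fused = [
            combine_tracks([pred_tracks[pid][s] for pid in sorted(predictions)], profiles)
            for s in fold
        ]
        for track in fold_fused:
            fused[track.sequence_id] = track
        fold_cm = confusion_from_predictions(fold_fused, [obs_tracks[s] for s in fold])
        fold_metrics.append(residue_metrics(fold_cm))

    ensemble_cm = confusion_from_predictions(
        [fused[s] for s in ids], list(obs_tracks.values()), predictor_id="ensemble"
    )
    predictor_cms = {
        pid: confusion_from_predictions(
            list(pred_tracks[pid].values()), list(obs_tracks.values()), predictor_id=pid
        )
        for pid in predictions
    }
    topo_pairs = [
        (
            decode_labels(fused[s].labels, min_tm_length, sequence_id=s),
            decode_labels(observed[s], min_tm_length, sequence_id=s),
        )
        for s in ids
    ]
    return CVResult(
        folds=tuple(tuple(f) for f in folds),
        ensemble_confusion=ensemble_cm,
        predictor_confusions=predictor_cms,
        ensemble_metrics=residue_metrics(ensemble_cm),
        predictor_metrics={pid: residue_metrics(cm) for pid, cm in predictor_cms.items()},
        region_score=region_scores(topo_pairs, min_overlap),
        topology_accuracy=topology_accuracy(topo_pairs, min_overlap),
        fold_metrics=tuple(fold_metrics),
        training_rates={pid: tuple(r) for pid, r in training_rates.items()},
    )
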