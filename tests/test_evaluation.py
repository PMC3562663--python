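"""Residue-, region- and topology-level scoring plus the CV harness."""

import numpy as np
import pytest

from topper.ensemble import PredictionTrack
from topper.evaluation import (
    RegionScore,
    confusion_from_predictions,
    crossvalidate,
    match_regions,
    region_scores,
    residue_metrics,
    round_half_up,
    topology_accuracy,
)
from topper.synthetic import SimSpec, simulate_dataset
from topper.topology import Segment, TopologyModel, decode_labels


def track(labels, seq="p1", pid="A"):
    return PredictionTrack(pid, seq, labels)


# --- confusion accumulation ----------------------------------------------

def test_confusion_identity_predictions():
    obs = [track("iiMMMoo", pid="obs"), track("ooMMii", seq="p2", pid="obs")]
    cm = confusion_from_predictions(obs, obs)
    assert np.array_equal(cm.counts, np.diag([4, 5, 4]))


def test_confusion_off_diagonal_cells():
    cm = confusion_from_predictions([track("Mo")], [track("iM", pid="obs")])
    expected = np.zeros((3, 3), dtype=int)
    expected[0, 1] = 1  # true i predicted M
    expected[1, 2] = 1  # true M predicted o
    assert np.array_equal(cm.counts, expected)


def test_confusion_mismatch_errors():
    with pytest.raises(ValueError, match="no observed track"):
        confusion_from_predictions([track("iM")], [track("iM", seq="p9", pid="obs")])
    with pytest.raises(ValueError, match="length mismatch"):
        confusion_from_predictions([track("iMo")], [track("iM", pid="obs")])


def test_confusion_matches_known_flip_rates(rng):
    """Empirical cell frequencies track the simulated corruption law."""
    probs = np.array([[0.8, 0.1, 0.1], [0.15, 0.7, 0.15], [0.05, 0.2, 0.75]])
    n = 60_000
    truth_idx = rng.integers(3, size=n)
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    pred_idx = (u[:, None] > cum[truth_idx]).sum(axis=1)
    classes = np.array(list("iMo"))
    obs = track("".join(classes[truth_idx]), pid="obs")
    pred = track("".join(classes[pred_idx]))
    cm = confusion_from_predictions([pred], [obs])
    rows = cm.counts.sum(axis=1, keepdims=True)
    freq = cm.counts / rows
    se = np.sqrt(probs * (1 - probs) / rows)
    assert np.all(np.abs(freq - probs) <= 3 * se + 1e-12)


# --- residue metrics ------------------------------------------------------

def test_residue_metrics_benchmark_spot_checks(benchmark_cms):
    pct = residue_metrics(benchmark_cms["TOPPER"]).as_percentages()
    assert pct["recall"]["i"] == 85.96
    assert pct["precision"]["i"] == 73.77
    assert pct["f_score"]["i"] == 0.7940
    assert pct["precision"]["M"] == 91.81
    assert pct["f_score"]["M"] == 0.8245
    assert residue_metrics(benchmark_cms["OCTOPUS"]).as_percentages()["accuracy"] == 78.69


def test_residue_metrics_perfect_predictions():
    m = residue_metrics(confusion_from_predictions([track("iiMMMoo")], [track("iiMMMoo", pid="obs")]))
    assert m.accuracy == 1.0
    assert all(v == 1.0 for v in m.recall.values())
    assert all(v == 1.0 for v in m.f_score.values())


def test_residue_metrics_undefined_for_empty_row_or_column():
    # no true or predicted 'o' residues anywhere
    m = residue_metrics(confusion_from_predictions([track("iMiM")], [track("iiMM", pid="obs")]))
    assert m.recall["o"] is None
    assert m.precision["o"] is None
    assert m.f_score["o"] is None
    assert m.as_percentages()["recall"]["o"] is None


def test_round_half_up_ties():
    assert round_half_up(79.985, 2) == 79.99
    assert round_half_up(0.79345, 4) == 0.7935
    assert round_half_up(2.5, 0) == 3.0


# --- region matching ------------------------------------------------------

def overlap_case(pred_segs, obs_segs, length=200):
    pred = TopologyModel("p", "in", tuple(Segment(*s) for s in pred_segs), length)
    obs = TopologyModel("p", "in", tuple(Segment(*s) for s in obs_segs), length)
    return pred, obs


def test_match_regions_nine_residue_boundary():
    pred, obs = overlap_case([(22, 45)], [(10, 30)])
    assert match_regions(pred, obs) == 1  # overlap exactly 9
    pred, obs = overlap_case([(23, 45)], [(10, 30)])
    assert match_regions(pred, obs) == 0  # overlap 8


def test_match_regions_is_one_to_one():
    pred, obs = overlap_case([(10, 60)], [(10, 25), (40, 60)])
    assert match_regions(pred, obs) == 1
    pred, obs = overlap_case([(10, 25), (40, 60)], [(10, 60)])
    assert match_regions(pred, obs) == 1


def test_match_regions_never_exceeds_either_count(rng):
    for _ in range(50):
        def random_segs():
            segs, pos = [], 1
            for _ in range(int(rng.integers(0, 6))):
                pos += int(rng.integers(1, 30))
                end = pos + int(rng.integers(5, 30))
                segs.append((pos, end))
                pos = end + 1
            return segs
        pred, obs = overlap_case(random_segs(), random_segs(), length=500)
        n = match_regions(pred, obs)
        assert n <= min(pred.n_segments, obs.n_segments)


# --- region scores --------------------------------------------------------

def test_region_scores_from_benchmark_counts(benchmark_regions):
    assert benchmark_regions["TOPPER"].as_percentages() == {"M": 97.09, "C": 98.62, "Q": 97.85}
    assert benchmark_regions["PRODIV"].as_percentages() == {"M": 97.67, "C": 95.99, "Q": 96.83}


def test_region_scores_pools_over_proteins():
    a = overlap_case([(10, 30)], [(12, 32)])
    b = overlap_case([(10, 30), (50, 70)], [(12, 32)])
    score = region_scores([a, b])
    assert (score.n_obs, score.n_prd, score.n_cor) == (2, 3, 2)


def test_region_score_geometric_mean_bounds(rng):
    for _ in range(100):
        n_obs, n_prd = int(rng.integers(1, 50)), int(rng.integers(1, 50))
        n_cor = int(rng.integers(0, min(n_obs, n_prd) + 1))
        s = RegionScore(n_obs, n_prd, n_cor)
        m, c = 100 * s.m_frac, 100 * s.c_frac
        assert min(m, c) - 1e-9 <= s.q <= max(m, c) + 1e-9
        assert s.q == pytest.approx(RegionScore(n_prd, n_obs, n_cor).q)  # symmetric in M/C


def test_region_score_validation_and_degenerate_counts():
    with pytest.raises(ValueError):
        RegionScore(3, 3, 4)
    empty = RegionScore(0, 2, 0)
    assert empty.m_frac is None and empty.q is None
    assert empty.as_percentages()["Q"] is None


def test_perfect_region_prediction():
    score = region_scores([overlap_case([(10, 30)], [(10, 30)])])
    assert score.as_percentages() == {"M": 100.0, "C": 100.0, "Q": 100.0}


# --- topology accuracy ----------------------------------------------------

def test_topology_accuracy():
    a = overlap_case([(10, 30)], [(10, 30)])
    flipped = (
        TopologyModel("p", "out", (Segment(10, 30),), 200),
        TopologyModel("p", "in", (Segment(10, 30),), 200),
    )
    assert topology_accuracy([a, a]) == 1.0
    assert topology_accuracy([a, flipped]) == 0.5


# --- cross-validation harness --------------------------------------------

def test_crossvalidate_fold_sizes_and_determinism():
    spec = SimSpec(n_proteins=125, seed=11)
    ds = simulate_dataset(spec)
    observed = {t.sequence_id: t.labels for t in ds.observed}
    predictions = {
        pid: {t.sequence_id: t.labels for t in tracks} for pid, tracks in ds.predictions.items()
    }
    r1 = crossvalidate(observed, predictions, n_folds=10, seed=3)
    assert sorted(len(f) for f in r1.folds) == [12] * 5 + [13] * 5
    assert sorted(s for f in r1.folds for s in f) == sorted(observed)
    r2 = crossvalidate(observed, predictions, n_folds=10, seed=3)
    assert r1.folds == r2.folds
    assert np.array_equal(r1.ensemble_confusion.counts, r2.ensemble_confusion.counts)
    assert r1.region_score == r2.region_score
    r3 = crossvalidate(observed, predictions, n_folds=10, seed=4)
    assert r1.folds != r3.folds


def test_crossvalidate_input_validation():
    obs = {f"p{k}": "iiMMMMMoo" for k in range(5)}
    preds = {"A": dict(obs)}
    with pytest.raises(ValueError, match="at least"):
        crossvalidate(obs, preds, n_folds=10, seed=0)
    with pytest.raises(ValueError):
        crossvalidate(obs, preds, n_folds=1, seed=0)
    with pytest.raises(ValueError, match="lacks predictions"):
        crossvalidate(obs, {"A": {"p0": "iiMMMMMoo"}}, n_folds=2, seed=0)


def test_crossvalidate_recovers_simulated_recognition_rates():
    """Held-out per-predictor accuracy matches the analytic value implied by
    the simulated confusion law, within Monte-Carlo error."""
    spec = SimSpec(n_proteins=60, seed=21)
    ds = simulate_dataset(spec)
    observed = {t.sequence_id: t.labels for t in ds.observed}
    predictions = {
        pid: {t.sequence_id: t.labels for t in tracks} for pid, tracks in ds.predictions.items()
    }
    result = crossvalidate(observed, predictions, n_folds=5, seed=1)
    n_res = sum(len(s) for s in observed.values())
    counts = np.zeros(3)
    idx = {"i": 0, "M": 1, "o": 2}
    for s in observed.values():
        for ch in s:
            counts[idx[ch]] += 1
    class_freq = counts / counts.sum()
    for pid, cm in result.predictor_confusions.items():
        probs = ds.spec.predictors[pid]
        expected = float(class_freq @ np.diag(probs))
        got = np.trace(cm.counts) / cm.counts.sum()
        se = np.sqrt(expected * (1 - expected) / n_res)
        assert abs(got - expected) <= 3 * se
        # training-fold recognition rates sit in the same neighbourhood
        assert abs(np.mean(result.training_rates[pid]) - expected) <= 4 * se
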