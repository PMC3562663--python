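"""Readers and writers for the tool's on-disk formats.

* FASTA protein sequences (standard, via Biopython).
* Label files: FASTA-like records whose "sequence" is the i/M/o label
  string, one character per residue, length-checked against the
  protein sequences.  External predictors' alphabets (e.g. H for
  helix) are handled through an explicit user-supplied dialect map.
* Confusion-matrix TSV: header ``truth<TAB>i<TAB>M<TAB>o`` then one
  integer row per true class, mirroring the canonical (i, M, o) layout.
* Topology report TSV: sequence id, N-terminal side, comma-separated
  ``start-end`` segments.
* YAML run configuration for the cross-validation driver.

All readers validate strictly and fail with file/record context rather
than truncating; all writers emit UTF-8 with Unix newlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO

from topper.bpa import ConfusionMatrix
from topper.ds_core import CLASSES
from topper.ensemble import PredictionTrack
from topper.evaluation import DEFAULT_MIN_OVERLAP, RegionScore, ResidueMetrics
from topper.topology import DEFAULT_MIN_TM_LENGTH, Segment, TopologyModel

__all__ = [
    "SequenceRecord",
    "RunConfig",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "read_confusion",
    "write_confusion",
    "read_topologies",
    "write_topologies",
    "write_residue_report",
    "write_region_report",
    "read_run_config",
]


class FormatError(ValueError):
    """Malformed input file; the message carries file and record context."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str

    def __post_init__(self):
        if not self.id or not self.residues:
            raise FormatError("sequence records need a non-empty id and sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RunConfig:
    """Parsed YAML configuration for a cross-validation run."""

    fasta: Path
    observed: Path
    predictors: dict[str, Path]
    n_folds: int = 10
    seed: int = 0
    min_tm_length: int = DEFAULT_MIN_TM_LENGTH
    min_overlap: int = DEFAULT_MIN_OVERLAP
    pseudocount: float = 0.0
    dialect: dict[str, str] = field(default_factory=dict)
    output: Path | None = None


def _fasta_records(path: str | Path) -> list:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein sequences; ids are the first whitespace-delimited token."""
    out = []
    for rec in _fasta_records(path):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(SequenceRecord(id=rec.id, residues=seq))
    return out


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.residues), width):
                fh.write(rec.residues[k : k + width] + "\n")


def read_labels(
    path: str | Path,
    sequences: Sequence[SequenceRecord],
    predictor_id: str = "",
    dialect: Mapping[str, str] | None = None,
) -> list[PredictionTrack]:
    """Read a FASTA-like label file and validate against the sequences.

    ``dialect`` maps foreign label characters onto the canonical
    alphabet (e.g. ``{"H": "M", "I": "i", "O": "o"}``) and is applied
    before validation.  Every record id must exist among ``sequences``
    and the label string must have exactly one character per residue.
    """
    by_id = {s.id: s for s in sequences}
    mapping = dict(dialect or {})
    tracks = []
    for rec in _fasta_records(path):
        seq = by_id.get(rec.id)
        if seq is None:
            raise FormatError(f"{path}: labels for unknown sequence {rec.id!r}")
        raw = str(rec.seq)
        labels = "".join(mapping.get(ch, ch) for ch in raw)
        if len(labels) != len(seq):
            raise FormatError(
                f"{path}: record {rec.id!r} has {len(labels)} labels for a "
                f"{len(seq)}-residue sequence"
            )
        for pos, ch in enumerate(labels, start=1):
            if ch not in CLASSES:
                raise FormatError(
                    f"{path}: record {rec.id!r} position {pos}: unknown label "
                    f"{ch!r} (after dialect mapping); expected one of {CLASSES}"
                )
        tracks.append(PredictionTrack(predictor_id=predictor_id, sequence_id=rec.id, labels=labels))
    return tracks


def write_labels(tracks: Sequence[PredictionTrack], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for track in tracks:
            fh.write(f">{track.sequence_id}\n")
            for k in range(0, len(track.labels), width):
                fh.write(track.labels[k : k + width] + "\n")


_CM_HEADER = ["truth", *CLASSES]


def read_confusion(path: str | Path, predictor_id: str = "") -> ConfusionMatrix:
    """Read a 3x3 confusion-matrix TSV (rows = truth, columns = prediction)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [ln.rstrip("\r") for ln in lines if ln.strip()]
    if not rows or rows[0].split("\t") != _CM_HEADER:
        raise FormatError(f"{path}: line 1: expected header {'TAB'.join(_CM_HEADER)!r}")
    if len(rows) != 4:
        raise FormatError(f"{path}: expected 3 data rows, found {len(rows) - 1}")
    counts = np.zeros((3, 3), dtype=np.int64)
    for k, row in enumerate(rows[1:], start=2):
        cells = row.split("\t")
        if len(cells) != 4 or cells[0] != CLASSES[k - 2]:
            raise FormatError(
                f"{path}: line {k}: expected row label {CLASSES[k - 2]!r} and 3 counts"
            )
        for j, cell in enumerate(cells[1:]):
            try:
                counts[k - 2, j] = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: line {k}: non-integer count {cell!r}"
                ) from None
    return ConfusionMatrix(counts=counts, predictor_id=predictor_id)


def write_confusion(cm: ConfusionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_CM_HEADER) + "\n")
        for k, c in enumerate(CLASSES):
            fh.write(c + "\t" + "\t".join(str(int(v)) for v in np.asarray(cm.counts)[k]) + "\n")


def read_topologies(path: str | Path) -> list[TopologyModel]:
    """Read a topology report TSV (id, length, n_term_side, segments)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [ln.rstrip("\r") for ln in lines if ln.strip()]
    if not rows or rows[0].split("\t") != ["sequence_id", "length", "n_term_side", "segments"]:
        raise FormatError(f"{path}: line 1: bad topology report header")
    models = []
    for k, row in enumerate(rows[1:], start=2):
        cells = row.split("\t")
        if len(cells) != 4:
            raise FormatError(f"{path}: line {k}: expected 4 tab-separated fields")
        seq_id, length_s, side, segs_s = cells
        side_val = None if side == "undefined" else side
        try:
            segments = tuple(
                Segment(*(int(x) for x in part.split("-")))
                for part in segs_s.split(",")
                if part
            )
            models.append(
                TopologyModel(
                    sequence_id=seq_id,
                    n_term_side=side_val,
                    segments=segments,
                    length=int(length_s),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {k}: {exc}") from None
    return models


def write_topologies(models: Sequence[TopologyModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sequence_id\tlength\tn_term_side\tsegments\n")
        for t in models:
            segs = ",".join(f"{s.start}-{s.end}" for s in t.segments)
            side = t.n_term_side if t.n_term_side is not None else "undefined"
            fh.write(f"{t.sequence_id}\t{t.length}\t{side}\t{segs}\n")


def _fmt(v: float | None) -> str:
    return "NA" if v is None else f"{v:.2f}"


def write_residue_report(metrics: Mapping[str, ResidueMetrics], path: str | Path) -> None:
    """Write per-predictor residue metrics as a TSV table (percent scale)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("predictor\tclass\trecall_pct\tprecision_pct\tf_score\taccuracy_pct\n")
        for pid, m in metrics.items():
            table = m.as_percentages()
            for c in CLASSES:
                f = table["f_score"][c]
                fh.write(
                    f"{pid}\t{c}\t{_fmt(table['recall'][c])}\t{_fmt(table['precision'][c])}\t"
                    f"{'NA' if f is None else f'{f:.4f}'}\t{_fmt(table['accuracy'])}\n"
                )


def write_region_report(scores: Mapping[str, RegionScore], path: str | Path) -> None:
    """Write per-predictor TM-region scores as a TSV table."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("predictor\tn_obs\tn_prd\tn_cor\tM_pct\tC_pct\tQ_pct\n")
        for pid, s in scores.items():
            p = s.as_percentages()
            fh.write(
                f"{pid}\t{s.n_obs}\t{s.n_prd}\t{s.n_cor}\t{_fmt(p['M'])}\t{_fmt(p['C'])}\t{_fmt(p['Q'])}\n"
            )


def read_run_config(path: str | Path) -> RunConfig:
    """Parse the YAML cross-validation configuration.

    Expected keys: ``fasta``, ``observed``, ``predictors`` (mapping id
    -> label file), and optional ``n_folds``, ``seed``,
    ``min_tm_length``, ``min_overlap``, ``pseudocount``, ``dialect``,
    ``output``.  Paths are resolved relative to the config file.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    base = path.parent
    try:
        predictors = {str(k): base / str(v) for k, v in raw["predictors"].items()}
        cfg = RunConfig(
            fasta=base / str(raw["fasta"]),
            observed=base / str(raw["observed"]),
            predictors=predictors,
            n_folds=int(raw.get("n_folds", 10)),
            seed=int(raw.get("seed", 0)),
            min_tm_length=int(raw.get("min_tm_length", DEFAULT_MIN_TM_LENGTH)),
            min_overlap=int(raw.get("min_overlap", DEFAULT_MIN_OVERLAP)),
            pseudocount=float(raw.get("pseudocount", 0.0)),
            dialect={str(k): str(v) for k, v in raw.get("dialect", {}).items()},
            output=(base / str(raw["output"])) if "output" in raw else None,
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing required config key {exc}") from None
    if len(predictors) < 1:
        raise FormatError(f"{path}: at least one predictor is required")
    if cfg.min_tm_length < 1 or cfg.min_overlap < 1:
        raise FormatError(f"{path}: thresholds must be positive")
    for p in [cfg.fasta, cfg.observed, *predictors.values()]:
        if not Path(p).is_file():
            raise FormatError(f"{path}: referenced file does not exist: {p}")
    return cfg
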