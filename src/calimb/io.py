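"""Delimited score-file dialect: ``id,label,score[,true_prob]``, UTF-8 CSV.

Labels must be 0/1 and probabilities must be finite decimals in [0, 1];
malformed rows are rejected with their line number.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .exceptions import ScoreFileError
from .synthetic import ScoreSet

_REQUIRED = ("id", "label", "score")


def _parse_prob(raw: str, column: str, lineno: int, path) -> float:
    try:
        value = float(raw)
    except ValueError as exc:
        raise ScoreFileError(f"{path}:{lineno}: {column} {raw!r} is not a number") from exc
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ScoreFileError(f"{path}:{lineno}: {column}={raw} outside [0, 1]")
    return value


def read_scores(path: str | Path) -> ScoreSet:
    """Read and validate a score file."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise ScoreFileError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        missing = [col for col in _REQUIRED if col not in header]
        if missing:
            raise ScoreFileError(f"{path}: header missing column(s) {', '.join(missing)}")
        col = {name: header.index(name) for name in header}
        has_true = "true_prob" in col
        ids, labels, scores, true_probs = [], [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ScoreFileError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            raw_label = row[col["label"]].strip()
            if raw_label not in ("0", "1"):
                raise ScoreFileError(f"{path}:{lineno}: label {raw_label!r} not in {{0, 1}}")
            ids.append(row[col["id"]])
            labels.append(int(raw_label))
            scores.append(_parse_prob(row[col["score"]].strip(), "score", lineno, path))
            if has_true:
                true_probs.append(
                    _parse_prob(row[col["true_prob"]].strip(), "true_prob", lineno, path)
                )
    if not labels:
        raise ScoreFileError(f"{path}: no data rows")
    return ScoreSet(
        ids=np.array(ids),
        labels=np.array(labels),
        scores=np.array(scores),
        true_probs=np.array(true_probs) if has_true else None,
        meta={"source": str(path)},
    )


def write_scores(score_set: ScoreSet, path: str | Path) -> None:
    """Write a score file; floats use ``repr`` so round trips are exact."""
    path = Path(path)
    has_true = score_set.true_probs is not None
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["id", "label", "score"] + (["true_prob"] if has_true else []))
        for i in range(len(score_set)):
            row = [str(score_set.ids[i]), str(int(score_set.labels[i])), repr(float(score_set.scores[i]))]
            if has_true:
                row.append(repr(float(score_set.true_probs[i])))
            writer.writerow(row)
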