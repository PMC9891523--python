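"""Peptide-level scoring of de novo predictions.

The headline metric is *peptide recall*: the fraction of ground-truth
peptides whose full sequence was predicted correctly.  Computed over a whole
test set it measures a model's generalizability (*global* recall); computed
per source enzyme it exposes cleavage-pattern bias (*local* recall).  Two
derived views localise where predictions fail: recall as a function of the
maximum peptide length admitted, and recall over subsets filtered on minimum
b- and y-ion recall (spectrum quality).

Correctness is positional identity under an equivalence policy.  By default
Ile and Leu are interchangeable — they are isobaric and indistinguishable by
mass alone — while modified tokens must match exactly and near-isobars such
as Gln/Lys (0.036 Da apart, resolvable at 15 ppm) are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import tokenize
from .ion_recall import IonRecallRecord

__all__ = [
    "EquivalencePolicy",
    "PredictionRecord",
    "RecallGrid",
    "peptide_correct",
    "evaluate_records",
    "peptide_recall",
    "recall_vs_maxlen",
    "recall_grid",
]


@dataclass(frozen=True)
class EquivalencePolicy:
    """Which residue tokens count as the same during sequence comparison."""

    ile_leu_equivalent: bool = True

    def canonical(self, token: str) -> str:
        if self.ile_leu_equivalent and token in ("I", "L"):
            return "I"
        return token

    def tokens_equal(self, a: Sequence[str], b: Sequence[str]) -> bool:
        return len(a) == len(b) and all(
            self.canonical(x) == self.canonical(y) for x, y in zip(a, b)
        )


DEFAULT_POLICY = EquivalencePolicy()


@dataclass(frozen=True)
class PredictionRecord:
    spectrum_id: str
    predicted: str  # modified-sequence string; empty = no prediction
    truth: str
    source_enzyme: str = ""
    correct: bool | None = None  # filled by evaluate_records


def peptide_correct(
    predicted: Sequence[str] | str,
    truth: Sequence[str] | str,
    policy: EquivalencePolicy = DEFAULT_POLICY,
) -> bool:
    """Whole-sequence correctness under the equivalence policy.

    An empty or absent prediction is incorrect, never an error: spectra the
    predictor declined still sit in the recall denominator.
    """
    if isinstance(truth, str):
        truth = tokenize(truth) if truth else []
    if not truth:
        raise ValueError("truth sequence must be non-empty")
    if isinstance(predicted, str):
        predicted = tokenize(predicted) if predicted else []
    if not predicted:
        return False
    return policy.tokens_equal(predicted, truth)


def evaluate_records(
    records: Iterable[PredictionRecord],
    policy: EquivalencePolicy = DEFAULT_POLICY,
) -> list[PredictionRecord]:
    """Fill the ``correct`` flag on every record."""
    return [
        replace(r, correct=peptide_correct(r.predicted, r.truth, policy))
        for r in records
    ]


def _require_evaluated(records: Sequence[PredictionRecord]) -> None:
    if any(r.correct is None for r in records):
        raise ValueError("records must be evaluated first (correct flag unset)")


def peptide_recall(
    records: Sequence[PredictionRecord],
    group_by: str | None = None,
    policy: EquivalencePolicy = DEFAULT_POLICY,
) -> float | dict[str, float]:
    """Correct fraction, globally or per source enzyme.

    Records with an unset ``correct`` flag are evaluated on the fly.
    """
    if not records:
        raise ValueError("no prediction records to score")
    if any(r.correct is None for r in records):
        records = evaluate_records(records, policy)
    if group_by is None:
        return sum(r.correct for r in records) / len(records)
    if group_by != "source_enzyme":
        raise ValueError("group_by must be None or 'source_enzyme'")
    groups: dict[str, list[PredictionRecord]] = {}
    for r in records:
        groups.setdefault(r.source_enzyme, []).append(r)
    return {k: sum(r.correct for r in v) / len(v) for k, v in sorted(groups.items())}


def recall_vs_maxlen(
    records: Sequence[PredictionRecord],
    lengths: Sequence[int],
    policy: EquivalencePolicy = DEFAULT_POLICY,
) -> pd.DataFrame:
    """Peptide recall restricted to truths of length ≤ each cut-off.

    Returns a tidy frame (max_length, n, recall); recall is NaN where no
    record qualifies.
    """
    if any(r.correct is None for r in records):
        records = evaluate_records(records, policy)
    true_len = np.array([len(tokenize(r.truth)) for r in records])
    correct = np.array([bool(r.correct) for r in records])
    rows = []
    for lmax in lengths:
        mask = true_len <= lmax
        n = int(mask.sum())
        rows.append(
            {
                "max_length": int(lmax),
                "n": n,
                "recall": float(correct[mask].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecallGrid:
    """Peptide recall over subsets with b/y ion recall above threshold pairs.

    ``cell_recall[i, j]`` is the recall over records with
    ``b_recall >= b_thresholds[i]`` and ``y_recall >= y_thresholds[j]``;
    NaN marks empty (undefined) cells, reported by ``cell_count``.
    """

    b_thresholds: np.ndarray
    y_thresholds: np.ndarray
    cell_recall: np.ndarray
    cell_count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, bt in enumerate(self.b_thresholds):
            for j, yt in enumerate(self.y_thresholds):
                rows.append(
                    {
                        "min_b_recall": float(bt),
                        "min_y_recall": float(yt),
                        "n": int(self.cell_count[i, j]),
                        "recall": float(self.cell_recall[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def recall_grid(
    records: Sequence[PredictionRecord],
    ion_records: Sequence[IonRecallRecord],
    b_step: float = 0.1,
    y_step: float = 0.1,
    policy: EquivalencePolicy = DEFAULT_POLICY,
) -> RecallGrid:
    """Peptide recall as a function of minimum b/y-ion recall thresholds."""
    if any(r.correct is None for r in records):
        records = evaluate_records(records, policy)
    ion_by_id = {r.spectrum_id: r for r in ion_records}
    unjoined = [r.spectrum_id for r in records if r.spectrum_id not in ion_by_id]
    if unjoined:
        raise KeyError(f"prediction records without ion-recall records: {sorted(set(unjoined))}")
    b = np.array([ion_by_id[r.spectrum_id].b_recall for r in records])
    y = np.array([ion_by_id[r.spectrum_id].y_recall for r in records])
    correct = np.array([bool(r.correct) for r in records])
    b_thr = np.round(np.arange(0.0, 1.0 + 1e-9, b_step), 10)
    y_thr = np.round(np.arange(0.0, 1.0 + 1e-9, y_step), 10)
    recall = np.full((len(b_thr), len(y_thr)), np.nan)
    count = np.zeros((len(b_thr), len(y_thr)), dtype=int)
    for i, bt in enumerate(b_thr):
        for j, yt in enumerate(y_thr):
            mask = (b >= bt) & (y >= yt)
            n = int(mask.sum())
            count[i, j] = n
            if n:
                recall[i, j] = correct[mask].mean()
    return RecallGrid(b_thr, y_thr, recall, count)
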