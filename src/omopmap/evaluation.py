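"""Score mapping results against an expert gold standard.

The operationalization follows standard binary-classification practice for
terminology-mapping tools evaluated over a sweep of similarity cutoffs: per
query the prediction is the rank-1 candidate; at cutoff *t* the prediction is
*asserted* iff its similarity is >= *t*.

* asserted and concept equals gold           → TP
* asserted and concept differs (or gold is NONE) → FP
* not asserted (or no candidates), gold is NONE  → TN
* not asserted, gold names a concept             → FN

This makes recall monotone non-increasing in the cutoff while precision
saturates as weak predictions drop out — the familiar shape of a
threshold-sweep table.  The rank-based AUC is the Mann–Whitney statistic:
the probability that a randomly chosen correctly-mapped query outscores a
randomly chosen incorrectly-mapped one, ties counting one half.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from omopmap.errors import ContractError, InputError, SchemaError
from omopmap.matcher import MappingResult

#: Cutoffs of the canonical threshold-sweep table.
DEFAULT_CUTOFFS = (0.85, 0.88, 0.90, 0.92, 0.95, 0.97, 0.99)


@dataclass
class GoldStandard:
    """Expert-adjudicated mapping: query identifier → concept_id or None.

    ``None`` means the reviewers judged that no valid concept mapping exists
    for the query (an explicit negative, not a missing entry).
    """

    entries: dict[str, Optional[int]]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, query_id: str) -> bool:
        return query_id in self.entries

    def expected(self, query_id: str) -> Optional[int]:
        return self.entries[query_id]

    @classmethod
    def from_csv(cls, path: str | Path) -> "GoldStandard":
        """Read a gold CSV with columns query_id, concept_id (empty = NONE)."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"gold standard not found: {path}")
        entries: dict[str, Optional[int]] = {}
        with open(path, encoding="utf-8-sig", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "query_id" not in reader.fieldnames:
                raise SchemaError(f"gold standard {path} missing column 'query_id'")
            if "concept_id" not in reader.fieldnames:
                raise SchemaError(f"gold standard {path} missing column 'concept_id'")
            for row in reader:
                qid = row["query_id"].strip()
                if not qid:
                    continue
                if qid in entries:
                    raise ContractError(f"duplicate query_id {qid!r} in gold standard")
                raw = (row["concept_id"] or "").strip()
                entries[qid] = int(raw) if raw else None
        return cls(entries=entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["query_id", "concept_id"])
            for qid, cid in self.entries.items():
                writer.writerow([qid, "" if cid is None else cid])


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts at one similarity cutoff."""

    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ThresholdMetrics:
    """One row of a threshold-sweep table."""

    cutoff: float
    precision: float
    recall: float
    f1: float


def _check_coverage(results: Sequence[MappingResult], gold: GoldStandard) -> None:
    missing = [r.query_key for r in results if r.query_key not in gold]
    if missing:
        raise ContractError(f"queries absent from gold standard: {missing}")


def classify_at_cutoff(
    results: Sequence[MappingResult], gold: GoldStandard, cutoff: float
) -> ConfusionCounts:
    """Confusion counts over all results at one similarity cutoff.

    The prediction for each query is its rank-1 candidate; see the module
    docstring for the TP/FP/FN/TN rules.  Every result's query identifier
    must be present in the gold standard.
    """
    _check_coverage(results, gold)
    tp = fp = fn = tn = 0
    for result in results:
        expected = gold.expected(result.query_key)
        top = result.top
        asserted = top is not None and top.similarity >= cutoff
        if asserted:
            if expected is not None and top.concept.concept_id == expected:
                tp += 1
            else:
                fp += 1
        else:
            if expected is None:
                tn += 1
            else:
                fn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, cutoff=cutoff)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def precision_recall_f1(counts: ConfusionCounts) -> ThresholdMetrics:
    """Precision, recall and F1 from confusion counts (degenerate → 0)."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return ThresholdMetrics(
        cutoff=counts.cutoff,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
    )


def threshold_sweep(
    results: Sequence[MappingResult],
    gold: GoldStandard,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> list[ThresholdMetrics]:
    """One metrics row per cutoff, in the given order, from a single matching pass.

    Candidate lists are cutoff-independent, so the same results are rescored
    at every cutoff with no re-matching.
    """
    if not cutoffs:
        raise ContractError("cutoffs must be nonempty")
    return [precision_recall_f1(classify_at_cutoff(results, gold, c)) for c in cutoffs]


def rank_auc(results: Sequence[MappingResult], gold: GoldStandard) -> Optional[float]:
    """Rank-based AUC over per-query top-1 scores.

    Each query is labeled 1 if its rank-1 concept equals the gold concept,
    else 0; its score is the rank-1 similarity (0 for candidate-less
    queries).  The AUC is the probability that a random positive outscores a
    random negative, ties counting one half (Mann–Whitney formulation via
    rank sums).  Returns None when every query has the same label (AUC
    undefined).
    """
    _check_coverage(results, gold)
    labels = []
    scores = []
    for result in results:
        expected = gold.expected(result.query_key)
        top = result.top
        correct = (
            top is not None and expected is not None and top.concept.concept_id == expected
        )
        labels.append(1 if correct else 0)
        scores.append(top.similarity if top is not None else 0.0)
    labels_arr = np.asarray(labels)
    scores_arr = np.asarray(scores, dtype=np.float64)
    n_pos = int(labels_arr.sum())
    n_neg = len(labels_arr) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores_arr)  # average ranks handle ties as 1/2
    rank_sum_pos = float(ranks[labels_arr == 1].sum())
    u_statistic = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u_statistic / (n_pos * n_neg)


def write_sweep_csv(
    rows: Sequence[ThresholdMetrics],
    counts: Sequence[ConfusionCounts],
    path: str | Path,
    auc: Optional[float] = None,
) -> None:
    """Write a threshold-sweep report CSV (cutoff, precision, recall, f1, counts)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cutoff", "precision", "recall", "f1", "tp", "fp", "fn", "tn"])
        for metrics, cc in zip(rows, counts):
            writer.writerow(
                [
                    f"{metrics.cutoff:g}",
                    f"{metrics.precision:.4f}",
                    f"{metrics.recall:.4f}",
                    f"{metrics.f1:.4f}",
                    cc.tp,
                    cc.fp,
                    cc.fn,
                    cc.tn,
                ]
            )
        if auc is not None:
            writer.writerow(["auc", f"{auc:.4f}", "", "", "", "", "", ""])
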