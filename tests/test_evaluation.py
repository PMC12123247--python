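"""Confusion-count rules, P/R/F1, threshold sweep, and rank-based AUC."""

import numpy as np
import pytest

from omopmap.errors import ContractError
from omopmap.evaluation import (
    ConfusionCounts,
    GoldStandard,
    classify_at_cutoff,
    precision_recall_f1,
    rank_auc,
    threshold_sweep,
)
from omopmap.fixtures import demo_concepts
from omopmap.matcher import MappingResult, MatchCandidate


def make_result(query_id, concept, similarity, tier="embedding"):
    candidates = []
    if concept is not None:
        candidates = [
            MatchCandidate(concept=concept, similarity=similarity, tier=tier, rank=1)
        ]
    return MappingResult(
        query_term=query_id, normalized_query=query_id, field_id=query_id, candidates=candidates
    )


@pytest.fixture
def concepts():
    return {c.concept_id: c for c in demo_concepts()}


class TestClassifyAtCutoff:
    def test_all_correct_exact_predictions(self, concepts):
        results = [
            make_result(f"q{i}", concepts[2001 + i], 1.0, tier="exact") for i in range(3)
        ]
        gold = GoldStandard(entries={f"q{i}": 2001 + i for i in range(3)})
        cc = classify_at_cutoff(results, gold, 0.85)
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (3, 0, 0, 0)

    def test_cutoff_above_all_scores_gives_all_fn(self, concepts):
        results = [make_result(f"q{i}", concepts[2001], 1.0, "exact") for i in range(4)]
        gold = GoldStandard(entries={f"q{i}": 2001 for i in range(4)})
        cc = classify_at_cutoff(results, gold, 1.01)
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (0, 0, 4, 0)

    def test_four_way_fixture(self, concepts):
        # correct@0.95, wrong@0.90, correct@0.80, gold-NONE@0.70 at cutoff 0.85
        results = [
            make_result("a", concepts[2001], 0.95),
            make_result("b", concepts[2002], 0.90),
            make_result("c", concepts[2003], 0.80),
            make_result("d", concepts[2004], 0.70),
        ]
        gold = GoldStandard(entries={"a": 2001, "b": 2009, "c": 2003, "d": None})
        cc = classify_at_cutoff(results, gold, 0.85)
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (1, 1, 1, 1)
        assert cc.total == 4

    def test_query_missing_from_gold_is_contract_error(self, concepts):
        results = [make_result("mystery", concepts[2001], 0.9)]
        with pytest.raises(ContractError, match="mystery"):
            classify_at_cutoff(results, GoldStandard(entries={"other": 2001}), 0.85)

    def test_no_candidates_counts_against_gold(self, concepts):
        results = [make_result("a", None, 0.0), make_result("b", None, 0.0)]
        gold = GoldStandard(entries={"a": 2001, "b": None})
        cc = classify_at_cutoff(results, gold, 0.85)
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (0, 0, 1, 1)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected_p,expected_r,expected_f1",
        [
            # 70 mappable queries: one borderline false positive at the loosest
            # cutoff, then four misses once the cutoff tightens — the counts
            # behind the canonical (0.9859, 1) and (1, 0.9429) sweep rows.
            (70, 1, 0, 0.9859, 1.0, 0.9929),
            (66, 0, 4, 1.0, 0.9429, 0.9706),
        ],
    )
    def test_f1_matches_published_threshold_table_rows(
        self, tp, fp, fn, expected_p, expected_r, expected_f1
    ):
        metrics = precision_recall_f1(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0, cutoff=0.85))
        assert metrics.precision == pytest.approx(expected_p, abs=5e-4)
        assert metrics.recall == pytest.approx(expected_r, abs=5e-4)
        assert metrics.f1 == pytest.approx(expected_f1, abs=5e-4)

    def test_counts_to_metrics(self):
        metrics = precision_recall_f1(ConfusionCounts(tp=70, fp=1, fn=0, tn=0, cutoff=0.85))
        assert metrics.precision == pytest.approx(70 / 71)
        assert metrics.recall == 1.0
        assert metrics.f1 == pytest.approx(2 * (70 / 71) / (1 + 70 / 71))

    def test_degenerate_all_zero(self):
        metrics = precision_recall_f1(ConfusionCounts(tp=0, fp=0, fn=0, tn=5, cutoff=0.9))
        assert metrics.precision == metrics.recall == metrics.f1 == 0.0


class TestThresholdSweep:
    def test_perfect_fixture_all_ones(self, concepts):
        results = [make_result(f"q{i}", concepts[2001 + i], 1.0, "exact") for i in range(3)]
        gold = GoldStandard(entries={f"q{i}": 2001 + i for i in range(3)})
        rows = threshold_sweep(results, gold, [0.85, 0.95])
        assert len(rows) == 2
        assert all(r.precision == r.recall == r.f1 == 1.0 for r in rows)

    def test_single_cutoff_equals_composition(self, concepts):
        results = [
            make_result("a", concepts[2001], 0.95),
            make_result("b", concepts[2002], 0.90),
        ]
        gold = GoldStandard(entries={"a": 2001, "b": 2009})
        (row,) = threshold_sweep(results, gold, [0.92])
        composed = precision_recall_f1(classify_at_cutoff(results, gold, 0.92))
        assert row == composed

    def test_recall_non_increasing_across_cutoffs(self, concepts):
        rng = np.random.default_rng(0)
        ids = list(concepts)
        results, entries = [], {}
        for i in range(60):
            cid = ids[i % len(ids)]
            sim = float(rng.uniform(0.5, 1.0))
            wrong = rng.random() < 0.2
            predicted = ids[(i + 1) % len(ids)] if wrong else cid
            results.append(make_result(f"q{i}", concepts[predicted], sim))
            entries[f"q{i}"] = cid
        gold = GoldStandard(entries=entries)
        cutoffs = [0.85, 0.88, 0.90, 0.92, 0.95, 0.97, 0.99]
        counts = [classify_at_cutoff(results, gold, c) for c in cutoffs]
        recalls = [precision_recall_f1(cc).recall for cc in counts]
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))
        # total queries conserved at every cutoff
        assert len({cc.total for cc in counts}) == 1

    def test_empty_cutoffs_rejected(self, concepts):
        with pytest.raises(ContractError):
            threshold_sweep([], GoldStandard(entries={}), [])


def brute_force_auc(labels, scores):
    """Independent oracle: exhaustive pairwise comparison, ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        return None
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRankAuc:
    def _build(self, concepts, labels, scores):
        results, entries = [], {}
        for i, (label, score) in enumerate(zip(labels, scores)):
            qid = f"q{i}"
            results.append(make_result(qid, concepts[2001], score))
            entries[qid] = 2001 if label else 2002
        return results, GoldStandard(entries=entries)

    def test_perfect_separation_is_one(self, concepts):
        results, gold = self._build(concepts, [1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2])
        assert rank_auc(results, gold) == 1.0

    def test_all_tied_scores_is_half(self, concepts):
        results, gold = self._build(concepts, [1, 1, 0, 0], [0.7] * 4)
        assert rank_auc(results, gold) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_fixtures(self, concepts):
        rng = np.random.default_rng(123)
        for _ in range(5):
            n = int(rng.integers(5, 100))
            labels = (rng.random(n) < 0.6).astype(int)
            scores = np.round(rng.uniform(0.5, 1.0, size=n), 2)  # rounding forces ties
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            results, gold = self._build(concepts, labels.tolist(), scores.tolist())
            assert rank_auc(results, gold) == pytest.approx(
                brute_force_auc(labels.tolist(), scores.tolist()), abs=1e-12
            )

    def test_sklearn_cross_check(self, concepts):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        scores = np.round(rng.uniform(0, 1, size=40), 2)
        results, gold = self._build(concepts, labels.tolist(), scores.tolist())
        assert rank_auc(results, gold) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_is_undefined(self, concepts):
        results, gold = self._build(concepts, [1, 1, 1], [0.9, 0.8, 0.7])
        assert rank_auc(results, gold) is None


class TestGoldStandardCsv:
    def test_round_trip_with_none_entries(self, tmp_path):
        gold = GoldStandard(entries={"q1": 2001, "q2": None, "q3": 2004})
        path = tmp_path / "gold.csv"
        gold.to_csv(path)
        assert GoldStandard.from_csv(path).entries == gold.entries
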