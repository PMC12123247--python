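"""Normalization rules and the three-tier matching cascade."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from omopmap.embedding import HashedNgramEmbedder, build_index, cosine_similarity
from omopmap.fixtures import FixtureSpec, generate_vocabulary
from omopmap.matcher import (
    SynonymTable,
    load_synonym_table,
    match_batch,
    match_term,
    normalize_term,
)


class TestNormalizeTerm:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("  Not  Hispanic or Latino ", "not hispanic or latino"),
            ("PAIN", "pain"),
            ('"Marital Status"', "marital status"),
            ("'quoted term'", "quoted term"),
            ("a\t b\n c", "a b c"),
            ("", ""),
            ("   ", ""),
            ("co-morbidity, severe", "co-morbidity, severe"),  # punctuation preserved
        ],
    )
    def test_stated_rules(self, raw, expected):
        assert normalize_term(raw) == expected

    @given(st.text(max_size=60))
    def test_idempotent(self, text):
        once = normalize_term(text)
        assert normalize_term(once) == once


def brute_force_scan(query, provider, collection, k):
    """Independent oracle: exhaustive cosine scan with the declared tie-break."""
    qvec = provider.embed(normalize_term(query))
    scored = []
    for c in collection:
        sim = cosine_similarity(qvec, provider.embed(c.concept_name)) if np.any(qvec) else 0.0
        scored.append((c, sim))
    scored.sort(key=lambda t: (-t[1], 0 if t[0].is_standard else 1, t[0].concept_id))
    return scored[:k]


class TestMatchTerm:
    def test_exact_match_is_rank_one_similarity_one(self, demo_col, demo_index):
        result = match_term("Not Hispanic or Latino", demo_index, demo_col, k=5)
        top = result.candidates[0]
        assert top.concept.concept_code == "LA19555-4"
        assert top.similarity == 1.0 and top.tier == "exact" and top.rank == 1

    def test_exact_match_case_and_whitespace_insensitive(self, demo_col, demo_index):
        result = match_term("  NOT hispanic OR latino ", demo_index, demo_col, k=3)
        assert result.candidates[0].concept.concept_code == "LA19555-4"
        assert result.candidates[0].tier == "exact"

    def test_single_concept_index(self, provider, tmp_path):
        from omopmap.fixtures import demo_concepts
        from omopmap.vocabulary import ConceptCollection

        col = ConceptCollection(concepts=demo_concepts()[:1])
        idx = build_index(col, provider)
        result = match_term("Not Hispanic or Latino", idx, col, k=5)
        assert len(result.candidates) == 1 and result.candidates[0].rank == 1

    def test_ranks_contiguous_similarity_nonincreasing(self, demo_col, demo_index):
        result = match_term("pain", demo_index, demo_col, k=8)
        ranks = [c.rank for c in result.candidates]
        sims = [c.similarity for c in result.candidates]
        assert ranks == list(range(1, len(ranks) + 1))
        assert all(a >= b for a, b in zip(sims, sims[1:]))

    def test_embedding_tier_equals_exhaustive_scan(self, provider, tmp_path):
        spec = FixtureSpec(n_concepts=60, n_queries=1, seed=11)
        _, col = generate_vocabulary(spec, tmp_path / "v.tsv")
        idx = build_index(col, provider)
        for query in ["xq", "chronic pain severity", "marital", "zzz unknown phrase"]:
            got = match_term(query, idx, col, k=10)
            expected = brute_force_scan(query, provider, col, 10)
            assert [c.concept.concept_id for c in got.candidates] == [
                c.concept_id for c, _ in expected
            ]
            for cand, (_, sim) in zip(got.candidates, expected):
                assert cand.similarity == pytest.approx(sim, abs=1e-12)

    def test_cutoff_only_flags_never_reorders(self, demo_col, demo_index):
        lo = match_term("pain intensity scale", demo_index, demo_col, k=5, cutoff=0.0)
        hi = match_term("pain intensity scale", demo_index, demo_col, k=5, cutoff=0.99)
        assert [c.concept.concept_id for c in lo.candidates] == [
            c.concept.concept_id for c in hi.candidates
        ]
        assert [c.similarity for c in lo.candidates] == [c.similarity for c in hi.candidates]
        assert all(not c.sub_threshold for c in lo.candidates)
        assert any(c.sub_threshold for c in hi.candidates)

    def test_empty_query_yields_error_annotation(self, demo_col, demo_index):
        result = match_term('" "', demo_index, demo_col)
        assert result.candidates == [] and result.error is not None

    def test_determinism(self, demo_col, demo_index):
        a = match_term("employment", demo_index, demo_col, k=5)
        b = match_term("employment", demo_index, demo_col, k=5)
        assert [(c.concept.concept_id, c.similarity) for c in a.candidates] == [
            (c.concept.concept_id, c.similarity) for c in b.candidates
        ]

    def test_k_truncates(self, demo_col, demo_index):
        assert len(match_term("pain", demo_index, demo_col, k=2).candidates) == 2


class TestSynonymTier:
    def test_synonym_guaranteed_inclusion(self, demo_col, demo_index):
        # associate an unrelated phrasing with Marital Status (concept 2004)
        table = SynonymTable.from_pairs([("relationship situation", 2004)], demo_col)
        without = match_term("relationship situation", demo_index, demo_col, k=3)
        assert 2004 not in [c.concept.concept_id for c in without.candidates]
        with_syn = match_term("relationship situation", demo_index, demo_col, synonyms=table, k=3)
        cand = {c.concept.concept_id: c for c in with_syn.candidates}
        assert 2004 in cand and cand[2004].tier == "linguistic"

    def test_linguistic_floor_bounds_similarity(self, demo_col, demo_index):
        table = SynonymTable.from_pairs([("zzzz", 2004)], demo_col)
        result = match_term("zzzz", demo_index, demo_col, synonyms=table, k=5, linguistic_floor=0.5)
        cand = {c.concept.concept_id: c for c in result.candidates}
        assert cand[2004].similarity >= 0.5

    def test_exact_tier_wins_over_synonym(self, demo_col, demo_index):
        table = SynonymTable.from_pairs([("marital status", 2001)], demo_col)
        result = match_term("Marital Status", demo_index, demo_col, synonyms=table, k=5)
        assert result.candidates[0].concept.concept_id == 2004
        assert result.candidates[0].tier == "exact"

    def test_load_synonym_table_reports_unresolved(self, demo_col, tmp_path):
        path = tmp_path / "syn.tsv"
        path.write_text(
            "# comment line\nrelationship situation\t2004\nghost entry\t424242\n",
            encoding="utf-8",
        )
        table = load_synonym_table(path, demo_col)
        assert table.lookup("relationship situation") == {2004}
        assert ("ghost entry", 424242) in table.unresolved
        assert table.lookup("ghost entry") == set()


class TestMatchBatch:
    def test_empty_batch(self, demo_col, demo_index):
        assert match_batch([], demo_index, demo_col) == []

    def test_batch_equals_elementwise_match_term(self, demo_col, demo_index):
        triples = [
            ("f1", "a", "Not Hispanic or Latino"),
            ("f1", "b", "marital"),
            (None, None, "exercise angina"),
        ]
        batch = match_batch(triples, demo_index, demo_col, k=4)
        assert [r.query_term for r in batch] == [t[2] for t in triples]
        for (form, fid, term), result in zip(triples, batch):
            single = match_term(term, demo_index, demo_col, k=4, form_id=form, field_id=fid)
            assert [(c.concept.concept_id, c.similarity, c.tier) for c in result.candidates] == [
                (c.concept.concept_id, c.similarity, c.tier) for c in single.candidates
            ]

    def test_duplicate_terms_get_identical_candidates(self, demo_col, demo_index):
        batch = match_batch(
            [(None, "x", "pain"), (None, "y", "pain")], demo_index, demo_col, k=3
        )
        assert [(c.concept.concept_id, c.similarity) for c in batch[0].candidates] == [
            (c.concept.concept_id, c.similarity) for c in batch[1].candidates
        ]

    def test_per_term_failure_recorded_batch_continues(self, demo_col, demo_index):
        batch = match_batch(
            [(None, "x", "pain"), (None, "y", '""'), (None, "z", "fatigue")],
            demo_index,
            demo_col,
        )
        assert len(batch) == 3
        assert batch[1].error is not None
        assert batch[0].candidates and batch[2].candidates
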