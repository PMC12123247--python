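"""The three-tier matching cascade: exact → linguistic association → embedding.

Given a free-text clinical term, the cascade produces ranked candidate
concepts from an OMOP vocabulary collection:

1. **Exact** — every concept whose normalized name is character-identical to
   the normalized query is a candidate with similarity exactly 1.0.
2. **Linguistic** — concepts the synonym table associates with the normalized
   query are guaranteed inclusion; their similarity is the embedding cosine
   (floor-bounded, so a curated association never scores below the floor).
3. **Embedding** — remaining slots are filled by the highest cosine-similarity
   concepts over the whole precomputed index.

The similarity cutoff only *flags* sub-threshold candidates; it never changes
membership or order.  That makes a single matching pass reusable across an
entire threshold sweep during evaluation.

Ties in similarity are broken deterministically: earlier tier first, then
standard concepts before non-standard, then ascending concept_id.
"""

from __future__ import annotations

import logging
import unicodedata
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import numpy as np

from omopmap.errors import InputError
from omopmap.vocabulary import Concept, ConceptCollection

if TYPE_CHECKING:  # avoid a circular import; embedding depends on normalize_term
    from omopmap.embedding import EmbeddingIndex

logger = logging.getLogger(__name__)

#: Human-readable description of normalize_term, recorded in index headers.
NORMALIZATION_SPEC = "NFC; casefold; trim; collapse whitespace runs; strip surrounding quotes"

_QUOTE_CHARS = "\"'‘’“”"

_TIER_ORDER = {"exact": 0, "linguistic": 1, "embedding": 2}


def normalize_term(text: str) -> str:
    """Canonical text form used by the exact tier and by embedding providers.

    Unicode NFC + casefold, leading/trailing whitespace trimmed, internal
    whitespace runs collapsed to single spaces, and symmetric surrounding
    quote characters stripped.  Punctuation is otherwise preserved.
    """
    out = unicodedata.normalize("NFC", text).strip()
    while len(out) >= 2 and out[0] in _QUOTE_CHARS and out[-1] in _QUOTE_CHARS:
        out = out[1:-1].strip()
    out = " ".join(out.split())
    return out.casefold()


@dataclass(frozen=True)
class MatchCandidate:
    """One ranked candidate concept for a query term."""

    concept: Concept
    similarity: float
    tier: str  # "exact" | "linguistic" | "embedding"
    rank: int
    sub_threshold: bool = False

    def __post_init__(self) -> None:
        if self.tier not in _TIER_ORDER:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == "exact" and self.similarity != 1.0:
            raise ValueError("exact-tier candidates must have similarity exactly 1.0")


@dataclass
class MappingResult:
    """A query term with its provenance and ranked candidates."""

    query_term: str
    normalized_query: str
    candidates: list[MatchCandidate] = field(default_factory=list)
    form_id: Optional[str] = None
    field_id: Optional[str] = None
    error: Optional[str] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def query_key(self) -> str:
        """Identifier used to join against a gold standard."""
        return self.field_id if self.field_id else self.query_term

    @property
    def top(self) -> Optional[MatchCandidate]:
        return self.candidates[0] if self.candidates else None


@dataclass
class SynonymTable:
    """Curated linguistic associations: normalized text → concept ids.

    Stands in for richer semantic-network reasoning: any resource that can
    say "this phrasing denotes these concepts" (UMLS synonyms, local code
    lists) reduces to this two-column form.
    """

    entries: dict[str, set[int]] = field(default_factory=dict)
    source: str = ""
    unresolved: list[tuple[str, int]] = field(default_factory=list)

    def lookup(self, normalized_text: str) -> set[int]:
        return self.entries.get(normalized_text, set())

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, int]],
        collection: Optional[ConceptCollection] = None,
        source: str = "",
    ) -> "SynonymTable":
        entries: dict[str, set[int]] = {}
        unresolved: list[tuple[str, int]] = []
        for text, concept_id in pairs:
            key = normalize_term(text)
            if not key:
                continue
            if collection is not None and concept_id not in collection:
                unresolved.append((key, concept_id))
                continue
            entries.setdefault(key, set()).add(concept_id)
        if unresolved:
            logger.warning("synonym table %s: %d unresolved concept references", source, len(unresolved))
        return cls(entries=entries, source=source, unresolved=unresolved)


def load_synonym_table(
    path: str | Path, collection: Optional[ConceptCollection] = None, delimiter: str = "\t"
) -> SynonymTable:
    """Read a two-column (text, concept_id) file; '#' lines are comments.

    Entries referencing a concept_id absent from ``collection`` are reported
    in ``table.unresolved`` rather than loaded.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"synonym table not found: {path}")
    pairs: list[tuple[str, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter in line else line.rsplit(",", 1)
            if len(parts) != 2:
                logger.warning("%s:%d: malformed synonym line skipped", path, lineno)
                continue
            text, raw_id = parts[0].strip(), parts[1].strip()
            try:
                pairs.append((text, int(raw_id)))
            except ValueError:
                logger.warning("%s:%d: non-integer concept_id %r skipped", path, lineno, raw_id)
    return SynonymTable.from_pairs(pairs, collection=collection, source=str(path))


def _sort_key(concept: Concept, similarity: float, tier: str) -> tuple:
    return (
        -similarity,
        _TIER_ORDER[tier],
        0 if concept.is_standard else 1,
        concept.concept_id,
    )


def match_term(
    term: str,
    index: "EmbeddingIndex",
    collection: ConceptCollection,
    synonyms: Optional[SynonymTable] = None,
    k: int = 5,
    cutoff: float = 0.85,
    linguistic_floor: float = 0.0,
    form_id: Optional[str] = None,
    field_id: Optional[str] = None,
) -> MappingResult:
    """Run the full cascade for one query term.

    Returns a :class:`MappingResult` whose candidates are sorted by
    (similarity desc, tier, standard-first, concept_id asc) and truncated to
    ``k``.  Candidates with similarity below ``cutoff`` are retained but
    flagged ``sub_threshold``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    normalized = normalize_term(term)
    result = MappingResult(
        query_term=term, normalized_query=normalized, form_id=form_id, field_id=field_id
    )
    if not normalized:
        result.error = "query is empty after normalization"
        return result
    if len(index) == 0:
        result.warnings.append("empty index: no candidates")
        warnings.warn("matching against an empty index", stacklevel=2)
        return result

    if index.provider is None:
        raise InputError("index has no attached provider; reload it with one")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        query_vec = index.provider.embed(normalized)
    sims = index.similarities(query_vec)
    id_to_row = {int(cid): row for row, cid in enumerate(index.concept_ids)}

    chosen: dict[int, tuple[Concept, float, str]] = {}

    # Tier 1: exact string correspondence on normalized names.
    for concept in collection:
        if normalize_term(concept.concept_name) == normalized:
            chosen[concept.concept_id] = (concept, 1.0, "exact")

    # Tier 2: curated linguistic associations, guaranteed inclusion.
    if synonyms is not None:
        for concept_id in synonyms.lookup(normalized):
            if concept_id in chosen or concept_id not in collection:
                continue
            concept = collection.get(concept_id)
            row = id_to_row.get(concept_id)
            sim = float(sims[row]) if row is not None else 0.0
            sim = max(sim, linguistic_floor)
            chosen[concept_id] = (concept, min(sim, 1.0), "linguistic")

    # Tier 3: fill remaining slots with the top cosine-similarity concepts.
    n_needed = k - len(chosen)
    if n_needed > 0:
        ranked_rows = sorted(
            range(len(sims)),
            key=lambda r: _sort_key(
                collection.get(int(index.concept_ids[r])), float(sims[r]), "embedding"
            ),
        )
        for row in ranked_rows:
            if n_needed == 0:
                break
            concept_id = int(index.concept_ids[row])
            if concept_id in chosen:
                continue
            concept = collection.get(concept_id)
            sim = float(np.clip(sims[row], -1.0, 1.0))
            chosen[concept_id] = (concept, sim, "embedding")
            n_needed -= 1

    ordered = sorted(chosen.values(), key=lambda t: _sort_key(t[0], t[1], t[2]))[:k]
    result.candidates = [
        MatchCandidate(
            concept=concept,
            similarity=sim,
            tier=tier,
            rank=rank,
            sub_threshold=sim < cutoff,
        )
        for rank, (concept, sim, tier) in enumerate(ordered, start=1)
    ]
    return result


def match_batch(
    terms: Sequence[tuple[Optional[str], Optional[str], str]],
    index: "EmbeddingIndex",
    collection: ConceptCollection,
    synonyms: Optional[SynonymTable] = None,
    k: int = 5,
    cutoff: float = 0.85,
    linguistic_floor: float = 0.0,
) -> list[MappingResult]:
    """Map a batch of (form_id, field_id, term) triples, order-preserving.

    Batch is a stateless map: each element equals the corresponding
    :func:`match_term` call.  A per-term failure is recorded in that element's
    ``error`` and the batch continues.
    """
    results: list[MappingResult] = []
    for form_id, field_id, term in terms:
        try:
            results.append(
                match_term(
                    term,
                    index,
                    collection,
                    synonyms=synonyms,
                    k=k,
                    cutoff=cutoff,
                    linguistic_floor=linguistic_floor,
                    form_id=form_id,
                    field_id=field_id,
                )
            )
        except Exception as exc:  # per-term failure must not abort the batch
            results.append(
                MappingResult(
                    query_term=term,
                    normalized_query=normalize_term(term) if isinstance(term, str) else "",
                    form_id=form_id,
                    field_id=field_id,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return results
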