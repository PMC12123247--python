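"""Read, validate, and filter OHDSI Athena-format vocabulary tables.

Athena distributes its CONCEPT table as a tab-delimited file (despite the
``.csv`` name) with ten named columns.  This module loads such a table into an
in-memory :class:`ConceptCollection`, rejecting malformed rows with a per-row
report rather than dropping them silently, and offers subset filtering by
domain, vocabulary, standard-concept status and validity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from omopmap.errors import InputError, IntegrityError, SchemaError

logger = logging.getLogger(__name__)

#: Columns that must be present in a concept table header.
MANDATORY_COLUMNS = (
    "concept_id",
    "concept_name",
    "domain_id",
    "vocabulary_id",
    "standard_concept",
    "concept_code",
    "invalid_reason",
)

#: OHDSI flag -> descriptive status. Empty flag means non-standard.
STANDARD_CONCEPT_FLAGS = {"S": "standard", "C": "classification", "": "non-standard"}
_STATUS_TO_FLAG = {v: k for k, v in STANDARD_CONCEPT_FLAGS.items()}

_DATE_SENTINELS = {"": None}


@dataclass(frozen=True)
class Concept:
    """One row of the Athena CONCEPT table.

    ``standard_concept`` is the descriptive status ("standard",
    "classification", "non-standard"), not the raw one-letter flag.
    A concept is *currently valid* iff ``invalid_reason`` is None.
    """

    concept_id: int
    concept_name: str
    domain_id: str
    vocabulary_id: str
    concept_class_id: str
    standard_concept: str
    concept_code: str
    valid_start_date: date
    valid_end_date: date
    invalid_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.concept_id <= 0:
            raise ValueError(f"concept_id must be positive, got {self.concept_id}")
        if not self.concept_name:
            raise ValueError("concept_name must be nonempty")
        if self.standard_concept not in _STATUS_TO_FLAG:
            raise ValueError(f"unknown standard_concept status {self.standard_concept!r}")
        if self.valid_start_date > self.valid_end_date:
            raise ValueError(
                f"concept {self.concept_id}: valid_start_date after valid_end_date"
            )

    @property
    def is_valid(self) -> bool:
        return self.invalid_reason is None

    @property
    def is_standard(self) -> bool:
        return self.standard_concept == "standard"


@dataclass(frozen=True)
class RejectedRow:
    """A data row the reader could not turn into a Concept."""

    row_number: int  # 1-based, counting data rows (header excluded)
    reason: str
    raw: str


@dataclass
class ConceptCollection:
    """Ordered collection of concepts with exact lookup by concept_id."""

    concepts: list[Concept]
    source_path: str = ""
    rejected: list[RejectedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id: dict[int, Concept] = {}
        for c in self.concepts:
            if c.concept_id in self._by_id:
                raise IntegrityError(f"duplicate concept_id {c.concept_id}")
            self._by_id[c.concept_id] = c

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self) -> Iterator[Concept]:
        return iter(self.concepts)

    def __contains__(self, concept_id: int) -> bool:
        return concept_id in self._by_id

    def get(self, concept_id: int) -> Concept:
        try:
            return self._by_id[concept_id]
        except KeyError:
            raise KeyError(f"concept_id {concept_id} not in collection") from None

    def find_by_code(self, vocabulary_id: str, concept_code: str) -> Optional[Concept]:
        """Linear lookup by (vocabulary, code); collections here are small."""
        for c in self.concepts:
            if c.vocabulary_id == vocabulary_id and c.concept_code == concept_code:
                return c
        return None

    @property
    def domain_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.concepts:
            counts[c.domain_id] = counts.get(c.domain_id, 0) + 1
        return counts

    @property
    def vocabulary_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.concepts:
            counts[c.vocabulary_id] = counts.get(c.vocabulary_id, 0) + 1
        return counts


def _parse_athena_date(raw: str, what: str) -> date:
    raw = raw.strip()
    if not raw:
        raise ValueError(f"empty {what}")
    return datetime.strptime(raw, "%Y%m%d").date()


def read_concept_table(path: str | Path, delimiter: str = "\t") -> ConceptCollection:
    """Load an Athena-format concept table.

    Parameters
    ----------
    path
        Tab-delimited (by default) concept file with a header row.
    delimiter
        Field delimiter; Athena ships TAB even in files named ``.csv``.

    Rows whose ``concept_id`` does not parse as a positive integer, or that
    violate a Concept invariant (empty name, reversed dates), are recorded in
    ``collection.rejected`` with the row number and reason — never silently
    dropped.  Duplicate concept_ids abort with :class:`IntegrityError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"concept table not found: {path}")

    frame = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        na_filter=False,
        quoting=3,  # csv.QUOTE_NONE: Athena files are not quoted
        engine="python",
    )
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"concept table {path} missing mandatory column(s): {', '.join(missing)}"
        )

    has_class = "concept_class_id" in frame.columns
    has_dates = "valid_start_date" in frame.columns and "valid_end_date" in frame.columns

    concepts: list[Concept] = []
    rejected: list[RejectedRow] = []
    seen: set[int] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        record = dict(zip(frame.columns, row))
        raw_repr = delimiter.join(str(v) for v in row)
        try:
            concept_id = int(record["concept_id"].strip())
            if concept_id <= 0:
                raise ValueError("concept_id must be positive")
        except ValueError:
            rejected.append(RejectedRow(i, f"unparseable concept_id {record['concept_id']!r}", raw_repr))
            continue
        if concept_id in seen:
            raise IntegrityError(f"duplicate concept_id {concept_id} at data row {i} of {path}")
        try:
            flag = record["standard_concept"].strip()
            status = STANDARD_CONCEPT_FLAGS.get(flag)
            if status is None:
                raise ValueError(f"unknown standard_concept flag {flag!r}")
            invalid = record["invalid_reason"].strip() or None
            if has_dates:
                start = _parse_athena_date(record["valid_start_date"], "valid_start_date")
                end = _parse_athena_date(record["valid_end_date"], "valid_end_date")
            else:
                start, end = date(1970, 1, 1), date(2099, 12, 31)
            concept = Concept(
                concept_id=concept_id,
                concept_name=record["concept_name"].strip(),
                domain_id=record["domain_id"].strip(),
                vocabulary_id=record["vocabulary_id"].strip(),
                concept_class_id=record["concept_class_id"].strip() if has_class else "",
                standard_concept=status,
                concept_code=record["concept_code"].strip(),
                valid_start_date=start,
                valid_end_date=end,
                invalid_reason=invalid,
            )
        except ValueError as exc:
            rejected.append(RejectedRow(i, str(exc), raw_repr))
            continue
        seen.add(concept_id)
        concepts.append(concept)

    if rejected:
        logger.warning("%s: rejected %d of %d data rows", path, len(rejected), len(frame))
    return ConceptCollection(concepts=concepts, source_path=str(path), rejected=rejected)


def filter_concepts(
    collection: ConceptCollection,
    domains: Optional[Iterable[str]] = None,
    vocabularies: Optional[Iterable[str]] = None,
    standard_only: bool = False,
    valid_only: bool = False,
) -> ConceptCollection:
    """Return the subset satisfying every supplied criterion.

    The input collection is never modified.  A filter naming a domain or
    vocabulary absent from the collection produces a warning, not an error;
    an empty result is legitimate.
    """
    domain_set = set(domains) if domains is not None else None
    vocab_set = set(vocabularies) if vocabularies is not None else None

    if domain_set is not None:
        unknown = domain_set - set(collection.domain_counts)
        if unknown:
            warnings.warn(f"domains not present in collection: {sorted(unknown)}", stacklevel=2)
    if vocab_set is not None:
        unknown = vocab_set - set(collection.vocabulary_counts)
        if unknown:
            warnings.warn(f"vocabularies not present in collection: {sorted(unknown)}", stacklevel=2)

    kept = [
        c
        for c in collection.concepts
        if (domain_set is None or c.domain_id in domain_set)
        and (vocab_set is None or c.vocabulary_id in vocab_set)
        and (not standard_only or c.is_standard)
        and (not valid_only or c.is_valid)
    ]
    return ConceptCollection(concepts=kept, source_path=collection.source_path)


def write_concept_table(concepts: Sequence[Concept], path: str | Path, delimiter: str = "\t") -> None:
    """Write concepts back out in the Athena dialect (header + YYYYMMDD dates)."""
    path = Path(path)
    columns = (
        "concept_id",
        "concept_name",
        "domain_id",
        "vocabulary_id",
        "concept_class_id",
        "standard_concept",
        "concept_code",
        "valid_start_date",
        "valid_end_date",
        "invalid_reason",
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(delimiter.join(columns) + "\n")
        for c in concepts:
            fh.write(
                delimiter.join(
                    [
                        str(c.concept_id),
                        c.concept_name,
                        c.domain_id,
                        c.vocabulary_id,
                        c.concept_class_id,
                        _STATUS_TO_FLAG[c.standard_concept],
                        c.concept_code,
                        c.valid_start_date.strftime("%Y%m%d"),
                        c.valid_end_date.strftime("%Y%m%d"),
                        c.invalid_reason or "",
                    ]
                )
                + "\n"
            )
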