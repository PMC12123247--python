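"""Input pathways for query terms and the structured mapping-output CSV.

Three input pathways are supported, mirroring how research teams actually
hold their terms:

* a plain **term list** (CSV or XLSX) with a label column and optional
  form/field columns;
* a **REDCap data dictionary** CSV, from which both field labels and coded
  answer-choice labels become mappable terms ("1, Married | 2, Single"
  yields the terms "Married" and "Single");
* direct terms passed programmatically (handled by the matcher itself).

The output side writes one CSV row per (query, candidate) carrying the full
vocabulary metadata.  Every metadata cell is taken from — and verified
against — the loaded vocabulary collection, so exports are 100% concordant
with the source table by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

from omopmap.errors import InputError, IntegrityError, SchemaError
from omopmap.matcher import MappingResult, MatchCandidate, normalize_term
from omopmap.vocabulary import Concept, ConceptCollection

#: Column order of the mapping output CSV.
MAPPING_COLUMNS = (
    "form_id",
    "field_id",
    "query_term",
    "rank",
    "tier",
    "similarity",
    "concept_id",
    "concept_name",
    "concept_code",
    "vocabulary_id",
    "domain_id",
    "concept_class_id",
    "standard_concept",
    "sub_threshold_flag",
)

_LABEL_COLUMNS = {"label", "term", "query", "text", "field_label", "field label"}
_FORM_COLUMNS = {"form", "form_id", "form_name", "form name"}
_FIELD_COLUMNS = {"field", "field_id", "field_name", "variable", "query_id"}

#: REDCap field types whose "choices" column holds coded answer options.
CHOICE_FIELD_TYPES = {"radio", "dropdown", "checkbox"}

#: REDCap field types excluded from semantic mapping by default.
DEFAULT_EXCLUDED_TYPES = frozenset({"descriptive", "calc"})

# Sentinel validity window for concepts reconstructed from a mapping CSV,
# whose listed columns do not carry dates.
_SENTINEL_START = date(1970, 1, 1)
_SENTINEL_END = date(2099, 12, 31)


@dataclass(frozen=True)
class TermRecord:
    """One mappable query term with its provenance."""

    label: str
    origin: str  # manual | term_list | redcap_field | redcap_choice | spreadsheet
    form_id: Optional[str] = None
    field_id: Optional[str] = None
    row_number: int = 0


@dataclass(frozen=True)
class RedcapField:
    """Structure of one REDCap data-dictionary field; choice codes kept verbatim."""

    variable_name: str
    form_name: str
    field_type: str
    field_label: str
    choices: tuple[tuple[str, str], ...] = ()


@dataclass
class TermListResult:
    """Records read from a term list, plus rows skipped for blank labels."""

    records: list[TermRecord]
    skipped: list[tuple[int, str]] = field(default_factory=list)  # (row_number, reason)


@dataclass
class RedcapParseResult:
    """Loss-accounted parse of a REDCap data dictionary.

    Invariant: ``len(records) + len(structure_entries) + len(choice_failures)
    == n_fields + n_choices`` — nothing in the dictionary is silently lost.
    """

    records: list[TermRecord]
    fields: list[RedcapField]
    structure_entries: list[tuple[str, str]] = field(default_factory=list)  # (variable, reason)
    choice_failures: list[tuple[str, str]] = field(default_factory=list)  # (variable, raw option)
    n_fields: int = 0
    n_choices: int = 0


def _read_rows(path: Path) -> list[list[str]]:
    """Raw cell rows from a CSV or XLSX file (trailing Nones stringified)."""
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
        ws = wb.worksheets[0]
        rows = [["" if c is None else str(c) for c in row] for row in ws.iter_rows(values_only=True)]
        wb.close()
        return rows
    with open(path, encoding="utf-8-sig", newline="") as fh:
        return [list(row) for row in csv.reader(fh)]


def read_term_list(path: str | Path) -> TermListResult:
    """Read query terms from a CSV or XLSX term list.

    A header row is recognized when it names a label column (``label``,
    ``term``, ``query`` or ``text``, case-insensitive); ``form``/``field``
    columns are optional.  A single-column file without such a header is
    treated as a bare list of terms.  Rows whose label is blank are skipped
    and reported with their row number.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"term list not found: {path}")
    origin = "spreadsheet" if path.suffix.lower() in {".xlsx", ".xlsm"} else "term_list"
    rows = [r for r in _read_rows(path)]
    if not rows:
        return TermListResult(records=[])

    header = [cell.strip().lower() for cell in rows[0]]
    label_idx = next((i for i, h in enumerate(header) if h in _LABEL_COLUMNS), None)

    if label_idx is None:
        if max(len(r) for r in rows) == 1:
            # headerless single-column list: every nonempty cell is a term
            records, skipped = [], []
            for n, row in enumerate(rows, start=1):
                label = row[0].strip() if row else ""
                if label:
                    records.append(TermRecord(label=label, origin=origin, row_number=n))
                else:
                    skipped.append((n, "blank label"))
            return TermListResult(records=records, skipped=skipped)
        raise SchemaError(
            f"term list {path} has no label column (expected one of {sorted(_LABEL_COLUMNS)})"
        )

    form_idx = next((i for i, h in enumerate(header) if h in _FORM_COLUMNS), None)
    field_idx = next((i for i, h in enumerate(header) if h in _FIELD_COLUMNS), None)

    records, skipped = [], []
    for n, row in enumerate(rows[1:], start=2):
        def cell(idx: Optional[int]) -> str:
            return row[idx].strip() if idx is not None and idx < len(row) else ""

        label = cell(label_idx)
        if not label or not normalize_term(label):
            skipped.append((n, "blank label"))
            continue
        records.append(
            TermRecord(
                label=label,
                origin=origin,
                form_id=cell(form_idx) or None,
                field_id=cell(field_idx) or None,
                row_number=n,
            )
        )
    return TermListResult(records=records, skipped=skipped)


def _find_header(header: list[str], needle: str, path: Path) -> int:
    for i, h in enumerate(header):
        if needle in h:
            return i
    raise SchemaError(f"REDCap dictionary {path} missing mandatory header containing {needle!r}")


def parse_choices(raw: str) -> tuple[list[tuple[str, str]], list[str]]:
    """Parse a REDCap choices string "code, label | code, label".

    '|' separates options; the first comma within an option separates code
    from label.  Returns (parsed (code, label) pairs, malformed raw options).
    """
    parsed: list[tuple[str, str]] = []
    failures: list[str] = []
    for option in raw.split("|"):
        option = option.strip()
        if not option:
            continue
        code, sep, label = option.partition(",")
        if not sep or not label.strip():
            failures.append(option)
            continue
        parsed.append((code.strip(), label.strip()))
    return parsed, failures


def read_redcap_dictionary(
    path: str | Path,
    excluded_types: frozenset[str] = DEFAULT_EXCLUDED_TYPES,
    exclude_record_id: bool = True,
) -> RedcapParseResult:
    """Parse a REDCap data dictionary into mappable term records.

    Each non-excluded field contributes one ``redcap_field`` record (its
    Field Label) and, for choice-bearing field types, one ``redcap_choice``
    record per parsed answer option.  Descriptive and calculated fields and
    the record-id field (by convention the dictionary's first field) are
    excluded from mapping but reported as structure entries.  Malformed
    choice options keep the field and report the failed option.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"REDCap dictionary not found: {path}")
    rows = _read_rows(path)
    if not rows:
        return RedcapParseResult(records=[], fields=[])
    header = [cell.strip().lower().strip('"') for cell in rows[0]]
    i_var = _find_header(header, "variable", path)
    i_form = _find_header(header, "form name", path)
    i_type = _find_header(header, "field type", path)
    i_label = _find_header(header, "field label", path)
    i_choices = _find_header(header, "choices", path)

    result = RedcapParseResult(records=[], fields=[])
    for n, row in enumerate(rows[1:], start=2):
        def cell(idx: int) -> str:
            return row[idx].strip() if idx < len(row) else ""

        variable = cell(i_var)
        if not variable:
            continue  # fully blank padding row
        result.n_fields += 1
        form_name = cell(i_form)
        field_type = cell(i_type).lower()
        label = cell(i_label)

        choices: tuple[tuple[str, str], ...] = ()
        include = field_type not in excluded_types
        if exclude_record_id and result.n_fields == 1:
            include = False
            reason = "record-id field"
        elif field_type in excluded_types:
            reason = f"excluded field type {field_type!r}"
        elif not label:
            include = False
            reason = "empty field label"
        else:
            reason = ""

        if include and field_type in CHOICE_FIELD_TYPES:
            parsed, failures = parse_choices(cell(i_choices))
            choices = tuple(parsed)
            result.n_choices += len(parsed) + len(failures)
            for raw_opt in failures:
                result.choice_failures.append((variable, raw_opt))

        result.fields.append(
            RedcapField(
                variable_name=variable,
                form_name=form_name,
                field_type=field_type,
                field_label=label,
                choices=choices,
            )
        )

        if not include:
            result.structure_entries.append((variable, reason))
            continue

        result.records.append(
            TermRecord(
                label=label, origin="redcap_field", form_id=form_name, field_id=variable, row_number=n
            )
        )
        for code, choice_label in choices:
            result.records.append(
                TermRecord(
                    label=choice_label,
                    origin="redcap_choice",
                    form_id=form_name,
                    field_id=f"{variable}.{code}",
                    row_number=n,
                )
            )
    return result


def write_mapping_csv(
    results: Sequence[MappingResult],
    collection: ConceptCollection,
    path: str | Path,
    top_n: int = 5,
) -> None:
    """Write the structured mapping output CSV.

    One row per (query, candidate) up to ``top_n`` candidates; a query with
    no candidates still appears as a single row with empty concept columns so
    the export is complete.  Concept metadata is written from the vocabulary
    collection itself; a candidate referencing a concept absent from the
    collection (or with diverging metadata) raises :class:`IntegrityError`.
    Similarity is fixed at 4 decimals; encoding UTF-8, comma-delimited,
    all fields quoted.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
        writer.writerow(MAPPING_COLUMNS)
        for result in results:
            base = [result.form_id or "", result.field_id or "", result.query_term]
            if not result.candidates:
                writer.writerow(base + [""] * (len(MAPPING_COLUMNS) - 3))
                continue
            for cand in result.candidates[:top_n]:
                cid = cand.concept.concept_id
                if cid not in collection:
                    raise IntegrityError(
                        f"candidate concept {cid} for query {result.query_term!r} "
                        "is absent from the vocabulary collection"
                    )
                source = collection.get(cid)
                if source != cand.concept:
                    raise IntegrityError(
                        f"candidate concept {cid} metadata diverges from the vocabulary table"
                    )
                writer.writerow(
                    base
                    + [
                        cand.rank,
                        cand.tier,
                        f"{cand.similarity:.4f}",
                        source.concept_id,
                        source.concept_name,
                        source.concept_code,
                        source.vocabulary_id,
                        source.domain_id,
                        source.concept_class_id,
                        source.standard_concept,
                        "true" if cand.sub_threshold else "false",
                    ]
                )


def read_mapping_csv(path: str | Path) -> list[MappingResult]:
    """Reload a mapping CSV into MappingResults.

    Concepts are reconstructed from the listed metadata columns; validity
    dates are not part of the format and carry sentinel values.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"mapping CSV not found: {path}")
    results: list[MappingResult] = []
    current: Optional[MappingResult] = None
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in MAPPING_COLUMNS if reader.fieldnames is None or c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"mapping CSV {path} missing column(s): {', '.join(missing)}")
        for row in reader:
            key = (row["form_id"], row["field_id"], row["query_term"])
            if current is None or key != (
                current.form_id or "",
                current.field_id or "",
                current.query_term,
            ):
                current = MappingResult(
                    query_term=row["query_term"],
                    normalized_query=normalize_term(row["query_term"]),
                    form_id=row["form_id"] or None,
                    field_id=row["field_id"] or None,
                )
                results.append(current)
            if not row["concept_id"]:
                continue  # candidate-less query row
            concept = Concept(
                concept_id=int(row["concept_id"]),
                concept_name=row["concept_name"],
                domain_id=row["domain_id"],
                vocabulary_id=row["vocabulary_id"],
                concept_class_id=row["concept_class_id"],
                standard_concept=row["standard_concept"],
                concept_code=row["concept_code"],
                valid_start_date=_SENTINEL_START,
                valid_end_date=_SENTINEL_END,
            )
            current.candidates.append(
                MatchCandidate(
                    concept=concept,
                    similarity=float(row["similarity"]),
                    tier=row["tier"],
                    rank=int(row["rank"]),
                    sub_threshold=row["sub_threshold_flag"] == "true",
                )
            )
    return results
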