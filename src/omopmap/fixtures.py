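"""Synthetic Athena-style vocabularies, query sets, and REDCap dictionaries.

No real OHDSI vocabulary can ship with a test suite (licensing and size), so
this module generates desk-scale stand-ins: concept tables in the Athena
dialect whose names are assembled from a built-in clinical word list
(symptoms, demographics, survey phrasing), query sets derived from those
names by controlled variants (case changes, whitespace noise, synonym swaps,
token shuffles, single-character typos) with gold labels attached, synonym
tables, and small REDCap data dictionaries.  Everything is deterministic in
the fixture seed.

Concept identifiers are synthetic integers; the generated geometry says
nothing about any real embedding model — these fixtures exercise the
machinery (parsing, cascade ordering, metric computation), not the semantic
quality of any particular embedding provider.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from omopmap.evaluation import GoldStandard
from omopmap.vocabulary import Concept, ConceptCollection, read_concept_table, write_concept_table

#: ~200 clinical tokens: symptoms, findings, demographics, survey phrasing.
WORD_LIST = (
    "pain chest abdominal back neck shoulder joint muscle bone headache migraine "
    "fatigue weakness nausea vomiting diarrhea constipation fever chills cough "
    "dyspnea wheezing palpitations dizziness vertigo syncope insomnia anxiety "
    "depression stress confusion memory tremor seizure numbness tingling rash "
    "itching swelling edema bruising bleeding anemia jaundice cyanosis pallor "
    "hypertension hypotension diabetes asthma copd pneumonia bronchitis influenza "
    "infection sepsis arthritis osteoporosis fracture sprain strain laceration "
    "burn wound ulcer lesion tumor cancer carcinoma lymphoma leukemia melanoma "
    "obesity malnutrition dehydration anorexia bulimia insulin glucose cholesterol "
    "triglyceride hemoglobin hematocrit platelet creatinine bilirubin albumin "
    "sodium potassium calcium magnesium phosphate chloride bicarbonate lactate "
    "severity duration frequency onset intensity location quality radiation "
    "chronic acute intermittent persistent recurrent moderate severe mild "
    "assessment screening questionnaire survey scale score index rating status "
    "history current former never daily weekly monthly yearly baseline followup "
    "age sex gender race ethnicity hispanic latino marital married single "
    "divorced widowed separated partnered education employment income insurance "
    "occupation retired disabled student veteran housing homeless smoking "
    "alcohol tobacco opioid medication dosage treatment therapy surgery "
    "procedure admission discharge referral diagnosis prognosis outcome "
    "response remission relapse recovery rehabilitation exercise activity "
    "mobility ambulation sleep appetite weight height pressure pulse "
    "temperature respiration saturation systolic diastolic cardiac renal "
    "hepatic pulmonary neurologic gastrointestinal musculoskeletal dermatologic "
    "psychiatric cognitive functional emotional physical social spiritual "
    "interference relief aggravating alleviating numbness stiffness cramping "
    "burning throbbing stabbing aching shooting dull sharp pressure squeezing"
).split()

#: Token-level synonym pairs used by the synonym_swap variant.
SYNONYMS = {
    "pain": "ache",
    "fatigue": "tiredness",
    "dyspnea": "breathlessness",
    "fever": "pyrexia",
    "dizziness": "lightheadedness",
    "itching": "pruritus",
    "bruising": "ecchymosis",
    "swelling": "puffiness",
    "hypertension": "high blood pressure",
    "cancer": "malignancy",
    "heart": "cardiac",
    "kidney": "renal",
    "liver": "hepatic",
    "married": "wedded",
    "single": "unmarried",
    "smoking": "tobacco use",
    "weekly": "every week",
    "daily": "every day",
    "severe": "intense",
    "mild": "slight",
}

VARIANT_KINDS = (
    "identical",
    "case_change",
    "whitespace_change",
    "synonym_swap",
    "token_shuffle",
    "typo",
)

_DOMAINS = ("Observation", "Condition", "Measurement", "Meas Value")
_CLASSES = ("Clinical Finding", "Question", "Answer")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror a desk-scale version of a CDE-mapping evaluation: a few
    hundred vocabulary concepts across two vocabularies and a couple of
    hundred query terms with a realistic mix of surface variation plus a
    small fraction of unmappable queries.
    """

    n_concepts: int = 500
    n_queries: int = 200
    vocabularies: tuple[str, ...] = ("LOINC", "SNOMED")
    variant_mix: dict = dc_field(
        default_factory=lambda: {
            "identical": 0.25,
            "case_change": 0.20,
            "whitespace_change": 0.15,
            "synonym_swap": 0.10,
            "token_shuffle": 0.10,
            "typo": 0.20,
        }
    )
    seed: int = 42
    none_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_concepts <= 0:
            raise ValueError("n_concepts must be positive")
        if not 0 <= self.none_fraction < 1:
            raise ValueError("none_fraction must be in [0, 1)")
        unknown = set(self.variant_mix) - set(VARIANT_KINDS)
        if unknown:
            raise ValueError(f"unknown variant kinds: {sorted(unknown)}")
        total = sum(self.variant_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variant_mix proportions sum to {total}, expected 1")


@dataclass(frozen=True)
class QueryRecord:
    """One synthetic query with its provenance."""

    query_id: str
    text: str
    variant: str  # one of VARIANT_KINDS or "none"
    gold_concept_id: Optional[int]


def _make_name(rng: np.random.Generator) -> str:
    n_tokens = int(rng.integers(2, 5))
    tokens = [WORD_LIST[int(i)] for i in rng.integers(0, len(WORD_LIST), size=n_tokens)]
    return " ".join(t.capitalize() for t in tokens)


def generate_vocabulary(
    spec: FixtureSpec, path: str | Path
) -> tuple[Path, ConceptCollection]:
    """Write a synthetic Athena-dialect concept table and return it parsed.

    Concept names are unique after normalization (so the exact tier is
    unambiguous); vocabulary and domain assignments cycle over the spec
    lists; a small deterministic fraction of concepts is non-standard or
    invalidated to exercise filters.
    """
    path = Path(path)
    rng = np.random.default_rng(spec.seed)
    concepts: list[Concept] = []
    seen_names: set[str] = set()
    for i in range(spec.n_concepts):
        name = _make_name(rng)
        while name.casefold() in seen_names:
            name = _make_name(rng)
        seen_names.add(name.casefold())
        vocab = spec.vocabularies[i % len(spec.vocabularies)]
        standard = "standard" if rng.random() < 0.85 else "non-standard"
        invalid = "D" if rng.random() < 0.05 else None
        concepts.append(
            Concept(
                concept_id=1001 + i,
                concept_name=name,
                domain_id=_DOMAINS[i % len(_DOMAINS)],
                vocabulary_id=vocab,
                concept_class_id=_CLASSES[i % len(_CLASSES)],
                standard_concept=standard,
                concept_code=f"{vocab[:2]}{1001 + i}",
                valid_start_date=date(2000, 1, 1),
                valid_end_date=date(2099, 12, 31),
                invalid_reason=invalid,
            )
        )
    write_concept_table(concepts, path)
    return path, read_concept_table(path)


def _apply_variant(
    name: str, kind: str, rng: np.random.Generator
) -> tuple[str, str]:
    """Apply a surface variant to a concept name; returns (text, kind used)."""
    if kind == "identical":
        return name, kind
    if kind == "case_change":
        choice = int(rng.integers(0, 3))
        return (name.upper(), name.lower(), name.swapcase())[choice], kind
    if kind == "whitespace_change":
        return "  " + name.replace(" ", "   ") + " ", kind
    if kind == "synonym_swap":
        for token in name.split():
            repl = SYNONYMS.get(token.casefold())
            if repl:
                swapped = " ".join(
                    repl if t.casefold() == token.casefold() else t for t in name.split()
                )
                return swapped, kind
        return _apply_variant(name, "case_change", rng)[0], "case_change"  # fallback, counted
    if kind == "token_shuffle":
        tokens = name.split()
        if len(tokens) < 2:
            return _apply_variant(name, "case_change", rng)[0], "case_change"
        perm = rng.permutation(len(tokens))
        while list(perm) == list(range(len(tokens))):
            perm = rng.permutation(len(tokens))
        return " ".join(tokens[int(p)] for p in perm), kind
    if kind == "typo":
        pos = int(rng.integers(0, len(name)))
        if rng.random() < 0.5 and len(name) > 3:
            return name[:pos] + name[pos + 1 :], kind  # deletion
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        new = alphabet[int(rng.integers(0, 26))]
        while new == name[pos].lower():
            new = alphabet[int(rng.integers(0, 26))]
        return name[:pos] + new + name[pos + 1 :], kind
    raise ValueError(f"unknown variant kind {kind!r}")


def generate_query_set(
    collection: ConceptCollection, spec: FixtureSpec
) -> tuple[list[QueryRecord], GoldStandard]:
    """Derive queries from sampled concept names and label them with gold.

    A ``none_fraction`` of queries is generated from the word list without a
    source concept (normalized text guaranteed absent from the collection)
    and labeled NONE.  Synonym-swap requests whose name contains no token
    with a known synonym fall back to a case change, and the variant actually
    applied is recorded on the query.
    """
    if len(collection) == 0:
        raise ValueError("collection is empty")
    rng = np.random.default_rng(spec.seed + 1)
    kinds = list(spec.variant_mix.keys())
    probs = np.array([spec.variant_mix[k] for k in kinds], dtype=np.float64)
    probs /= probs.sum()
    known_names = {c.concept_name.casefold() for c in collection}

    queries: list[QueryRecord] = []
    entries: dict[str, Optional[int]] = {}
    for i in range(spec.n_queries):
        qid = f"q{i:04d}"
        if rng.random() < spec.none_fraction:
            text = _make_name(rng)
            while text.casefold() in known_names:
                text = _make_name(rng)
            queries.append(QueryRecord(query_id=qid, text=text, variant="none", gold_concept_id=None))
            entries[qid] = None
            continue
        concept = collection.concepts[int(rng.integers(0, len(collection)))]
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        text, used = _apply_variant(concept.concept_name, kind, rng)
        queries.append(
            QueryRecord(query_id=qid, text=text, variant=used, gold_concept_id=concept.concept_id)
        )
        entries[qid] = concept.concept_id
    return queries, GoldStandard(entries=entries)


def write_query_csv(queries: Sequence[QueryRecord], path: str | Path) -> None:
    """Write queries as a term-list CSV with a query_id column."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["query_id", "label", "variant"])
        for q in queries:
            writer.writerow([q.query_id, q.text, q.variant])


def generate_synonym_table(
    collection: ConceptCollection, spec: FixtureSpec, path: str | Path, n_entries: int = 20
) -> Path:
    """Write a two-column synonym table rephrasing a sample of concept names."""
    path = Path(path)
    rng = np.random.default_rng(spec.seed + 2)
    n = min(n_entries, len(collection))
    picks = rng.choice(len(collection), size=n, replace=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# synthetic synonym table: alternate phrasing\tconcept_id\n")
        for p in picks:
            concept = collection.concepts[int(p)]
            alt, _ = _apply_variant(concept.concept_name, "synonym_swap", rng)
            fh.write(f"{alt}\t{concept.concept_id}\n")
    return path


#: Fixed REDCap dictionary used by parser tests; field/choice counts are
#: hand-countable: 6 fields (1 record-id, 1 descriptive, 1 calc excluded),
#: radio and dropdown fields carrying 4 + 2 = 6 choices.
REDCAP_TEMPLATE_ROWS = [
    ["record_id", "demographics", "text", "Record ID", ""],
    [
        "relationship_status",
        "demographics",
        "radio",
        "What category best describes your current relationship status?",
        "1, Married | 2, Single | 3, Divorced | 4, Widowed",
    ],
    [
        "ethnicity",
        "demographics",
        "dropdown",
        "Ethnicity",
        "1, Hispanic or Latino | 2, Not Hispanic or Latino",
    ],
    ["intro_text", "demographics", "descriptive", "Welcome to the survey", ""],
    ["pain_now", "pain_assessment", "text", "Current pain intensity", ""],
    ["bmi", "pain_assessment", "calc", "Body mass index", "[weight]/(([height]/100)^(2))"],
]


def generate_redcap_dictionary(path: str | Path) -> Path:
    """Write a small synthetic REDCap data dictionary with standard headers."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
        writer.writerow(
            [
                "Variable / Field Name",
                "Form Name",
                "Field Type",
                "Field Label",
                "Choices, Calculations, OR Slider Labels",
            ]
        )
        writer.writerows(REDCAP_TEMPLATE_ROWS)
    return path


def demo_concepts() -> list[Concept]:
    """A hand-written demonstration vocabulary of demographic/clinical concepts.

    Concept ids are synthetic; codes follow the conventions of the named
    vocabularies (LOINC answer codes, SNOMED numeric codes).
    """
    mk = lambda cid, name, dom, vocab, cls, code: Concept(  # noqa: E731
        concept_id=cid,
        concept_name=name,
        domain_id=dom,
        vocabulary_id=vocab,
        concept_class_id=cls,
        standard_concept="standard",
        concept_code=code,
        valid_start_date=date(2000, 1, 1),
        valid_end_date=date(2099, 12, 31),
    )
    return [
        mk(2001, "Not Hispanic or Latino", "Meas Value", "LOINC", "Answer", "LA19555-4"),
        mk(2002, "Non-Hispanic or Latino", "Meas Value", "LOINC", "Answer", "LA10597-5"),
        mk(2003, "Hispanic or Latino", "Meas Value", "LOINC", "Answer", "LA6214-6"),
        mk(2004, "Marital Status", "Observation", "SNOMED", "Observable Entity", "125680007"),
        mk(2005, "Male-to-female transsexual", "Condition", "SNOMED", "Clinical Finding", "407275005"),
        mk(2006, "Exercise-induced angina", "Condition", "SNOMED", "Clinical Finding", "233819005"),
        mk(2007, "Pain intensity", "Observation", "LOINC", "Question", "72514-3"),
        mk(2008, "Employment status", "Observation", "LOINC", "Question", "67875-5"),
        mk(2009, "Highest level of education", "Observation", "LOINC", "Question", "82589-3"),
        mk(2010, "Current smoker", "Observation", "SNOMED", "Clinical Finding", "77176002"),
    ]


def demo_collection(path: Optional[str | Path] = None) -> ConceptCollection:
    """The demonstration vocabulary as a collection, optionally round-tripped
    through an Athena-dialect file at ``path``."""
    concepts = demo_concepts()
    if path is not None:
        write_concept_table(concepts, path)
        return read_concept_table(path)
    return ConceptCollection(concepts=concepts, source_path="<demo>")
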