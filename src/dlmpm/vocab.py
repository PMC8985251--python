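"""Disease vocabulary construction and disease-name annotation.

Metabolite databases record disease associations as free-text names, with no
uniform representation: the same disease appears as singular/plural/possessive
variants ("Disease, Hodgkin's"), with or without special symbols ("Chicken
Pox" vs "chickenpox"), as abbreviations ("AN"), with inverted word order
("Diabetes Mellitus, Type 1"), or under true synonyms.  This module builds an
expanded vocabulary over a disease ontology — every ontology name and synonym,
plus the names and synonyms of a MEDIC-style vocabulary attached through
MeSH/OMIM cross-references — and annotates free-text names to canonical
ontology accessions through a deterministic normalization pipeline.
"""

from __future__ import annotations

import io
import logging
import re
from collections.abc import Iterable
from dataclasses import dataclass, field

import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyTerm",
    "MedicEntry",
    "DiseaseVocabulary",
    "NormalizedName",
    "parse_ontology",
    "parse_medic",
    "build_vocabulary",
    "normalize_term",
    "comma_invert",
    "match_disease",
]

# Source priority used to resolve surface-form collisions (lower wins).
_SOURCE_PRIORITY = {"ontology-name": 0, "ontology-synonym": 1, "medic-via-xref": 2}

_SYMBOL_TABLE = str.maketrans({c: " " for c in "-_,.()"})
_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term (accession, label, synonyms, cross-references)."""

    term_id: str
    name: str
    synonyms: frozenset[str] = frozenset()
    xrefs: frozenset[str] = frozenset()
    obsolete: bool = False


@dataclass(frozen=True)
class MedicEntry:
    """One row of a MEDIC-style disease vocabulary (MeSH/OMIM id + labels)."""

    medic_id: str
    name: str
    synonyms: frozenset[str] = frozenset()


@dataclass(frozen=True)
class NormalizedName:
    """Primary normalized surface form plus ordered candidate variants."""

    primary: str
    variants: tuple[str, ...]


@dataclass
class DiseaseVocabulary:
    """Mapping from normalized disease surface forms to ontology accessions.

    ``entries`` maps each normalized surface form to exactly one term id;
    collisions between sources are resolved by source priority
    (ontology-name > ontology-synonym > medic-via-xref), ties by the
    lexicographically smaller accession, and every collision is logged in
    ``collisions`` rather than dropped silently.
    """

    entries: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    token_inventory: set[str] = field(default_factory=set)
    collisions: list[tuple[str, str, str]] = field(default_factory=list)
    n_terms: int = 0
    n_medic_matched: int = 0
    n_medic_unmatched: int = 0
    expansion_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def match(self, raw: str) -> str | None:
        return match_disease(raw, self)


def _strip_possessive(s: str) -> str:
    s = s.replace("’", "'")
    s = re.sub(r"'s\b", "", s)
    s = re.sub(r"'(?=\s|$)", "", s)
    return s


def _collapse(s: str) -> str:
    return " ".join(s.translate(_SYMBOL_TABLE).split())


def comma_invert(s: str) -> str:
    """Swap the segments around the first comma: ``"A, B"`` -> ``"B, A"``.

    An involution on two-segment forms; forms without a comma are returned
    unchanged.
    """
    if "," not in s:
        return s
    head, tail = s.split(",", 1)
    return f"{tail.strip()}, {head.strip()}"


def _depluralize(form: str, token_inventory: set[str] | None) -> str:
    """Strip a single trailing "s" from tokens, conservatively.

    With a token inventory, a token is singularized only when the stripped
    form is itself a known vocabulary token (so "diabetes" survives).  Without
    one, a suffix heuristic skips short tokens and -ss/-us/-is/-es endings.
    """
    out = []
    for tok in form.split():
        cand = tok[:-1] if tok.endswith("s") else tok
        if cand != tok:
            if token_inventory is not None:
                keep = cand in token_inventory
            else:
                keep = len(cand) >= 3 and not tok.endswith(("ss", "us", "is", "es"))
            tok = cand if keep else tok
        out.append(tok)
    return " ".join(out)


def normalize_term(raw: str, token_inventory: set[str] | None = None) -> NormalizedName:
    """Normalize a free-text disease name.

    Pipeline: lowercase and trim; strip possessive markers; replace the
    symbols ``- _ , . ( )`` with spaces and collapse whitespace (the primary
    form); additionally generate a comma-inverted candidate ("A, B" -> "B A",
    first comma only) and depluralized candidates of each.  Always returns at
    least the primary form; the primary form is a fixed point of the pipeline.
    """
    base = _strip_possessive(raw.strip().lower())
    primary = _collapse(base)
    variants: list[str] = [primary]
    if "," in base:
        inv = _collapse(comma_invert(base))
        if inv not in variants:
            variants.append(inv)
    for v in list(variants):
        dp = _depluralize(v, token_inventory)
        if dp and dp not in variants:
            variants.append(dp)
    return NormalizedName(primary=primary, variants=tuple(variants))


def _extract_synonym_labels(raw_synonyms: Iterable[str]) -> set[str]:
    """Pull the quoted label out of OBO synonym lines."""
    labels = set()
    for raw in raw_synonyms:
        m = _SYNONYM_RE.search(raw)
        if m:
            labels.add(m.group(1))
        elif raw.strip():
            labels.add(raw.strip())
    return labels


def parse_ontology(obo_source) -> list[OntologyTerm]:
    """Parse an OBO flat file into a list of :class:`OntologyTerm`.

    ``obo_source`` is a path or an open text handle.  Obsolete terms are kept
    but flagged (they are excluded later, at vocabulary-build time).  A
    duplicate ``id:`` inside the stanzas is an error, as is a malformed
    stanza (reported with its line number).
    """
    if hasattr(obo_source, "read"):
        text = obo_source.read()
    else:
        with open(obo_source, encoding="utf-8") as fh:
            text = fh.read()

    seen: dict[str, int] = {}
    in_term = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("["):
            in_term = stripped == "[Term]"
        elif in_term and stripped.startswith("id:"):
            tid = stripped[3:].strip()
            if tid in seen:
                raise ValueError(
                    f"duplicate term id {tid!r} at line {lineno} "
                    f"(first seen at line {seen[tid]})"
                )
            seen[tid] = lineno
            in_term = False  # only the first id line of a stanza counts

    try:
        graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except ValueError as exc:
        raise ValueError(f"malformed OBO stanza: {exc}") from exc

    terms = []
    for term_id, data in graph.nodes(data=True):
        name = data.get("name", "")
        if not name:
            continue
        terms.append(
            OntologyTerm(
                term_id=term_id,
                name=name,
                synonyms=frozenset(_extract_synonym_labels(data.get("synonym", []))),
                xrefs=frozenset(data.get("xref", [])),
                obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            )
        )
    logger.info("parsed %d ontology terms", len(terms))
    return terms


def parse_medic(
    table_source,
    *,
    sep: str = "\t",
    id_col: str = "DiseaseID",
    name_col: str = "DiseaseName",
    synonyms_col: str = "Synonyms",
    synonym_sep: str = "|",
) -> list[MedicEntry]:
    """Parse a MEDIC-style disease table (TSV/CSV) into entries.

    Column names are configurable; the synonym column holds a
    ``synonym_sep``-separated list and blank tokens are dropped.
    """
    import pandas as pd

    df = pd.read_csv(table_source, sep=sep, dtype=str, comment="#").fillna("")
    if id_col not in df.columns:
        raise ValueError(f"missing id column {id_col!r}; found {list(df.columns)}")
    if name_col not in df.columns:
        raise ValueError(f"missing name column {name_col!r}; found {list(df.columns)}")
    syn_values = (
        df[synonyms_col] if synonyms_col in df.columns else [""] * len(df)
    )
    entries = []
    for medic_id, name, raw_syn in zip(df[id_col], df[name_col], syn_values):
        syns = frozenset(t.strip() for t in raw_syn.split(synonym_sep) if t.strip())
        entries.append(MedicEntry(medic_id=medic_id.strip(), name=name, synonyms=syns))
    return entries


def build_vocabulary(
    terms: Iterable[OntologyTerm], medic: Iterable[MedicEntry] = ()
) -> DiseaseVocabulary:
    """Build the expanded disease vocabulary.

    Inserts every non-obsolete ontology term's name and synonyms, then
    attaches each MEDIC entry's name and synonyms to the ontology term(s)
    whose cross-references contain the MEDIC accession.  All surface forms
    are stored normalized (primary form plus the comma-inverted variant);
    depluralization happens query-side against the token inventory.
    """
    vocab = DiseaseVocabulary()
    candidates: list[tuple[str, str, int, str]] = []  # surface, term_id, prio, source

    def add(label: str, term_id: str, source: str) -> None:
        base = _strip_possessive(label.strip().lower())
        surfaces = [_collapse(base)]
        if "," in base:
            surfaces.append(_collapse(comma_invert(base)))
        for surface in dict.fromkeys(surfaces):
            if surface:
                candidates.append((surface, term_id, _SOURCE_PRIORITY[source], source))

    xref_index: dict[str, list[str]] = {}
    active_terms = [t for t in terms if not t.obsolete]
    vocab.n_terms = len(active_terms)
    for term in active_terms:
        add(term.name, term.term_id, "ontology-name")
        for syn in term.synonyms:
            add(syn, term.term_id, "ontology-synonym")
        for xref in term.xrefs:
            xref_index.setdefault(xref, []).append(term.term_id)

    for entry in medic:
        targets = xref_index.get(entry.medic_id, [])
        if not targets:
            vocab.n_medic_unmatched += 1
            continue
        vocab.n_medic_matched += 1
        if len(targets) > 1:
            logger.info(
                "MEDIC id %s maps to multiple ontology terms: %s",
                entry.medic_id,
                sorted(targets),
            )
        for term_id in targets:
            add(entry.name, term_id, "medic-via-xref")
            for syn in entry.synonyms:
                add(syn, term_id, "medic-via-xref")

    # Deterministic collision resolution: priority, then smaller accession.
    for surface, term_id, prio, source in sorted(
        candidates, key=lambda c: (c[0], c[2], c[1])
    ):
        if surface not in vocab.entries:
            vocab.entries[surface] = term_id
            vocab.provenance[surface] = source
            vocab.expansion_counts[source] = vocab.expansion_counts.get(source, 0) + 1
        elif vocab.entries[surface] != term_id:
            vocab.collisions.append((surface, vocab.entries[surface], term_id))
            logger.debug(
                "collision on %r: kept %s, dropped %s",
                surface,
                vocab.entries[surface],
                term_id,
            )

    for surface in vocab.entries:
        vocab.token_inventory.update(surface.split())
    if vocab.collisions:
        logger.info("resolved %d surface-form collisions", len(vocab.collisions))
    return vocab


def match_disease(raw: str, vocab: DiseaseVocabulary) -> str | None:
    """Annotate a free-text disease name to an ontology accession.

    Tries the primary normalized form, then the comma-inverted candidate,
    then the depluralized candidates, in that fixed order.  Returns ``None``
    (an explicit no-match, not an error) when nothing hits.
    """
    nf = normalize_term(raw, token_inventory=vocab.token_inventory)
    for form in nf.variants:
        term_id = vocab.entries.get(form)
        if term_id is not None:
            return term_id
    return None
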