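"""Readers and writers for the external formats and labeled matrices.

All matrices are serialized as labeled TSV — first row holds the disease
ids, first column the metabolite ids — so orientation is never implicit;
numeric output uses 6 decimal places.  Provenance grids use the
single-character codes K/D/M/B/E in the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssociationMatrix, ScoreTable, SimilarityMatrix
from .lfm import FactorPair, PredictionMatrix, TrainTrace
from .vocab import DiseaseVocabulary

__all__ = [
    "MetaboliteRecord",
    "read_metabolite_xml",
    "build_associations",
    "read_score_table",
    "read_similarity",
    "write_similarity",
    "read_pairs",
    "write_pairs",
    "write_association_matrix",
    "read_association_matrix",
    "write_prediction_matrix",
    "write_factors",
    "write_trace",
    "write_vocabulary",
    "read_vocabulary",
]

_FLOAT_FMT = "%.6f"


@dataclass
class MetaboliteRecord:
    """A metabolite with its free-text disease-name list (HMDB-style)."""

    accession: str
    name: str
    disease_names: list[str] = field(default_factory=list)


def read_metabolite_xml(
    xml_source,
    *,
    metabolite_tag: str = "metabolite",
    accession_tag: str = "accession",
    name_tag: str = "name",
    disease_name_path: str = "diseases/disease/name",
) -> list[MetaboliteRecord]:
    """Parse metabolite records out of an HMDB-style XML file.

    Element paths are configurable to absorb schema drift across database
    releases.  Records without an accession are skipped (counted via a
    warning); records with zero disease names are kept — they still rank as
    candidates.
    """
    from lxml import etree

    try:
        tree = etree.parse(
            str(xml_source) if isinstance(xml_source, (str, Path)) else xml_source
        )
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML: {exc}") from exc
    records = []
    skipped = 0
    for el in tree.iter(metabolite_tag):
        acc = el.findtext(accession_tag)
        if not acc or not acc.strip():
            skipped += 1
            continue
        name = (el.findtext(name_tag) or "").strip()
        diseases = [
            d.text.strip() for d in el.findall(disease_name_path) if d.text
        ]
        records.append(
            MetaboliteRecord(accession=acc.strip(), name=name, disease_names=diseases)
        )
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "skipped %d metabolite elements without accession", skipped
        )
    return records


def build_associations(
    records: list[MetaboliteRecord], vocab: DiseaseVocabulary
) -> tuple[list[tuple[str, str]], dict]:
    """Resolve each record's disease names through the vocabulary.

    Returns the deduplicated (metabolite_id, disease_id) pair list plus a
    report with matched/unmatched name counts and distinct entity tallies.
    """
    pairs: set[tuple[str, str]] = set()
    matched = unmatched = 0
    unmatched_names: set[str] = set()
    for rec in records:
        for raw in rec.disease_names:
            term_id = vocab.match(raw)
            if term_id is None:
                unmatched += 1
                unmatched_names.add(raw)
            else:
                matched += 1
                pairs.add((rec.accession, term_id))
    pair_list = sorted(pairs)
    report = {
        "n_names_matched": matched,
        "n_names_unmatched": unmatched,
        "unmatched_names": sorted(unmatched_names),
        "n_pairs": len(pair_list),
        "n_metabolites": len({m for m, _ in pair_list}),
        "n_diseases": len({d for _, d in pair_list}),
    }
    return pair_list, report


def read_score_table(
    score_source,
    mapping_source=None,
    *,
    id1_col: str = "chemical1",
    id2_col: str = "chemical2",
    score_col: str = "textmining",
    sep: str = "\t",
) -> ScoreTable:
    """Read a STITCH-style pairwise score table, optionally translating
    chemical ids to metabolite accessions through a two-column mapping."""
    df = pd.read_csv(score_source, sep=sep, dtype={id1_col: str, id2_col: str})
    for col in (id1_col, id2_col, score_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in score table")
    mapping = None
    if mapping_source is not None:
        mp = pd.read_csv(mapping_source, sep=sep, dtype=str)
        mapping = dict(zip(mp.iloc[:, 0], mp.iloc[:, 1]))
    table = ScoreTable()
    for id1, id2, score in zip(df[id1_col], df[id2_col], df[score_col]):
        if mapping is not None:
            id1 = mapping.get(id1)
            id2 = mapping.get(id2)
            if id1 is None or id2 is None:
                continue
        table.add(id1, id2, float(score))
    return table


def write_similarity(sim: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(sim.values, index=sim.labels, columns=sim.labels)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=sim.kind)


def read_similarity(path, kind: str = "disease") -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    values = (values + values.T) / 2.0  # absorb serialization rounding
    return SimilarityMatrix(
        labels=[str(c) for c in df.columns], values=values, kind=kind
    )


def write_pairs(pairs, path) -> int:
    lines = ["metabolite_id\tdisease_id"]
    lines += [f"{m}\t{d}" for m, d in pairs]
    Path(path).write_text("\n".join(lines) + "\n")
    return len(lines) - 1


def read_pairs(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [tuple(row) for row in df.itertuples(index=False)]


def write_association_matrix(mat: AssociationMatrix, path, provenance_path=None) -> None:
    df = pd.DataFrame(
        mat.values, index=mat.metabolite_labels, columns=mat.disease_labels
    )
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="metabolite")
    if provenance_path is not None:
        pdf = pd.DataFrame(
            mat.provenance, index=mat.metabolite_labels, columns=mat.disease_labels
        )
        pdf.to_csv(provenance_path, sep="\t", index_label="metabolite")


def read_association_matrix(path, provenance_path=None) -> AssociationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    prov = None
    if provenance_path is not None:
        prov = pd.read_csv(provenance_path, sep="\t", index_col=0).to_numpy(dtype="<U1")
    return AssociationMatrix(
        metabolite_labels=[str(i) for i in df.index],
        disease_labels=[str(c) for c in df.columns],
        values=np.clip(df.to_numpy(dtype=float), 0.0, 1.0),
        provenance=prov,
    )


def read_prediction_matrix(path) -> PredictionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PredictionMatrix(
        metabolite_labels=[str(i) for i in df.index],
        disease_labels=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_prediction_matrix(pred: PredictionMatrix, path) -> None:
    df = pd.DataFrame(
        pred.values, index=pred.metabolite_labels, columns=pred.disease_labels
    )
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="metabolite")


def write_factors(factors: FactorPair, dlf_path, mlf_path, disease_labels, metabolite_labels) -> None:
    cols = [f"f{k}" for k in range(factors.n_factors)]
    pd.DataFrame(factors.dlf, index=disease_labels, columns=cols).to_csv(
        dlf_path, sep="\t", float_format=_FLOAT_FMT, index_label="disease"
    )
    pd.DataFrame(factors.mlf, index=metabolite_labels, columns=cols).to_csv(
        mlf_path, sep="\t", float_format=_FLOAT_FMT, index_label="metabolite"
    )


def write_trace(trace: TrainTrace, path) -> None:
    lines = ["epoch\tcost"]
    lines += [f"{i}\t{c:.10g}" for i, c in enumerate(trace.epoch_costs)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_vocabulary(vocab: DiseaseVocabulary, path) -> None:
    lines = ["surface_form\tterm_id\tprovenance"]
    for surface in sorted(vocab.entries):
        lines.append(
            f"{surface}\t{vocab.entries[surface]}\t{vocab.provenance[surface]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vocabulary(path) -> DiseaseVocabulary:
    df = pd.read_csv(path, sep="\t", dtype=str)
    vocab = DiseaseVocabulary()
    for surface, term_id, prov in zip(
        df["surface_form"], df["term_id"], df["provenance"]
    ):
        vocab.entries[surface] = term_id
        vocab.provenance[surface] = prov
        vocab.token_inventory.update(surface.split())
    return vocab
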