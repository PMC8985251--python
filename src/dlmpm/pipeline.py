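"""End-to-end pipeline: vocabulary → associations → completion → factorization → rankings."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as dio
from .association import (
    build_initial_matrix,
    combine_fills,
    coverage_stats,
    disease_fill,
    metabolite_fill,
    metabolite_similarity_from_scores,
)
from .lfm import LFMConfig, finalize_predictions, train
from .vocab import build_vocabulary, parse_medic, parse_ontology

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "rank_candidates"]


@dataclass
class PipelineConfig:
    """File paths and options for a full pipeline run."""

    ontology_path: str
    medic_path: str
    metabolite_xml_path: str
    score_table_path: str
    disease_similarity_path: str
    out_dir: str
    chemical_mapping_path: str | None = None
    lfm: LFMConfig = field(default_factory=LFMConfig)
    msim_direction: str = "ascending"
    clip: bool = False
    include_known_in_rankings: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        lfm = LFMConfig(**raw.pop("lfm", {}))
        return cls(lfm=lfm, **raw)


def rank_candidates(pred, init, disease_id: str, exclude_known: bool = True):
    """Ranked (metabolite, score) list for one disease, best first.

    Known metabolites (score pinned at 1) are excluded by default since
    evaluation scores only unknown candidates; ties break by accession so
    rankings are reproducible.
    """
    col = pred.disease_column(disease_id)
    d = init.disease_index(disease_id)
    out = []
    for i, met in enumerate(pred.metabolite_labels):
        if exclude_known and init.values[i, d] == 1.0:
            continue
        out.append((met, float(col[i])))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all intermediates; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "summary": {}}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("vocabulary")
        terms = parse_ontology(config.ontology_path)
        medic = parse_medic(config.medic_path)
        vocab = build_vocabulary(terms, medic)
        dio.write_vocabulary(vocab, out / "vocabulary.tsv")
        manifest["outputs"]["vocabulary"] = "vocabulary.tsv"

        _stage("associations")
        records = dio.read_metabolite_xml(config.metabolite_xml_path)
        pairs, match_report = dio.build_associations(records, vocab)
        dio.write_pairs(pairs, out / "associations.tsv")
        manifest["outputs"]["associations"] = "associations.tsv"
        metabolite_labels = sorted({r.accession for r in records})
        disease_labels = sorted({d for _, d in pairs})

        _stage("initial matrix")
        init = build_initial_matrix(pairs, metabolite_labels, disease_labels)
        dio.write_association_matrix(
            init, out / "initial_matrix.tsv", out / "initial_provenance.tsv"
        )

        _stage("completion")
        dsim = dio.read_similarity(config.disease_similarity_path, kind="disease")
        table = dio.read_score_table(
            config.score_table_path, config.chemical_mapping_path
        )
        msim = metabolite_similarity_from_scores(
            table, labels=metabolite_labels, direction=config.msim_direction
        )
        df = disease_fill(init, dsim)
        mf = metabolite_fill(init, msim)
        completed = combine_fills(df, mf, init)
        coverage = coverage_stats(completed)
        dio.write_association_matrix(
            completed, out / "completed_matrix.tsv", out / "completed_provenance.tsv"
        )
        manifest["outputs"]["completed_matrix"] = "completed_matrix.tsv"

        _stage("training")
        factors, trace = train(completed, config.lfm)
        dio.write_factors(
            factors,
            out / "disease_factors.tsv",
            out / "metabolite_factors.tsv",
            disease_labels,
            metabolite_labels,
        )
        dio.write_trace(trace, out / "training_trace.tsv")

        _stage("prediction")
        pred = finalize_predictions(factors, init, clip=config.clip)
        dio.write_prediction_matrix(pred, out / "predictions.tsv")
        manifest["outputs"]["predictions"] = "predictions.tsv"

        _stage("ranking")
        rank_lines = ["disease_id\trank\tmetabolite_id\tscore"]
        for d in disease_labels:
            for r, (met, score) in enumerate(
                rank_candidates(
                    pred, init, d, exclude_known=not config.include_known_in_rankings
                ),
                start=1,
            ):
                rank_lines.append(f"{d}\t{r}\t{met}\t{score:.6f}")
        (out / "rankings.tsv").write_text("\n".join(rank_lines) + "\n")
        manifest["outputs"]["rankings"] = "rankings.tsv"
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    manifest["summary"] = {
        "n_diseases": len(disease_labels),
        "n_metabolites": len(metabolite_labels),
        "n_known_pairs": len(pairs),
        "match_report": {
            k: v for k, v in match_report.items() if k != "unmatched_names"
        },
        "coverage": {
            "n_known": coverage.n_known,
            "n_disease_only": coverage.n_disease_only,
            "n_metabolite_only": coverage.n_metabolite_only,
            "n_both": coverage.n_both,
            "n_empty": coverage.n_empty,
            "coverage_rate": coverage.coverage_rate,
            "degenerate": coverage.degenerate,
        },
        "final_cost": trace.epoch_costs[-1] if trace.epoch_costs else None,
        "epochs_run": trace.epochs_run,
        "converged": trace.converged,
        "seed": config.lfm.seed,
        "msim_direction": config.msim_direction,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
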