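"""Validation schemes: data-increment test sets, LOOCV, AUC, ablations.

Curated disease–metabolite databases grow between releases, so the
difference between two versions of the association map yields a natural
test set: for a disease that already had at least one association shared by
both versions (the "detection target" condition), the metabolites newly
associated in the later version — restricted to metabolites present in both
versions — are positives, and metabolites of the earlier version never
associated with the disease in either version are negatives.  Per-disease
AUC (probability that a random positive outranks a random negative, ties
half) scores the ranked predictions; leave-one-out cross-validation rebuilds
the full pipeline once per known association and scores the held-out pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from .association import (
    AssociationMatrix,
    SimilarityMatrix,
    build_initial_matrix,
    combine_fills,
    disease_fill,
    metabolite_fill,
)
from .lfm import LFMConfig, PredictionMatrix, finalize_predictions, svd_baseline, train

__all__ = [
    "AssociationMapVersion",
    "TestSet",
    "EvaluationReport",
    "extract_incremental_test_sets",
    "auc",
    "evaluate",
    "loocv",
    "run_ablation",
    "ABLATION_VARIANTS",
]

ABLATION_VARIANTS = (
    "init",
    "disease_only",
    "metabolite_only",
    "full",
    "svd",
    "lfm_nr",
)


@dataclass(frozen=True)
class AssociationMapVersion:
    """One release of the disease–metabolite bipartite association map."""

    version_tag: str
    pairs: frozenset[tuple[str, str]]  # (metabolite_id, disease_id)
    metabolites: frozenset[str]
    diseases: frozenset[str]

    def __post_init__(self) -> None:
        for m, d in self.pairs:
            if m not in self.metabolites or d not in self.diseases:
                raise ValueError(
                    f"pair ({m!r}, {d!r}) not covered by the entity sets of "
                    f"version {self.version_tag!r}"
                )

    @classmethod
    def from_pairs(
        cls,
        version_tag: str,
        pairs,
        metabolites=None,
        diseases=None,
    ) -> "AssociationMapVersion":
        pairs = frozenset(tuple(p) for p in pairs)
        mets = frozenset(metabolites) if metabolites is not None else frozenset(
            m for m, _ in pairs
        )
        dis = frozenset(diseases) if diseases is not None else frozenset(
            d for _, d in pairs
        )
        return cls(version_tag, pairs, mets, dis)


@dataclass
class TestSet:
    """Per-disease positive/negative metabolite partition."""

    disease_id: str
    positives: set[str]
    negatives: set[str]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives must be disjoint")


@dataclass
class EvaluationReport:
    """Per-disease AUCs with positive/negative counts, and their mean."""

    per_disease: dict[str, float] = field(default_factory=dict)
    per_disease_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_diseases(self) -> int:
        return len(self.per_disease)

    @property
    def mean_auc(self) -> float:
        if not self.per_disease:
            return float("nan")
        return float(np.mean(list(self.per_disease.values())))


def extract_incremental_test_sets(
    v1: AssociationMapVersion, v2: AssociationMapVersion
) -> list[TestSet]:
    """Diff two association-map versions into per-disease test sets.

    A disease qualifies when at least one metabolite of M1 ∩ M2 is associated
    with it in BOTH versions; its positives are the metabolites of M1 ∩ M2
    newly associated in version 2, its negatives all metabolites of M1 never
    associated with it in either version.  Version-1 positives that persist
    into version 2 are training knowledge, not test items.  Diseases with no
    positives are dropped.
    """
    shared = v1.metabolites & v2.metabolites
    out = []
    for d in sorted(v1.diseases):
        anchors = {m for m in shared if (m, d) in v1.pairs and (m, d) in v2.pairs}
        if not anchors:
            continue
        positives = {
            m for m in shared if (m, d) in v2.pairs and (m, d) not in v1.pairs
        }
        if not positives:
            continue
        negatives = {
            m
            for m in v1.metabolites
            if (m, d) not in v1.pairs and (m, d) not in v2.pairs
        }
        out.append(TestSet(disease_id=d, positives=positives, negatives=negatives))
    return out


def auc(positive_scores, negative_scores) -> float:
    """Probability a random positive outranks a random negative, ties half
    (the normalized Mann–Whitney U statistic)."""
    pos = list(positive_scores)
    neg = list(negative_scores)
    if not pos or not neg:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return float(roc_auc_score(y, np.concatenate([pos, neg])))


def evaluate(
    predictions: PredictionMatrix, test_sets: list[TestSet]
) -> EvaluationReport:
    """Per-disease AUC from the prediction matrix columns."""
    report = EvaluationReport()
    met_index = {m: i for i, m in enumerate(predictions.metabolite_labels)}
    for ts in test_sets:
        if ts.disease_id not in predictions.disease_labels:
            raise KeyError(f"disease {ts.disease_id!r} missing from predictions")
        col = predictions.disease_column(ts.disease_id)
        try:
            pos = [col[met_index[m]] for m in sorted(ts.positives)]
            neg = [col[met_index[m]] for m in sorted(ts.negatives)]
        except KeyError as exc:
            raise KeyError(f"metabolite {exc.args[0]!r} missing from predictions")
        report.per_disease[ts.disease_id] = auc(pos, neg)
        report.per_disease_counts[ts.disease_id] = (len(pos), len(neg))
    return report


def _complete(
    pairs,
    metabolite_labels,
    disease_labels,
    dsim: SimilarityMatrix,
    msim: SimilarityMatrix,
) -> tuple[AssociationMatrix, AssociationMatrix]:
    init = build_initial_matrix(pairs, metabolite_labels, disease_labels)
    df = disease_fill(init, dsim)
    mf = metabolite_fill(init, msim)
    return init, combine_fills(df, mf, init)


def loocv(
    pairs,
    metabolite_labels: list[str],
    disease_labels: list[str],
    dsim: SimilarityMatrix,
    msim: SimilarityMatrix,
    config: LFMConfig,
) -> EvaluationReport:
    """Leave-one-out cross-validation over the known associations.

    Each fold removes one known pair, reruns the whole pipeline — similarity
    completion AND factorization, since the removed pair changes the fill
    sets — and scores the held-out metabolite against all metabolites never
    associated with that disease.  One AUC per fold, keyed by the held-out
    pair.
    """
    pairs = sorted(set(tuple(p) for p in pairs))
    if len(pairs) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    known_by_disease: dict[str, set[str]] = {}
    for m, d in pairs:
        known_by_disease.setdefault(d, set()).add(m)
    report = EvaluationReport()
    for held_m, held_d in pairs:
        fold_pairs = [p for p in pairs if p != (held_m, held_d)]
        init, completed = _complete(
            fold_pairs, metabolite_labels, disease_labels, dsim, msim
        )
        factors, _ = train(completed, config)
        pred = finalize_predictions(factors, init)
        col = pred.disease_column(held_d)
        met_index = {m: i for i, m in enumerate(metabolite_labels)}
        negatives = [
            m for m in metabolite_labels if m not in known_by_disease[held_d]
        ]
        pos = [col[met_index[held_m]]]
        neg = [col[met_index[m]] for m in negatives]
        key = f"{held_m}|{held_d}"
        report.per_disease[key] = auc(pos, neg)
        report.per_disease_counts[key] = (1, len(neg))
    return report


def run_ablation(
    pairs,
    metabolite_labels: list[str],
    disease_labels: list[str],
    dsim: SimilarityMatrix,
    msim: SimilarityMatrix,
    config: LFMConfig,
    variant: str = "full",
) -> PredictionMatrix:
    """Run one pipeline variant.

    ``init`` factorizes the raw 0–1 matrix; ``disease_only`` /
    ``metabolite_only`` factorize a matrix completed with a single fill;
    ``full`` uses the noisy-OR of both fills; ``svd`` swaps the factorization
    for a truncated-SVD reconstruction of the fully completed matrix (rank =
    ``config.n_factors``); ``lfm_nr`` is the full pipeline without
    regularization.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {ABLATION_VARIANTS}")
    init = build_initial_matrix(pairs, metabolite_labels, disease_labels)
    df = disease_fill(init, dsim)
    mf = metabolite_fill(init, msim)
    zeros = np.zeros(init.shape)
    if variant == "init":
        target = combine_fills(init.values, zeros, init)
    elif variant == "disease_only":
        target = combine_fills(df, zeros, init)
    elif variant == "metabolite_only":
        target = combine_fills(zeros, mf, init)
    else:
        target = combine_fills(df, mf, init)
    if variant == "svd":
        k = min(config.n_factors, min(target.shape))
        return svd_baseline(target, k)
    cfg = replace(config, reg_lambda=0.0) if variant == "lfm_nr" else config
    factors, _ = train(target, cfg)
    return finalize_predictions(factors, init)
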