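"""Disease–metabolite association matrix construction and similarity completion.

The initial association matrix is a sparse 0–1 matrix (rows = metabolites,
columns = diseases) built from curated associations.  Its unknown cells are
completed with two independent evidence channels: a disease-similarity fill
(an unknown (m, d) cell receives the maximum similarity between d and any
disease already associated with m) and a metabolite literature-similarity
fill (symmetric construction over the metabolites of d).  The two fills are
combined per cell with a noisy-OR, mdr = 1 − (1 − DF)(1 − MF), i.e. the
probability that at least one channel fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimilarityMatrix",
    "AssociationMatrix",
    "ScoreTable",
    "CoverageReport",
    "build_initial_matrix",
    "metabolite_similarity_from_scores",
    "disease_fill",
    "metabolite_fill",
    "combine_fills",
    "coverage_stats",
]

# Single-character provenance codes used both in memory and on disk.
PROV_KNOWN = "K"
PROV_DISEASE = "D"
PROV_METABOLITE = "M"
PROV_BOTH = "B"
PROV_EMPTY = "E"


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix over diseases or metabolites, values in [0,1]."""

    labels: list[str]
    values: np.ndarray
    kind: str = "disease"  # "disease" | "metabolite"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def sim(self, a: str, b: str) -> float:
        """Similarity of a pair; self-similarity is 1, missing labels give 0."""
        if a == b:
            return 1.0
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.values[ia, ib])

    def aligned(self, labels: list[str]) -> np.ndarray:
        """Values re-indexed to ``labels``; missing labels become zero rows
        (self-similarity on the diagonal stays 1)."""
        n = len(labels)
        out = np.zeros((n, n))
        idx = [self._index.get(lab) for lab in labels]
        for i, ii in enumerate(idx):
            if ii is None:
                continue
            for j, jj in enumerate(idx):
                if jj is not None:
                    out[i, j] = self.values[ii, jj]
        np.fill_diagonal(out, 1.0)
        return out


@dataclass
class AssociationMatrix:
    """Metabolite-by-disease association matrix with per-cell provenance.

    ``provenance`` uses the codes K (known 1 in the initial matrix),
    D (disease-similarity fill only), M (metabolite-similarity fill only),
    B (both fills), E (empty).
    """

    metabolite_labels: list[str]
    disease_labels: list[str]
    values: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.metabolite_labels), len(self.disease_labels))
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != {shape}")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("association degrees must lie in [0, 1]")
        if self.provenance is None:
            self.provenance = np.where(self.values >= 1.0, PROV_KNOWN, PROV_EMPTY)
        self.provenance = np.asarray(self.provenance, dtype="<U1")
        if self.provenance.shape != shape:
            raise ValueError("provenance shape does not match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def metabolite_index(self, label: str) -> int:
        return self.metabolite_labels.index(label)

    def disease_index(self, label: str) -> int:
        return self.disease_labels.index(label)


@dataclass
class ScoreTable:
    """Unordered-pair literature co-occurrence scores (STITCH text-mining style).

    Self-pairs are ignored; duplicate unordered pairs keep the maximum score;
    negative scores are rejected.
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records) -> "ScoreTable":
        table = cls()
        for id1, id2, score in records:
            table.add(id1, id2, score)
        return table

    def add(self, id1: str, id2: str, score: float) -> None:
        score = float(score)
        if not np.isfinite(score) or score < 0:
            raise ValueError(f"invalid score {score!r} for pair ({id1}, {id2})")
        if id1 == id2:
            return
        key = (id1, id2) if id1 < id2 else (id2, id1)
        if key in self.pairs:
            self.pairs[key] = max(self.pairs[key], score)
        else:
            self.pairs[key] = score

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CoverageReport:
    """Provenance-class counts of a completed matrix and the coverage rate.

    coverage_rate = 100 · (filled unknown cells) / (all unknown cells); when
    every cell is known the denominator is zero and the rate is reported as
    100 with ``degenerate`` set.
    """

    n_known: int
    n_disease_only: int
    n_metabolite_only: int
    n_both: int
    n_empty: int
    degenerate: bool = False

    @property
    def total(self) -> int:
        return (
            self.n_known
            + self.n_disease_only
            + self.n_metabolite_only
            + self.n_both
            + self.n_empty
        )

    @property
    def n_predicted(self) -> int:
        return self.n_disease_only + self.n_metabolite_only + self.n_both

    @property
    def coverage_rate(self) -> float:
        denom = self.total - self.n_known
        if denom == 0:
            return 100.0
        return 100.0 * self.n_predicted / denom


def build_initial_matrix(
    associations, metabolite_labels: list[str], disease_labels: list[str]
) -> AssociationMatrix:
    """0–1 initial matrix: cell (m, d) is 1 iff the pair is listed.

    Duplicate pairs collapse to a single 1; a pair referencing an unknown
    label is an error naming the pair.
    """
    m_index = {lab: i for i, lab in enumerate(metabolite_labels)}
    d_index = {lab: j for j, lab in enumerate(disease_labels)}
    values = np.zeros((len(metabolite_labels), len(disease_labels)))
    for met, dis in associations:
        if met not in m_index or dis not in d_index:
            raise KeyError(f"association ({met!r}, {dis!r}) references unknown label")
        values[m_index[met], d_index[dis]] = 1.0
    prov = np.where(values == 1.0, PROV_KNOWN, PROV_EMPTY)
    return AssociationMatrix(metabolite_labels, disease_labels, values, prov)


def metabolite_similarity_from_scores(
    table: ScoreTable,
    labels: list[str] | None = None,
    direction: str = "ascending",
) -> SimilarityMatrix:
    """Normalize raw literature scores into metabolite similarities.

    ``ascending`` (default) maps the highest score to similarity 1:
    (ST − ST_min)/(ST_max − ST_min).  ``as_printed`` applies the inverted
    normalization (ST_max − ST)/(ST_max − ST_min), which maps the lowest
    score to 1; both are kept because the appropriate direction depends on
    whether the raw score grows with association strength.  Pairs absent
    from the table get similarity 0.
    """
    if direction not in {"ascending", "as_printed"}:
        raise ValueError(f"unknown direction {direction!r}")
    if not table.pairs:
        raise ValueError("empty score table")
    scores = np.array(list(table.pairs.values()))
    st_max, st_min = scores.max(), scores.min()
    if st_max == st_min:
        raise ValueError("ST_max equals ST_min; normalization undefined")
    if labels is None:
        labels = sorted({i for pair in table.pairs for i in pair})
    index = {lab: i for i, lab in enumerate(labels)}
    values = np.zeros((len(labels), len(labels)))
    for (id1, id2), score in table.pairs.items():
        i, j = index.get(id1), index.get(id2)
        if i is None or j is None:
            continue
        if direction == "as_printed":
            sim = (st_max - score) / (st_max - st_min)
        else:
            sim = (score - st_min) / (st_max - st_min)
        values[i, j] = values[j, i] = sim
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(labels=list(labels), values=values, kind="metabolite")


def disease_fill(init: AssociationMatrix, dsim: SimilarityMatrix) -> np.ndarray:
    """Disease-similarity fill DF, shaped like the association matrix.

    DF(m, d) = 1 for d already associated with m; otherwise the maximum
    similarity between d and any disease of m (0 when m has none).
    """
    sim = dsim.aligned(init.disease_labels)
    n_m, n_d = init.shape
    df = np.zeros((n_m, n_d))
    for m in range(n_m):
        cols = np.flatnonzero(init.values[m] == 1.0)
        if cols.size == 0:
            continue
        df[m, :] = sim[:, cols].max(axis=1)
        df[m, cols] = 1.0
    return df


def metabolite_fill(init: AssociationMatrix, msim: SimilarityMatrix) -> np.ndarray:
    """Metabolite-similarity fill MF, the symmetric counterpart of
    :func:`disease_fill` over the metabolites of each disease."""
    sim = msim.aligned(init.metabolite_labels)
    n_m, n_d = init.shape
    mf = np.zeros((n_m, n_d))
    for d in range(n_d):
        rows = np.flatnonzero(init.values[:, d] == 1.0)
        if rows.size == 0:
            continue
        mf[:, d] = sim[:, rows].max(axis=1)
        mf[rows, d] = 1.0
    return mf


def combine_fills(
    df: np.ndarray, mf: np.ndarray, init: AssociationMatrix
) -> AssociationMatrix:
    """Noisy-OR combination of the two fills: mdr = 1 − (1 − DF)(1 − MF).

    Provenance: K where the initial matrix held a 1, D/M/B by which fill is
    positive, E where both are zero.
    """
    df = np.asarray(df, dtype=float)
    mf = np.asarray(mf, dtype=float)
    if df.shape != init.shape or mf.shape != init.shape:
        raise ValueError("fill matrices must match the association matrix shape")
    for name, arr in (("DF", df), ("MF", mf)):
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise ValueError(f"{name} entries must lie in [0, 1]")
    values = 1.0 - (1.0 - df) * (1.0 - mf)
    values = np.clip(values, 0.0, 1.0)
    prov = np.full(init.shape, PROV_EMPTY, dtype="<U1")
    prov[(df > 0) & (mf == 0)] = PROV_DISEASE
    prov[(df == 0) & (mf > 0)] = PROV_METABOLITE
    prov[(df > 0) & (mf > 0)] = PROV_BOTH
    prov[init.values == 1.0] = PROV_KNOWN
    return AssociationMatrix(
        init.metabolite_labels, init.disease_labels, values, prov
    )


def coverage_stats(mdr: AssociationMatrix) -> CoverageReport:
    """Provenance-class counts of a completed matrix (they always partition
    the |M|·|D| cells) and the resulting coverage rate."""
    prov = mdr.provenance
    report = CoverageReport(
        n_known=int((prov == PROV_KNOWN).sum()),
        n_disease_only=int((prov == PROV_DISEASE).sum()),
        n_metabolite_only=int((prov == PROV_METABOLITE).sum()),
        n_both=int((prov == PROV_BOTH).sum()),
        n_empty=int((prov == PROV_EMPTY).sum()),
    )
    if report.total - report.n_known == 0:
        report.degenerate = True
    assert report.total == mdr.shape[0] * mdr.shape[1]
    return report
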