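"""Self-contained synthetic datasets with the structure the model assumes.

The generator draws non-negative ground-truth factor matrices of a chosen
rank, turns their inner products into association probabilities in [0, 1],
and derives everything else from that single latent structure: disease and
metabolite similarities are (noisy) cosine similarities of the true factor
rows — encoding the assumption that functionally adjacent metabolites relate
to similar diseases — and the observed 0–1 association maps are sampled from
the top-probability cells, with a later "version 2" release that is a strict
superset of "version 1" so the data-increment validation scheme applies.  A
toy ontology/vocabulary covering the five disease-naming cases (plural and
possessive variants, special symbols, abbreviations, inverted word order,
true synonyms) makes the name-annotation pipeline testable end to end.

Everything is deterministic given the seed; fixtures are written in the
exact external formats the production readers consume (OBO, MEDIC TSV,
metabolite XML, STITCH-style score TSV, labeled similarity/pair TSVs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .association import SimilarityMatrix
from .evaluation import AssociationMapVersion
from .lfm import FactorPair
from .vocab import MedicEntry, OntologyTerm

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "write_fixture"]

# Raw literature-score range used when serializing metabolite similarity as a
# STITCH-style table (score = SCORE_MIN + sim * (SCORE_MAX - SCORE_MIN)).
SCORE_MIN = 150.0
SCORE_MAX = 900.0

# The five naming cases, mapped onto the first five toy diseases:
# (ontology name, ontology synonyms, MEDIC name or None, MEDIC synonyms,
#  surface form used in the metabolite XML)
_NAMING_CASES = [
    # 1. singular/plural/possessive: possessive+inverted MEDIC label
    ("Hodgkin disease", (), "Disease, Hodgkin's", (), "Disease, Hodgkin's"),
    # 2. special symbols / spacing
    ("chickenpox", (), "Chicken Pox", (), "Chicken Pox"),
    # 3. abbreviation via explicit synonym
    ("anorexia nervosa", ("AN",), None, (), "AN"),
    # 4. inverted word order
    (
        "type 1 diabetes mellitus",
        (),
        "Diabetes Mellitus, Type 1",
        (),
        "Diabetes Mellitus, Type 1",
    ),
    # 5. true synonym
    (
        "malignant tumor of lingual tonsil",
        ("malignant neoplasm of lingual tonsil",),
        None,
        (),
        "malignant neoplasm of lingual tonsil",
    ),
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults: 40 diseases × 60 metabolites with rank-3 latent structure,
    5% of cells observed in version 1, 2% more in version 2, similarity
    noise 0.05.
    """

    n_diseases: int = 40
    n_metabolites: int = 60
    true_rank: int = 3
    observation_density: float = 0.05
    version2_extra_density: float = 0.02
    similarity_noise: float = 0.05
    seed: int = 7

    def __post_init__(self) -> None:
        if self.true_rank > min(self.n_diseases, self.n_metabolites):
            raise ValueError("true_rank exceeds the matrix dimensions")
        if not 0 < self.observation_density <= 1:
            raise ValueError("observation_density must be in (0, 1]")
        if not 0 <= self.version2_extra_density < 1:
            raise ValueError("version2_extra_density must be in [0, 1)")
        if self.similarity_noise < 0:
            raise ValueError("similarity_noise must be non-negative")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    metabolite_labels: list[str]
    disease_labels: list[str]
    true_factors: FactorPair
    true_probabilities: np.ndarray  # metabolites × diseases, in [0, 1]
    disease_similarity: SimilarityMatrix
    metabolite_similarity: SimilarityMatrix
    version1: AssociationMapVersion
    version2: AssociationMapVersion
    ontology_terms: list[OntologyTerm] = field(default_factory=list)
    medic_entries: list[MedicEntry] = field(default_factory=list)
    disease_surface_names: dict[str, str] = field(default_factory=dict)


def _cosine_rows(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1)
    norms[norms == 0] = 1.0
    sim = (mat @ mat.T) / np.outer(norms, norms)
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


def _noisy_similarity(
    base: np.ndarray, noise: float, rng: np.random.Generator
) -> np.ndarray:
    if noise > 0:
        n = base.shape[0]
        upper = rng.normal(0.0, noise, size=(n, n))
        upper = np.triu(upper, k=1)
        base = base + upper + upper.T
    base = np.clip(base, 0.0, 1.0)
    np.fill_diagonal(base, 1.0)
    return base


def _rescale_offdiag(sim: np.ndarray) -> np.ndarray:
    """Min-max rescale the off-diagonal entries to span [0, 1] exactly."""
    mask = ~np.eye(sim.shape[0], dtype=bool)
    lo, hi = sim[mask].min(), sim[mask].max()
    if hi - lo < 1e-12:
        return sim
    out = sim.copy()
    out[mask] = (sim[mask] - lo) / (hi - lo)
    return out


def _toy_vocabulary(
    disease_labels: list[str],
) -> tuple[list[OntologyTerm], list[MedicEntry], dict[str, str]]:
    terms: list[OntologyTerm] = []
    medic: list[MedicEntry] = []
    surfaces: dict[str, str] = {}
    for j, doid in enumerate(disease_labels):
        if j < len(_NAMING_CASES):
            name, syns, medic_name, medic_syns, surface = _NAMING_CASES[j]
            mesh_id = f"MESH:D{700000 + j:06d}"
            xrefs = frozenset({mesh_id}) if medic_name else frozenset()
            terms.append(
                OntologyTerm(
                    term_id=doid, name=name, synonyms=frozenset(syns), xrefs=xrefs
                )
            )
            if medic_name:
                medic.append(
                    MedicEntry(
                        medic_id=mesh_id,
                        name=medic_name,
                        synonyms=frozenset(medic_syns),
                    )
                )
        else:
            name = f"synthetic disorder {j}"
            surface = name
            terms.append(OntologyTerm(term_id=doid, name=name))
        surfaces[doid] = surface
    return terms, medic, surfaces


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n_d, n_m, r = config.n_diseases, config.n_metabolites, config.true_rank

    dlf = rng.uniform(0.0, 1.0, size=(n_d, r))
    mlf = rng.uniform(0.0, 1.0, size=(n_m, r))
    probs = mlf @ dlf.T
    probs = probs / probs.max()

    disease_labels = [f"DOID:{9000000 + j}" for j in range(n_d)]
    metabolite_labels = [f"HMDB{7000000 + i:07d}" for i in range(n_m)]

    dsim_vals = _noisy_similarity(_cosine_rows(dlf), config.similarity_noise, rng)
    msim_vals = _noisy_similarity(_cosine_rows(mlf), config.similarity_noise, rng)
    # Metabolite similarity spans [0, 1] so the STITCH-style score file
    # round-trips exactly through min-max normalization.
    msim_vals = _rescale_offdiag(msim_vals)
    dsim = SimilarityMatrix(labels=disease_labels, values=dsim_vals, kind="disease")
    msim = SimilarityMatrix(
        labels=metabolite_labels, values=msim_vals, kind="metabolite"
    )

    n_cells = n_d * n_m
    n_v1 = int(round(config.observation_density * n_cells))
    n_v2 = int(round((config.observation_density + config.version2_extra_density) * n_cells))
    if n_v1 == 0:
        raise ValueError("configuration yields zero version-1 pairs")
    if config.version2_extra_density > 0:
        n_v2 = max(n_v2, n_v1 + 1)

    flat = probs.ravel()
    threshold = np.quantile(flat, 0.75)
    eligible = np.flatnonzero(flat >= threshold)
    n_v2 = min(n_v2, eligible.size)
    if n_v2 <= n_v1 and config.version2_extra_density > 0:
        raise ValueError("not enough high-probability cells for two versions")
    # Weight by probability so sampled pairs concentrate on the strongest cells.
    weights = flat[eligible] / flat[eligible].sum()
    chosen_v2 = rng.choice(eligible, size=n_v2, replace=False, p=weights)
    chosen_v1 = rng.choice(chosen_v2, size=n_v1, replace=False)

    def cells_to_pairs(cells: np.ndarray) -> set[tuple[str, str]]:
        rows, cols = np.unravel_index(cells, (n_m, n_d))
        return {
            (metabolite_labels[i], disease_labels[j]) for i, j in zip(rows, cols)
        }

    v2_pairs = cells_to_pairs(chosen_v2)
    v1_pairs = cells_to_pairs(chosen_v1)
    version1 = AssociationMapVersion.from_pairs(
        "v1", v1_pairs, metabolites=metabolite_labels, diseases=disease_labels
    )
    version2 = AssociationMapVersion.from_pairs(
        "v2", v2_pairs, metabolites=metabolite_labels, diseases=disease_labels
    )

    terms, medic, surfaces = _toy_vocabulary(disease_labels)
    return SyntheticDataset(
        config=config,
        metabolite_labels=metabolite_labels,
        disease_labels=disease_labels,
        true_factors=FactorPair(dlf=dlf, mlf=mlf),
        true_probabilities=probs,
        disease_similarity=dsim,
        metabolite_similarity=msim,
        version1=version1,
        version2=version2,
        ontology_terms=terms,
        medic_entries=medic,
        disease_surface_names=surfaces,
    )


def _write_obo(terms: list[OntologyTerm], path: Path) -> int:
    lines = ["format-version: 1.2", "ontology: synthetic-doid", ""]
    for t in terms:
        lines.append("[Term]")
        lines.append(f"id: {t.term_id}")
        lines.append(f"name: {t.name}")
        for syn in sorted(t.synonyms):
            lines.append(f'synonym: "{syn}" EXACT []')
        for xref in sorted(t.xrefs):
            lines.append(f"xref: {xref}")
        if t.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    path.write_text("\n".join(lines))
    return len(terms)


def _write_medic(entries: list[MedicEntry], path: Path) -> int:
    rows = ["DiseaseName\tDiseaseID\tSynonyms"]
    for e in entries:
        rows.append(f"{e.name}\t{e.medic_id}\t{'|'.join(sorted(e.synonyms))}")
    path.write_text("\n".join(rows) + "\n")
    return len(entries)


def _write_metabolite_xml(ds: SyntheticDataset, path: Path) -> int:
    from lxml import etree

    by_met: dict[str, list[str]] = {m: [] for m in ds.metabolite_labels}
    for m, d in sorted(ds.version2.pairs):
        by_met[m].append(ds.disease_surface_names[d])
    root = etree.Element("hmdb")
    for met in ds.metabolite_labels:
        el = etree.SubElement(root, "metabolite")
        etree.SubElement(el, "accession").text = met
        etree.SubElement(el, "name").text = f"synthetic metabolite {met}"
        dis_el = etree.SubElement(el, "diseases")
        for name in by_met[met]:
            d_el = etree.SubElement(dis_el, "disease")
            etree.SubElement(d_el, "name").text = name
    path.write_bytes(etree.tostring(root, pretty_print=True))
    return len(ds.metabolite_labels)


def _write_scores(ds: SyntheticDataset, score_path: Path, mapping_path: Path) -> int:
    labels = ds.metabolite_labels
    sim = ds.metabolite_similarity.values
    rows = ["chemical1\tchemical2\ttextmining"]
    n = 0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            score = SCORE_MIN + sim[i, j] * (SCORE_MAX - SCORE_MIN)
            rows.append(f"CIDm{i:08d}\tCIDm{j:08d}\t{score:.6f}")
            n += 1
    score_path.write_text("\n".join(rows) + "\n")
    mapping = ["chemical\tmetabolite"]
    mapping += [f"CIDm{i:08d}\t{lab}" for i, lab in enumerate(labels)]
    mapping_path.write_text("\n".join(mapping) + "\n")
    return n


def write_fixture(ds: SyntheticDataset, directory) -> dict:
    """Write the dataset as production-format input files; returns a manifest
    mapping each written file to its row/record count."""
    from .io import write_pairs, write_similarity

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}
    manifest["ontology.obo"] = _write_obo(ds.ontology_terms, directory / "ontology.obo")
    manifest["medic.tsv"] = _write_medic(ds.medic_entries, directory / "medic.tsv")
    manifest["metabolites.xml"] = _write_metabolite_xml(
        ds, directory / "metabolites.xml"
    )
    manifest["scores.tsv"] = _write_scores(
        ds, directory / "scores.tsv", directory / "chemical_mapping.tsv"
    )
    manifest["chemical_mapping.tsv"] = len(ds.metabolite_labels)
    write_similarity(ds.disease_similarity, directory / "disease_similarity.tsv")
    manifest["disease_similarity.tsv"] = len(ds.disease_labels)
    manifest["version1.tsv"] = write_pairs(
        sorted(ds.version1.pairs), directory / "version1.tsv"
    )
    manifest["version2.tsv"] = write_pairs(
        sorted(ds.version2.pairs), directory / "version2.tsv"
    )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
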