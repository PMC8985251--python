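import numpy as np
import pytest

from dlmpm.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """Compact synthetic dataset shared across read-only tests."""
    return generate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def tiny_config():
    """A config small enough for per-test regeneration."""
    return SyntheticConfig(
        n_diseases=12,
        n_metabolites=16,
        true_rank=2,
        observation_density=0.08,
        version2_extra_density=0.04,
        similarity_noise=0.02,
        seed=3,
    )


TOY_OBO = """format-version: 1.2
ontology: toy-doid

[Term]
id: DOID:8567
name: Hodgkin disease

[Term]
id: DOID:8659
name: chickenpox
xref: MESH:D002644

[Term]
id: DOID:8689
name: anorexia nervosa
synonym: "AN" EXACT []

[Term]
id: DOID:9744
name: type 1 diabetes mellitus
xref: MESH:D003922

[Term]
id: DOID:4143
name: orbital neoplasm

[Term]
id: DOID:8649
name: malignant tumor of lingual tonsil
synonym: "malignant neoplasm of lingual tonsil" EXACT []

[Term]
id: DOID:8692
name: myelocytic leukemia
synonym: "Leukemia, Myelocytic" EXACT []

[Term]
id: DOID:0001
name: retired disorder
is_obsolete: true
"""

TOY_MEDIC = """DiseaseName\tDiseaseID\tSynonyms
Chicken Pox\tMESH:D002644\t
Diabetes Mellitus, Type 1\tMESH:D003922\tType 1 Diabetes|IDDM
Unmappable Condition\tMESH:D999999\tNowhere Syndrome
"""


@pytest.fixture(scope="session")
def toy_vocab():
    import io

    from dlmpm.vocab import build_vocabulary, parse_medic, parse_ontology

    terms = parse_ontology(io.StringIO(TOY_OBO))
    medic = parse_medic(io.StringIO(TOY_MEDIC))
    return build_vocabulary(terms, medic)


def random_association_matrix(rng, n_m=6, n_d=5, density=0.3):
    from dlmpm.association import AssociationMatrix, PROV_EMPTY, PROV_KNOWN

    values = (rng.random((n_m, n_d)) < density).astype(float)
    prov = np.where(values == 1.0, PROV_KNOWN, PROV_EMPTY)
    return AssociationMatrix(
        [f"m{i}" for i in range(n_m)],
        [f"d{j}" for j in range(n_d)],
        values,
        prov,
    )


def random_similarity(rng, labels, kind):
    from dlmpm.association import SimilarityMatrix

    n = len(labels)
    a = rng.random((n, n))
    vals = (a + a.T) / 2
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(labels=list(labels), values=vals, kind=kind)
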