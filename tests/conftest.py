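import numpy as np
import pytest

from rhamnopan import synthetic_data as sd
from rhamnopan.ortholog_calling import build_presence_matrix


@pytest.fixture(scope="session")
def reference():
    """Standard simulated reference: 300 genes, 6 islands, embedded CRISPR."""
    return sd.default_reference(seed=11)


@pytest.fixture(scope="session")
def small_reference():
    """Compact reference (40 genes, 2 islands) for fast per-module tests."""
    crispr = sd.simulate_reference_crispr(seed=5)
    return sd.simulate_reference(n_genes=40, n_islands=2, island_sizes=(8, 8),
                                 genome_length=60_000, seed=5, crispr=crispr)


@pytest.fixture(scope="session")
def cohort(reference):
    """16-strain dairy/intestinal cohort with coupled phenotypes."""
    return sd.simulate_cohort(reference, {"dairy": 8, "intestinal": 8},
                              seed=11)


@pytest.fixture(scope="session")
def cohort_matrix(reference, cohort):
    strains, _ = cohort
    return build_presence_matrix(reference.annotation, reference.sequence,
                                 strains)


@pytest.fixture(scope="session")
def cohort_profiles(reference, cohort):
    from rhamnopan.crispr_typing import oligotype_cohort

    strains, _ = cohort
    profiles, _ = oligotype_cohort(reference.crispr, strains)
    return profiles


def truth_row(reference, strain) -> np.ndarray:
    """Ground-truth presence row for a simulated strain."""
    return np.array([0 if g.locus_tag in strain.truth.lost_gene_tags else 1
                     for g in reference.annotation.genes], dtype=np.int8)
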