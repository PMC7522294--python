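import numpy as np
import pandas as pd
import pytest

from sarcomix import synthetic as syn
from sarcomix.catalogs import Mutation, MutationCatalog, ReferenceCohort


@pytest.fixture(scope="session")
def small_cohort() -> ReferenceCohort:
    """Seeded 12-sample reference cohort used across clonality tests."""
    return syn.generate_reference_cohort(12, muts_per_sample=40, seed=101)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_catalog(sample_id: str, n: int, gene_prefix: str = "G", start_pos: int = 1000,
                 effect: str = "nonsynonymous") -> MutationCatalog:
    """Deterministic catalog of n distinct mutations for hand-built fixtures."""
    muts = [
        Mutation("chr1", start_pos + i, "A", "T", f"{gene_prefix}{i}", effect)
        for i in range(n)
    ]
    return MutationCatalog(sample_id, muts)


@pytest.fixture(scope="session")
def lf_dataset() -> dict:
    return syn.generate_lf_dataset([0.0, 0.3, 0.7, 1.0], n_loci=2000, noise_sd=0.02, seed=77)


@pytest.fixture(scope="session")
def expression_cohort():
    """Expression matrix with planted subtype, EMT and infiltration structure."""
    centroids = syn.make_default_centroids(n_genes=300, seed=5)
    emt_sig = syn.make_emt_signature()
    li_sig = syn.make_li_signature()
    subtypes = list(centroids.columns)
    labels = [subtypes[i % len(subtypes)] for i in range(20)]
    infiltration = [0.15 * i for i in range(20)]
    expr, truth = syn.generate_expression_with_structure(
        centroids,
        labels,
        emt_signature=emt_sig,
        emt_shift=2.0,
        emt_samples=list(range(10)),
        li_signature=li_sig,
        infiltration_level=infiltration,
        noise_sd=0.1,
        seed=6,
    )
    return {
        "expr": expr,
        "truth": truth,
        "centroids": centroids,
        "emt_signature": emt_sig,
        "li_signature": li_sig,
        "labels": labels,
        "infiltration": infiltration,
    }
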