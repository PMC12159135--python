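import numpy as np
import pandas as pd
import pytest

from nddmeta.core_io import DatasetMetadata, DatasetSummary, StudyCollection
from nddmeta.enrichment import OntologyDAG


def make_dataset(dataset_id, gene_ids, log2fc=None, se=None, p=None,
                 mean_expr=None):
    """Hand-assemble a DatasetSummary from parallel lists."""
    n = len(gene_ids)
    tab = pd.DataFrame(
        {
            "log2fc": log2fc if log2fc is not None else np.zeros(n),
            "se": se if se is not None else np.ones(n),
            "p": p if p is not None else np.full(n, 0.5),
            "mean_expr": mean_expr if mean_expr is not None else np.ones(n),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return DatasetSummary(dataset_id, tab)


def make_collection(datasets, disorders=None, phenotypes=None,
                    sample_types=None, model_systems=None):
    n = len(datasets)
    disorders = disorders or ["other"] * n
    metadata = [
        DatasetMetadata(
            dataset_id=d.dataset_id,
            disorder=disorders[i],
            phenotypes=(phenotypes or [frozenset()] * n)[i],
            sample_type=(sample_types or ["other"] * n)[i],
            model_system=(model_systems or ["non-in vitro"] * n)[i],
            n_cases=4, n_controls=4,
        )
        for i, d in enumerate(datasets)
    ]
    return StudyCollection(datasets, metadata)


@pytest.fixture
def tiny_ontology():
    """root(8 genes) -> A(4), B(4); A -> C(2).

    Annotation closure: n(C)=2, n(A)=4, n(B)=4, n(root)=8;
    IC(A)=ln2, IC(C)=ln4 = max IC.
    """
    edges = [("A", "root"), ("B", "root"), ("C", "A")]
    annotations = {
        "C": {"g1", "g2"},
        "A": {"g3", "g4"},
        "B": {"g5", "g6", "g7", "g8"},
    }
    return OntologyDAG(edges, annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
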