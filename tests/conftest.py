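import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pesignet.simulate import CONDITIONS, ExpressionStudy


def make_two_group_study(
    values: np.ndarray, n_case: int, flag: str = "PE"
) -> ExpressionStudy:
    """Tiny hand-built study: first n_case samples are cases of `flag`."""
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    pheno = pd.DataFrame(index=pd.Index(samples, name="sample"))
    for c in CONDITIONS:
        pheno[c] = 0
    pheno[flag] = [1] * n_case + [0] * (n_samples - n_case)
    return ExpressionStudy(vals, pheno)


@pytest.fixture
def balanced_spec():
    """40v40-style single-condition design used for recovery checks."""
    from pesignet.simulate import CohortSpec

    return CohortSpec(
        n_genes=400,
        n_samples=80,
        condition_prevalences={c: 0.5 for c in CONDITIONS},
        signature_sizes={"PE": 30, "asthma": 30, "excess_BMI": 30, "vitD_insufficient": 30},
        core_size=10,
        effect_size=1.0,
        noise_sd=0.5,
        seed=11,
    )


@pytest.fixture
def path_graph_net():
    """Interactome a-b-c-d-e path, all scores 0.9."""
    from pesignet.network import Interactome

    g = nx.path_graph(["a", "b", "c", "d", "e"])
    nx.set_edge_attributes(g, 0.9, "score")
    return Interactome(g)


@pytest.fixture
def tiny_dag():
    """root <- A <- B chain plus sibling C under root, all is_a."""
    from pesignet.ontology import OntologyDag

    g = nx.DiGraph()
    for t in ("root", "A", "B", "C"):
        g.add_node(t, name=t, namespace="biological_process")
    g.add_edge("A", "root", relation="is_a")
    g.add_edge("B", "A", relation="is_a")
    g.add_edge("C", "root", relation="is_a")
    return OntologyDag(g)
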