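import numpy as np
import pandas as pd
import pytest

from pathmarker import (EdgeTable, ExpressionMatrix, simulate_expression,
                        simulate_network)


@pytest.fixture(scope="session")
def planted_expression():
    """Study-scale synthetic matrix: 26+26 samples, 2000 probes, 6 planted
    discriminative probes at effect five noise-SDs."""
    em, truth = simulate_expression(n_pos=26, n_neg=26, n_probes=2000,
                                    k_informative=6, effect_size=5.0,
                                    noise_sd=1.0, seed=20120404)
    return em, truth


@pytest.fixture(scope="session")
def planted_network():
    """Synthetic association network: 6 seeds, hub on 7 of 15 backbones."""
    return simulate_network(n_nodes=60, seed_gene_count=6, hub_degree=7,
                            seed=20120404)


@pytest.fixture()
def toy_expression():
    """4 samples x 3 probes, labels (pos, pos, neg, neg)."""
    values = np.array([[5.0, 1.0, 3.0],
                       [5.5, 1.2, 3.1],
                       [1.0, 5.0, 2.9],
                       [1.2, 5.5, 3.0]])
    return ExpressionMatrix(values, ["s1", "s2", "s3", "s4"],
                            ["pA", "pB", "pC"], np.array([1, 1, 0, 0]))


def make_edge_table(triples, scale="thousand"):
    return EdgeTable(pd.DataFrame(triples,
                                  columns=["node_a", "node_b", "score"]),
                     scale=scale)
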