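import pandas as pd
import pytest

from matrixrnai import CtTable, ExpressionCompendium, assemble_network
from matrixrnai.network import RegulatoryEdge


@pytest.fixture
def small_compendium():
    """2 genes x 4 samples, two groups, hand-checkable means."""
    values = pd.DataFrame(
        {"f1": [10.0, 5.0], "f2": [10.0, 5.0], "b1": [5.0, 5.0], "b2": [5.0, 5.0]},
        index=["GENE_UP", "GENE_FLAT"],
    )
    groups = pd.Series(
        {"f1": "fibroblast", "f2": "fibroblast", "b1": "other", "b2": "other"}
    )
    return ExpressionCompendium(values=values, groups=groups)


@pytest.fixture
def minimal_ct_table():
    """Control + one knockdown, one measured gene, 4 replicates each."""
    rows = []
    for cond, dcts in [("NC", [5.0, 5.1, 4.9, 5.0]), ("TFA", [3.0, 3.1, 2.9, 3.0])]:
        for rep, dct in enumerate(dcts, 1):
            rows.append(
                {
                    "condition": cond,
                    "gene": "TFA",
                    "replicate": rep,
                    "ct_target": 20.0 + dct,
                    "ct_reference": 20.0,
                }
            )
    return CtTable(records=pd.DataFrame(rows), control_label="NC")


def make_edge(source, target, sign="activating", log2_ratio=None, p_value=0.01):
    if log2_ratio is None:
        log2_ratio = -2.0 if sign == "activating" else 2.0
    return RegulatoryEdge(
        source=source, target=target, sign=sign, log2_ratio=log2_ratio, p_value=p_value
    )


def make_network(edge_pairs, nodes, signs=None):
    """Build a network from (source, target) pairs with default attributes."""
    edges = [
        make_edge(s, t, sign=(signs or {}).get((s, t), "activating"))
        for s, t in edge_pairs
    ]
    return assemble_network(edges, nodes)


def random_network(rng, n_nodes=8, density=0.3):
    nodes = [f"N{i}" for i in range(n_nodes)]
    pairs = [
        (s, t)
        for s in nodes
        for t in nodes
        if s != t and rng.random() < density
    ]
    signs = {
        p: ("inhibiting" if rng.random() < 0.3 else "activating") for p in pairs
    }
    return make_network(pairs, nodes, signs)
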