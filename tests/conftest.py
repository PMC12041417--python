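import numpy as np
import pytest

from alertgs.alerts import GeneAlert
from alertgs.genesets import GeneSetDAG
from alertgs.prep import prepare_alerts


@pytest.fixture
def exchangeable_prepared():
    """200 genes with i.i.d. uniform alerts in (3, 48): exchangeable null."""
    rng = np.random.default_rng(123)
    table = [
        GeneAlert(f"g{i:03d}", float(a), "up")
        for i, a in enumerate(rng.uniform(3, 48, size=200))
    ]
    return prepare_alerts(table, intended_direction="up", cmax=48.0, seed=5)


@pytest.fixture
def diamond_dag():
    """A -> {B, C} -> D with child-subset memberships."""
    import networkx as nx

    g = nx.DiGraph([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])
    sets = {
        "A": frozenset({"g1", "g2", "g3", "g4", "g5"}),
        "B": frozenset({"g1", "g2", "g3"}),
        "C": frozenset({"g3", "g4"}),
        "D": frozenset({"g3"}),
    }
    return GeneSetDAG(sets=sets, graph=g)
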