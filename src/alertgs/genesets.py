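"""Gene-set collections with optional hierarchical (DAG) structure.

A :class:`GeneSetDAG` stores named gene sets plus parent->child edges, e.g.
a Gene Ontology "biological process" subgraph where every child's genes are
contained in each parent.  Size filtering keeps the full edge graph around
so that parent/child queries can resolve *transitively* through
filtered-out nodes -- required by the LocMin decorrelation step, which
must not see the hierarchy artificially broken by the >=10-gene filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class GeneSetDAG:
    sets: dict            # set_id -> frozenset of gene ids
    names: dict = field(default_factory=dict)
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)  # parent -> child
    universe: frozenset | None = None
    #: full graph incl. nodes removed by filtering (for transitive queries)
    full_graph: nx.DiGraph | None = None

    def __post_init__(self):
        if self.full_graph is None:
            self.full_graph = self.graph.copy()
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("gene-set hierarchy contains a cycle")

    @property
    def set_ids(self) -> list:
        return list(self.sets)

    def size(self, set_id) -> int:
        return len(self.sets[set_id])

    def neighbors(self, set_id) -> tuple[set, set]:
        """Direct (parents, children) by the current edge list."""
        if set_id not in self.sets:
            raise KeyError(f"unknown set id: {set_id}")
        if set_id not in self.graph:
            return set(), set()
        return set(self.graph.predecessors(set_id)), set(self.graph.successors(set_id))

    def resolved_neighbors(self, set_id, analyzed=None) -> tuple[set, set]:
        """(parents, children) resolved transitively through nodes not in
        ``analyzed`` (default: the current set collection).

        A neighbor chain A -> x -> B where x was filtered out makes A a
        resolved parent of B.
        """
        analyzed = set(self.sets) if analyzed is None else set(analyzed)
        g = self.full_graph
        if set_id not in g:
            return set(), set()

        def reach(start, direction):
            found, stack, visited = set(), [start], {start}
            while stack:
                node = stack.pop()
                nbrs = g.predecessors(node) if direction == "up" else g.successors(node)
                for nb in nbrs:
                    if nb in visited:
                        continue
                    visited.add(nb)
                    if nb in analyzed:
                        found.add(nb)
                    else:
                        stack.append(nb)
            return found

        return reach(set_id, "up"), reach(set_id, "down")

    def validate_hierarchy(self) -> list:
        """Warn on parent-child pairs violating child-subset-of-parent."""
        bad = []
        for p, c in self.graph.edges:
            if p in self.sets and c in self.sets and not self.sets[c] <= self.sets[p]:
                bad.append((p, c))
        if bad:
            logger.warning("%d edges violate child ⊆ parent", len(bad))
        return bad


def read_gmt(path) -> GeneSetDAG:
    """Read a GMT file (set_id <tab> description <tab> members...)."""
    sets, names = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: need >=3 fields")
            set_id, desc = parts[0], parts[1]
            sets[set_id] = frozenset(parts[2:])
            names[set_id] = desc
    return GeneSetDAG(sets=sets, names=names)


def read_edges(path, dag: GeneSetDAG | None = None) -> nx.DiGraph:
    """Parent->child edge list TSV (two columns, optional header)."""
    g = nx.DiGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed edge line {lineno}")
            if lineno == 1 and parts[:2] == ["parent_id", "child_id"]:
                continue
            g.add_edge(parts[0], parts[1])
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("edge list contains a cycle")
    if dag is not None:
        dag.graph = g
        dag.full_graph = g.copy()
    return g


def restrict_to_universe(dag: GeneSetDAG, universe) -> GeneSetDAG:
    """Intersect every set's membership with the analyzed gene universe."""
    uni = frozenset(universe)
    return GeneSetDAG(
        sets={k: v & uni for k, v in dag.sets.items()},
        names=dict(dag.names),
        graph=dag.graph.copy(),
        universe=uni,
        full_graph=dag.full_graph.copy(),
    )


def filter_by_size(
    dag: GeneSetDAG, min_size: int = 10, max_size: int | None = None
) -> GeneSetDAG:
    """Keep sets with min_size <= |members| <= max_size.

    Current edges are restricted to surviving nodes; the full graph is
    retained so that :meth:`GeneSetDAG.resolved_neighbors` can traverse
    removed nodes transitively.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    keep = {
        k: v
        for k, v in dag.sets.items()
        if len(v) >= min_size and (max_size is None or len(v) <= max_size)
    }
    sub = dag.graph.subgraph([n for n in dag.graph if n in keep]).copy()
    return GeneSetDAG(
        sets=keep,
        names={k: dag.names.get(k, "") for k in keep},
        graph=sub,
        universe=dag.universe,
        full_graph=dag.full_graph.copy(),
    )


def write_gmt(dag: GeneSetDAG, path) -> None:
    with open(path, "w") as fh:
        for sid, members in dag.sets.items():
            desc = dag.names.get(sid, "")
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def write_edges(dag: GeneSetDAG, path) -> None:
    with open(path, "w") as fh:
        fh.write("parent_id\tchild_id\n")
        for p, c in dag.full_graph.edges:
            fh.write(f"{p}\t{c}\n")
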