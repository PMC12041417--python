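"""DAG-aware decorrelation of gene-set p-values.

Hierarchical collections such as the Gene Ontology produce heavily
overlapping sets, so neighboring sets share signal.  Two remedies are
implemented:

* **LocMin** -- a set's p-value is retained only if it is strictly smaller
  than the p-values of all its parents and children (resolved transitively
  through sets filtered out of the analysis).  Evaluated as a single
  simultaneous pass against the original p-value map, which makes the
  result independent of iteration order.
* **elim** -- the classic bottom-up Fisher-test decorrelation used as a
  comparison baseline: gene sets are tested children-first with a
  hypergeometric overrepresentation test of the genes alerted before a
  time/concentration cutoff, and genes of significant sets are removed
  from all their ancestors before those are tested.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .genesets import GeneSetDAG


def locmin_filter(p_values: dict, dag: GeneSetDAG) -> dict:
    """Keep a set iff its p-value is strictly smaller than every
    p-valued parent's and child's.

    Neighborless sets are kept vacuously; exact ties drop both sides
    (strict inequality).  Returns ``{set_id: bool}`` over all p-valued sets.
    """
    analyzed = set(p_values)
    kept = {}
    for sid, p in p_values.items():
        parents, children = dag.resolved_neighbors(sid, analyzed=analyzed)
        nbr = (parents | children) - {sid}
        kept[sid] = all(p < p_values[q] for q in nbr)
    return kept


def fisher_overrepresentation(significant_genes, universe, group) -> float:
    """One-sided hypergeometric tail p-value of the group/significant overlap."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sig = set(significant_genes) & uni
    grp = set(group) & uni
    overlap = len(sig & grp)
    return float(hypergeom.sf(overlap - 1, len(uni), len(sig), len(grp)))


def elim_procedure(
    dag: GeneSetDAG,
    gene_alerts: dict,
    cutoff: float = 20.0,
    alpha: float = 0.05,
    universe=None,
    p_fun=None,
) -> dict:
    """Bottom-up elim decorrelation of Fisher overrepresentation tests.

    ``gene_alerts`` maps gene -> alert value (genes without an alert are
    simply absent); a gene is "significant" when its alert <= cutoff.
    Sets are processed in reverse topological order (children before
    parents, ties broken by set id); whenever a set tests below alpha its
    member genes are removed from the memberships of all its ancestors
    before those are tested.

    Returns ``{set_id: p_value}`` computed under elimination; significant
    sets are those with p < alpha.
    """
    if p_fun is None:
        p_fun = fisher_overrepresentation
    if universe is None:
        universe = dag.universe or frozenset().union(*dag.sets.values())
    sig_genes = {g for g, a in gene_alerts.items() if a is not None and a <= cutoff}

    order = _bottom_up_order(dag)
    current = {sid: set(m) for sid, m in dag.sets.items()}
    pvals = {}
    for sid in order:
        pvals[sid] = p_fun(sig_genes, universe, current[sid])
        if pvals[sid] < alpha:
            for anc in _ancestors(dag, sid):
                if anc in current:
                    current[anc] -= dag.sets[sid]
    return pvals


def _bottom_up_order(dag: GeneSetDAG) -> list:
    """Children before parents; sets not in the graph come first by id."""
    g = dag.graph
    topo = list(nx.lexicographical_topological_sort(g))
    in_graph = [sid for sid in reversed(topo) if sid in dag.sets]
    loose = sorted(sid for sid in dag.sets if sid not in g)
    return loose + in_graph


def _ancestors(dag: GeneSetDAG, sid) -> set:
    if sid not in dag.full_graph:
        return set()
    return nx.ancestors(dag.full_graph, sid)


def elim_significant(dag: GeneSetDAG, gene_alerts: dict, cutoff: float = 20.0,
                     alpha: float = 0.05, universe=None) -> set:
    """Convenience: ids significant under :func:`elim_procedure`."""
    p = elim_procedure(dag, gene_alerts, cutoff=cutoff, alpha=alpha, universe=universe)
    return {sid for sid, v in p.items() if v < alpha}


# ---------------------------------------------------------------------------
# comparison utilities


def _around(dag: GeneSetDAG, sid) -> set:
    parents, children = dag.resolved_neighbors(sid)
    return {sid} | parents | children


def compare_result_lists(alert_gs_sets, elim_sets, dag: GeneSetDAG):
    """(intersect, #AlertGS hits found by elim-or-neighbors, vice versa).

    The second count is the number of AlertGS sets for which the set itself
    or one of its parents/children appears in the elim list; the third is
    the symmetric count over the elim list.
    """
    A, E = set(alert_gs_sets), set(elim_sets)
    intersect = len(A & E)
    a_in_e = sum(1 for a in A if _around(dag, a) & E)
    e_in_a = sum(1 for e in E if _around(dag, e) & A)
    return intersect, a_in_e, e_in_a


def topk_with_neighbors(sorted_sets, truth, dag: GeneSetDAG, k_max: int = 50):
    """For k = 1..k_max: how many true groups (or a direct parent/child of
    one) appear among the top-k sets.  May exceed k when one identified set
    neighbors several true groups."""
    if k_max > len(sorted_sets):
        raise ValueError("k_max exceeds the number of ranked sets")
    truth_around = {t: _around(dag, t) for t in truth}
    counts = []
    top = set()
    for k in range(1, k_max + 1):
        top.add(sorted_sets[k - 1])
        counts.append(sum(1 for t in truth_around.values() if t & top))
    return counts


def benjamini_hochberg(p_values: dict, alpha: float = 0.05) -> dict:
    """Plain BH-FDR flags, provided as an optional classic alternative."""
    ids = list(p_values)
    p = np.array([p_values[i] for i in ids])
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.flatnonzero(passed)) + 1 if passed.any() else 0
    cut = p[order][k - 1] if k else -1.0
    return {i: bool(pv <= cut) for i, pv in zip(ids, p)}
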