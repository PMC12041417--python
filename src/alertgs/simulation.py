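"""Simulation framework: synthetic alert data on a (synthetic or real)
hierarchical gene-set collection, plus evaluation metrics.

Three regimes generate gene-wise alerts on the window [3, 48] (weeks, the
time range the design emulates):

* **null** -- no group carries signal; a fraction ``r`` of all genes gets
  i.i.d. Uniform(3, 48) background alerts.
* **independent** -- ``n`` meaningful groups (sizes 20..200) are drawn,
  each with an integer group alert g in {5..46}; per group,
  ``ceil(x * size)`` members *currently without an alert* receive
  Beta(2,2)-shaped alerts on [g-2, g+2] (mean g), groups processed in draw
  order.
* **iterative** -- groups are processed by increasing g; ``ceil(x * size)``
  members are sampled from *all* members, but only currently unassigned
  genes receive alerts, so a gene shared between groups keeps the alert of
  the earliest group.

Both alternative regimes then overlay Uniform(3, 48) background alerts on
a fraction ``r`` of all genes; a background candidate only replaces a
meaningful alert when it is strictly smaller.

Every picked group draws from its own RNG substream keyed by draw order,
so on pairwise-disjoint collections the independent and iterative regimes
produce identical truths for the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .decorrelation import _around, compare_result_lists, elim_significant, topk_with_neighbors
from .genesets import GeneSetDAG
from .prep import prepare_alerts
from .pipeline import analyze_gene_sets

ALERT_LOW, ALERT_HIGH = 3.0, 48.0
GROUP_ALERT_RANGE = (5, 46)  # inclusive integer support for group alerts


@dataclass
class SimulationScenario:
    regime: str = "iterative"          # null | independent | iterative
    n_meaningful: int = 10
    ratio_meaningful_x: float = 0.3
    ratio_uniform_r: float = 0.1
    seed: int = 0
    n_runs: int = 200
    permutations: int = 1000
    alpha: float = 0.05

    def __post_init__(self):
        if self.regime not in ("null", "independent", "iterative"):
            raise ValueError(f"unknown regime: {self.regime}")
        if self.regime == "null":
            self.n_meaningful = 0


@dataclass
class SimulatedTruth:
    universe: list
    alerts: dict = field(default_factory=dict)        # gene -> alert value
    provenance: dict = field(default_factory=dict)    # gene -> meaningful|background
    source_group: dict = field(default_factory=dict)  # gene -> set_id
    group_alerts: dict = field(default_factory=dict)  # set_id -> integer g (draw order)
    regime: str = "null"

    def alert_table(self):
        """GeneAlert-like records (direction 'up' for alerted genes)."""
        from .alerts import GeneAlert

        return [
            GeneAlert(g, self.alerts.get(g), "up" if g in self.alerts else "none")
            for g in self.universe
        ]


def sample_meaningful_alert(g: int, rng: np.random.Generator, size=None):
    """Beta(2,2) * 4 + (g - 2): support [g-2, g+2], mean g."""
    return rng.beta(2.0, 2.0, size=size) * 4.0 + (g - 2.0)


def simulate_null(universe, r: float, seed) -> SimulatedTruth:
    """ceil(r*N) genes get i.i.d. Uniform(3, 48) alerts; no meaningful groups."""
    if not 0 < r < 1:
        raise ValueError("r must be in (0,1)")
    rng = _as_rng(seed)
    universe = list(universe)
    n = math.ceil(r * len(universe))
    chosen = rng.choice(len(universe), size=n, replace=False)
    truth = SimulatedTruth(universe=universe, regime="null")
    vals = rng.uniform(ALERT_LOW, ALERT_HIGH, size=n)
    for i, v in zip(chosen, vals):
        g = universe[int(i)]
        truth.alerts[g] = float(v)
        truth.provenance[g] = "background"
    return truth


def pick_meaningful_groups(dag: GeneSetDAG, n: int, seed,
                           size_range=(20, 200)) -> list:
    """n distinct groups uniform from the size-window pool, each with an
    independent integer group alert in {5..46} (repeats across groups OK)."""
    rng = _as_rng(seed)
    pool = sorted(s for s in dag.sets if size_range[0] <= len(dag.sets[s]) <= size_range[1])
    if len(pool) < n:
        raise ValueError(f"only {len(pool)} eligible groups for n={n}")
    picked = [pool[int(i)] for i in rng.choice(len(pool), size=n, replace=False)]
    lo, hi = GROUP_ALERT_RANGE
    alerts = rng.integers(lo, hi + 1, size=n)
    return [(sid, int(g)) for sid, g in zip(picked, alerts)]


def _group_streams(picked, seed):
    """One RNG substream per picked group, keyed by draw order."""
    ss = np.random.SeedSequence(_seed_int(seed))
    return [np.random.default_rng(s) for s in ss.spawn(len(picked))]


def _assign_group(truth, members_sorted, g, x, rng, candidates, sid):
    """Sample ceil(x*|group|) genes from `candidates` and alert the
    currently unassigned ones from the group's Beta window."""
    needed = min(math.ceil(x * len(members_sorted)), len(candidates))
    if needed == 0:
        return
    sel = rng.choice(len(candidates), size=needed, replace=False)
    targets = [candidates[int(i)] for i in sel]
    fresh = [t for t in targets if t not in truth.alerts]
    vals = sample_meaningful_alert(g, rng, size=len(fresh))
    for t, v in zip(fresh, np.atleast_1d(vals)):
        truth.alerts[t] = float(v)
        truth.provenance[t] = "meaningful"
        truth.source_group[t] = sid


def simulate_independent(dag: GeneSetDAG, picked, x: float, seed) -> SimulatedTruth:
    """Groups processed in draw order; genes selected only among members
    currently without an alert (all remaining ones when fewer exist)."""
    if not 0 < x <= 1:
        raise ValueError("x must be in (0,1]")
    universe = sorted(dag.universe or frozenset().union(*dag.sets.values()))
    truth = SimulatedTruth(universe=universe, regime="independent",
                           group_alerts={sid: g for sid, g in picked})
    for (sid, g), rng in zip(picked, _group_streams(picked, seed)):
        members = sorted(dag.sets[sid])
        candidates = [m for m in members if m not in truth.alerts]
        _assign_group(truth, members, g, x, rng, candidates, sid)
    return truth


def simulate_iterative(dag: GeneSetDAG, picked, x: float, seed) -> SimulatedTruth:
    """Groups processed by increasing group alert (draw order on ties);
    genes sampled from all members, but an already-alerted gene keeps the
    alert of the earlier (smaller-g) group."""
    if not 0 < x <= 1:
        raise ValueError("x must be in (0,1]")
    universe = sorted(dag.universe or frozenset().union(*dag.sets.values()))
    truth = SimulatedTruth(universe=universe, regime="iterative",
                           group_alerts={sid: g for sid, g in picked})
    streams = _group_streams(picked, seed)
    order = sorted(range(len(picked)), key=lambda i: (picked[i][1], i))
    for i in order:
        sid, g = picked[i]
        members = sorted(dag.sets[sid])
        _assign_group(truth, members, g, x, streams[i], members, sid)
    return truth


def add_background(truth: SimulatedTruth, r: float, seed) -> SimulatedTruth:
    """Overlay Uniform(3,48) alerts on ceil(r*N) genes; a candidate is kept
    only when the gene has no meaningful alert or a strictly larger one."""
    if not 0 < r < 1:
        raise ValueError("r must be in (0,1)")
    rng = _as_rng(seed)
    n = math.ceil(r * len(truth.universe))
    chosen = rng.choice(len(truth.universe), size=n, replace=False)
    vals = rng.uniform(ALERT_LOW, ALERT_HIGH, size=n)
    for i, v in zip(chosen, vals):
        g = truth.universe[int(i)]
        old = truth.alerts.get(g)
        if old is None or v < old:
            truth.alerts[g] = float(v)
            truth.provenance[g] = "background"
            truth.source_group.pop(g, None)
    return truth


def simulate_truth(scenario: SimulationScenario, dag: GeneSetDAG, run_seed) -> SimulatedTruth:
    """Full truth for one run of a scenario (group picking, meaningful
    alerts, background overlay), driven by independent substreams."""
    ss = np.random.SeedSequence(_seed_int(run_seed))
    s_pick, s_groups, s_bg = ss.spawn(3)
    if scenario.regime == "null":
        return simulate_null(
            sorted(dag.universe or frozenset().union(*dag.sets.values())),
            scenario.ratio_uniform_r, np.random.default_rng(s_bg))
    picked = pick_meaningful_groups(dag, scenario.n_meaningful, np.random.default_rng(s_pick))
    sim = simulate_independent if scenario.regime == "independent" else simulate_iterative
    truth = sim(dag, picked, scenario.ratio_meaningful_x, s_groups)
    return add_background(truth, scenario.ratio_uniform_r, np.random.default_rng(s_bg))


# ---------------------------------------------------------------------------
# synthetic hierarchical collection


def synthesize_dag(n_genes: int = 5000, n_sets: int = 600, depth: int = 4,
                   overlap: float = 0.1, seed: int = 0) -> GeneSetDAG:
    """Random GO-like DAG: child ⊆ parent, sizes spanning ~[10, several
    hundred], and a heavy right tail of per-gene annotation counts.

    Layered construction: leaf sets sample genes with Pareto-weighted
    probabilities (heavy multi-annotation tail); each higher level unions
    2-4 children plus a few extra genes; ``overlap`` controls extra
    cross-level edges injected before the final upward membership closure.
    """
    if n_genes < 100 or n_sets < depth + 1 or depth < 2 or not 0 <= overlap <= 1:
        raise ValueError("infeasible generator parameters")
    rng = _as_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)], dtype=object)
    w = rng.pareto(1.5, size=n_genes) + 1.0
    w /= w.sum()

    # geometric level sizes, leaves largest
    props = np.array([0.5**lv for lv in range(depth)], float)
    counts = np.maximum((n_sets * props / props.sum()).astype(int), 1)
    counts[0] += n_sets - counts.sum()

    g = nx.DiGraph()
    base_members: dict = {}
    levels: list[list[str]] = []
    for lv in range(depth):
        ids = [f"S{lv}_{i:04d}" for i in range(counts[lv])]
        levels.append(ids)
        for sid in ids:
            if lv == 0:
                size = int(np.clip(rng.lognormal(np.log(25.0), 0.7), 8, 120))
                base_members[sid] = set(
                    rng.choice(genes, size=size, replace=False, p=w)
                )
            else:
                nc = int(rng.integers(2, 5))
                children = rng.choice(levels[lv - 1], size=min(nc, len(levels[lv - 1])),
                                      replace=False)
                for c in children:
                    g.add_edge(sid, c)
                extra = int(rng.integers(0, 6))
                base_members[sid] = set(
                    rng.choice(genes, size=extra, replace=False, p=w)
                ) if extra else set()
            g.add_node(sid)

    # GO groups typically have several parents and/or children: guarantee
    # at least two parents for every non-root node so no set sits isolated
    for lv in range(depth - 1):
        uppers = levels[lv + 1]
        for sid in levels[lv]:
            need = 2 - g.in_degree(sid)
            if need > 0 and len(uppers) >= 2:
                have = set(g.predecessors(sid))
                avail = [u for u in uppers if u not in have]
                for u in rng.choice(avail, size=min(need, len(avail)),
                                    replace=False):
                    g.add_edge(u, sid)

    n_cross = int(overlap * g.number_of_edges())
    for _ in range(n_cross):
        lp = int(rng.integers(1, depth))
        lc = int(rng.integers(0, lp))
        parent = levels[lp][int(rng.integers(len(levels[lp])))]
        child = levels[lc][int(rng.integers(len(levels[lc])))]
        if parent != child:
            g.add_edge(parent, child)

    # upward closure: every node's members include all descendants' genes
    sets: dict = {}
    for sid in reversed(list(nx.topological_sort(g))):
        m = set(base_members[sid])
        for c in g.successors(sid):
            m |= sets[c]
        sets[sid] = m
    for sid in base_members:
        sets.setdefault(sid, set(base_members[sid]))

    return GeneSetDAG(
        sets={k: frozenset(v) for k, v in sets.items()},
        names={k: "" for k in sets},
        graph=g,
        universe=frozenset(genes),
    )


# ---------------------------------------------------------------------------
# evaluation


def evaluate_run(results: pd.DataFrame, truth: SimulatedTruth, dag: GeneSetDAG,
                 k_max: int = 50, elim_cutoff: float = 20.0,
                 alpha: float = 0.05, include_elim: bool = False) -> dict:
    """Per-run metrics: true/total positives after LocMin, neighborhood
    recovery, alert-estimation errors, top-k curve, and (optionally) the
    comparison counts against the Fisher/elim baseline."""
    meaningful = set(truth.group_alerts)
    if results.empty:
        sig = set()
    else:
        sig = set(results.loc[results["significant_locmin"], "set_id"])
    tp = len(meaningful & sig)
    recovered = sum(1 for t in meaningful if _around(dag, t) & sig)

    errors = []
    if not results.empty:
        est = dict(zip(results["set_id"], results["alert_gs"]))
        for t in meaningful & sig:
            e = est.get(t, np.nan)
            if np.isfinite(e):
                errors.append(e - truth.group_alerts[t])

    metrics = {
        "n_meaningful": len(meaningful),
        "true_positives": tp,
        "total_significant": len(sig),
        "recovered_with_neighbors": recovered,
        "alert_errors": errors,
    }

    if not results.empty and meaningful:
        kept = results.loc[results["locmin_kept"]].sort_values(
            ["p_gumbel", "set_id"], kind="stable")
        ranked = list(kept["set_id"])
        kk = min(k_max, len(ranked))
        metrics["topk_counts"] = (
            topk_with_neighbors(ranked, meaningful, dag, kk) if kk else []
        )

    if include_elim and not results.empty:
        elim = elim_significant(dag, truth.alerts, cutoff=elim_cutoff, alpha=alpha)
        mask = results["significant_locmin"] & (results["alert_gs"] <= elim_cutoff)
        alert_sets = set(results.loc[mask.fillna(False), "set_id"])
        inter, a_in_e, e_in_a = compare_result_lists(alert_sets, elim, dag)
        metrics.update(
            n_alertgs=len(alert_sets), n_elim=len(elim),
            intersect=inter, elim_alertgs_or_around=a_in_e,
            alertgs_elim_or_around=e_in_a,
        )
    return metrics


def run_scenario(scenario: SimulationScenario, dag: GeneSetDAG,
                 cmax: float = ALERT_HIGH, include_elim: bool = False,
                 k_max: int = 50) -> pd.DataFrame:
    """Simulate + analyze + evaluate ``scenario.n_runs`` independent runs."""
    ss = np.random.SeedSequence(_seed_int(scenario.seed))
    rows = []
    for run, child in enumerate(ss.spawn(scenario.n_runs)):
        s_truth, s_prep, s_analysis = child.spawn(3)
        truth = simulate_truth(scenario, dag, s_truth)
        prepared = prepare_alerts(
            truth.alert_table(), intended_direction="up", cmax=cmax,
            seed=_seed_int(s_prep))
        results = analyze_gene_sets(
            prepared, dag, P=scenario.permutations,
            seed=_seed_int(s_analysis), alpha=scenario.alpha)
        m = evaluate_run(results, truth, dag, k_max=k_max,
                         include_elim=include_elim, alpha=scenario.alpha)
        m["run"] = run
        m["median_alert_error"] = (
            float(np.median(m["alert_errors"])) if m["alert_errors"] else np.nan
        )
        rows.append(m)
    return pd.DataFrame(rows)


def table1_scenarios(seed: int = 0, n_runs: int = 200) -> list[SimulationScenario]:
    """The full simulation grid: 3 null + 2 regimes x {10,20,50} x {0.1,0.3,0.5}."""
    out = [
        SimulationScenario(regime="null", ratio_uniform_r=r, seed=seed, n_runs=n_runs)
        for r in (0.05, 0.1, 0.15)
    ]
    for regime in ("independent", "iterative"):
        for n in (10, 20, 50):
            for x in (0.1, 0.3, 0.5):
                out.append(SimulationScenario(
                    regime=regime, n_meaningful=n, ratio_meaningful_x=x,
                    ratio_uniform_r=0.1, seed=seed, n_runs=n_runs))
    return out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _seed_int(seed) -> int:
    """Collapse int / SeedSequence / Generator seeds to a 31-bit integer."""
    if isinstance(seed, (int, np.integer)):
        return int(seed) & 0x7FFFFFFF
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0]) & 0x7FFFFFFF
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(0, 2**31))
    raise TypeError(f"cannot derive a seed from {type(seed)}")
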