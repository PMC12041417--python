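"""End-to-end orchestration of the gene set-wise alert analysis.

Given prepared gene-wise alerts and a (possibly hierarchical) gene-set
collection, each set receives: running-sum Enrichment Score, empirical
permutation p-value, smooth rectified-Gumbel p-value, a group-wise alert
estimate (for globally significant sets), and a LocMin decorrelation flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alert_estimation import estimate_alert_gs
from .decorrelation import locmin_filter
from .enrichment import (
    enrichment_score,
    fit_rectified_gumbel,
    gumbel_pvalue,
    permutation_null,
    permutation_pvalue,
    running_sum,
)
from .genesets import GeneSetDAG
from .prep import PreparedAlerts


def analyze_gene_sets(
    prepared: PreparedAlerts,
    dag: GeneSetDAG,
    P: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    ratio_threshold: float = 0.05,
    pvalue_flavor: str = "gumbel",
    cmax: float | None = None,
) -> pd.DataFrame:
    """Run enrichment, alert estimation, and LocMin over all sets.

    Sets are processed in sorted-id order, each with its own RNG substream
    spawned from ``seed``, so results are reproducible and independent of
    iteration order.  Group-wise alerts are estimated for sets whose
    global p-value (of the chosen flavor) falls below ``alpha``; the same
    stored permutations drive both the p-value and the alert estimate.
    """
    if pvalue_flavor not in ("gumbel", "permutation"):
        raise ValueError("pvalue_flavor must be 'gumbel' or 'permutation'")
    if cmax is None:
        cmax = prepared.cmax
    universe = set(prepared.gene_ids)
    set_ids = sorted(dag.sets)
    seeds = np.random.SeedSequence(seed).spawn(len(set_ids))

    rows = []
    for sid, ss in zip(set_ids, seeds):
        members = dag.sets[sid] & universe
        M = len(members)
        if M == 0 or M == len(universe):
            continue
        rs = running_sum(prepared, members)
        es, argmax_alert = enrichment_score(rs, cmax)
        null = permutation_null(
            prepared, M, P=P, cmax=cmax, seed=np.random.default_rng(ss)
        )
        p_perm = permutation_pvalue(es, null)
        try:
            mu, beta = fit_rectified_gumbel(null.es_values)
            p_gum = gumbel_pvalue(es, mu, beta)
        except (ValueError, RuntimeError):
            mu = beta = np.nan
            p_gum = p_perm
        p_used = p_gum if pvalue_flavor == "gumbel" else p_perm
        alert_gs = np.nan
        if p_used < alpha:
            res = estimate_alert_gs(
                rs, null, prepared, members,
                threshold=ratio_threshold, cmax=cmax, set_id=sid,
            )
            if res.alert_gs is not None:
                alert_gs = res.alert_gs
        rows.append(
            {
                "set_id": sid,
                "size": M,
                "es": es,
                "argmax_alert": argmax_alert,
                "p_perm": p_perm,
                "p_gumbel": p_gum,
                "gumbel_mu": mu,
                "gumbel_beta": beta,
                "alert_gs": alert_gs,
            }
        )

    df = pd.DataFrame(rows)
    if df.empty:
        df["locmin_kept"] = []
        df["significant_locmin"] = []
        return df
    pcol = "p_gumbel" if pvalue_flavor == "gumbel" else "p_perm"
    pmap = dict(zip(df["set_id"], df[pcol]))
    kept = locmin_filter(pmap, dag)
    df["locmin_kept"] = df["set_id"].map(kept)
    df["significant_locmin"] = (df[pcol] < alpha) & df["locmin_kept"]
    return df
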