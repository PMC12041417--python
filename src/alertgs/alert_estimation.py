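"""Group-wise alert estimation from the running sum and its permutation null.

For a gene set already deemed globally significant, the member genes'
correct-direction alerts are visited in increasing order.  At each member
alert ``a`` the original running sum RS_a is compared against the same
quantity RS_ia of every stored permutation; the ratio #{RS_ia >= RS_a}/P
is a local exceedance probability, and the smallest ``a`` where it drops
to the threshold (default 0.05) is the group-wise alert, AlertGS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enrichment import NullDistribution, RunningSum, step_weights
from .prep import ORIGIN_CORRECT, PreparedAlerts


@dataclass
class AlertGSResult:
    set_id: str
    alert_gs: float | None
    ratio_trace: list          # (alert a, RS_a, ratio) per evaluated candidate
    threshold: float = 0.05


def ratio_at_alert(a: float, rs: RunningSum, null: NullDistribution,
                   cmax: float | None = None) -> float:
    """Exceedance ratio #{RS_ia >= RS_a} / P at one alert coordinate."""
    if cmax is not None and a > cmax:
        raise ValueError("alert coordinate beyond cmax")
    k = int(np.searchsorted(rs.sorted_alerts, a, side="right"))
    rs_a = float(rs.values[k - 1]) if k > 0 else 0.0
    perm = null.values_at_position(k)
    return float(np.count_nonzero(perm >= rs_a)) / null.P


def estimate_alert_gs(
    rs: RunningSum,
    null: NullDistribution,
    prepared: PreparedAlerts,
    members,
    threshold: float = 0.05,
    cmax: float | None = None,
    set_id: str = "",
) -> AlertGSResult:
    """Smallest member alert where the running sum beats the permutation
    null at the given ratio threshold.

    Candidate coordinates are exactly the member genes' correct-direction
    prepared alerts (<= cmax); imputed or wrong-direction members are not
    interpretable alert coordinates.  The stored permutations from the
    global test are reused, so p-value and alert estimate are mutually
    consistent.  ``alert_gs`` is None when no candidate ratio qualifies.
    """
    if cmax is None:
        cmax = prepared.cmax
    mask = np.zeros(prepared.n_genes, dtype=bool)
    mask[prepared.positions(set(members))] = True
    mask &= prepared.origin == ORIGIN_CORRECT
    mask &= prepared.prepared_values <= cmax
    idx = np.flatnonzero(mask)          # already in increasing alert order
    if idx.size == 0:
        return AlertGSResult(set_id, None, [], threshold)

    alerts = prepared.prepared_values[idx]
    ks = idx + 1                        # prefix length including this gene
    rs_vals = rs.values[idx]
    up, down = step_weights(null.N, null.M)
    # per-permutation member counts at each candidate prefix length
    m = np.vstack([np.searchsorted(row, ks, side="left") for row in null.positions])
    perm_vals = m * up - (ks[None, :] - m) * down
    ratios = (perm_vals >= rs_vals[None, :]).sum(axis=0) / null.P

    trace = [(float(a), float(v), float(r)) for a, v, r in zip(alerts, rs_vals, ratios)]
    hit = np.flatnonzero(ratios <= threshold)
    alert_gs = float(alerts[hit[0]]) if hit.size else None
    return AlertGSResult(set_id, alert_gs, trace, threshold)
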