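"""Gene-wise alert (ALEC) derivation from condition-response data.

Two-step MCP-Mod style procedure per gene:

1. *MCP step* -- for each candidate shape an optimal contrast against a flat
   profile is tested; multiplicity over candidates is handled through the
   Monte-Carlo distribution of the maximum contrast statistic under the
   fitted (flat Gaussian) null.  A gene is significant iff at least one
   candidate's adjusted p-value falls below alpha.
2. *Mod step* -- each significant candidate is fitted by least squares and
   the winner minimizes the information criterion (AIC).

From the winner model the ALEC (absolute lowest effective concentration) is
found by grid search: the smallest condition value where the fitted curve
departs from its value at the lowest tested condition by the effect size
(default log2(1.5)) upward or downward; when both directions yield an ALEC
only the minimum is retained.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .models import CandidateModel, default_candidates, evaluate_model, fit_model

logger = logging.getLogger(__name__)

#: default pre-specified expression change on the log2 scale
DEFAULT_EFFECT = math.log2(1.5)


@dataclass
class ResponseProfile:
    """One gene's responses across increasing condition values.

    ``responses[i][j]`` is the j-th replicate at condition
    ``condition_values[i]`` (log2-scale expression).  Condition values must
    be strictly increasing with at least two distinct levels.
    """

    gene_id: str
    condition_values: np.ndarray
    responses: list  # one 1-d array of replicates per condition

    def __post_init__(self):
        self.condition_values = np.asarray(self.condition_values, float)
        if self.condition_values.ndim != 1 or self.condition_values.size < 2:
            raise ValueError("need >=2 distinct condition values")
        if np.any(np.diff(self.condition_values) <= 0):
            raise ValueError("condition values must be strictly increasing")
        if np.any(self.condition_values < 0):
            raise ValueError("condition values must be non-negative")
        self.responses = [np.atleast_1d(np.asarray(r, float)) for r in self.responses]
        if len(self.responses) != self.condition_values.size:
            raise ValueError("one replicate vector per condition required")
        if any(r.size < 1 for r in self.responses):
            raise ValueError("every condition needs >=1 replicate")

    @property
    def x0(self) -> float:
        return float(self.condition_values[0])

    @property
    def cmax(self) -> float:
        return float(self.condition_values[-1])

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) with x repeated per replicate."""
        x = np.concatenate(
            [np.full(r.size, c) for c, r in zip(self.condition_values, self.responses)]
        )
        y = np.concatenate(self.responses)
        return x, y


@dataclass
class GeneAlert:
    gene_id: str
    alert: float | None = None
    direction: str = "none"  # up | down | none
    winner_model: CandidateModel | None = None
    significant: bool = False


# ---------------------------------------------------------------------------
# MCP step


def _optimal_contrast(mu0: np.ndarray, n_i: np.ndarray) -> np.ndarray:
    """Optimal contrast for a candidate mean vector under homoscedasticity.

    c_i proportional to n_i * (mu0_i - weighted mean), normalized to unit
    Euclidean norm; the test statistic is invariant to the scaling.
    """
    w = n_i / n_i.sum()
    c = n_i * (mu0 - np.sum(w * mu0))
    nrm = np.linalg.norm(c)
    if nrm < 1e-12:
        raise ValueError("candidate shape is flat over the tested conditions")
    return c / nrm


@lru_cache(maxsize=64)
def _max_abs_t_null(key: bytes, k: int, df: int, n_sims: int) -> np.ndarray:
    """Sorted Monte-Carlo sample of max_j |t_j| under the flat Gaussian null.

    ``key`` packs the contrast matrix (J x k) and replicate counts; the RNG
    seed is a stable digest of the design so results are reproducible and
    shared across genes measured under the same design.
    """
    buf = np.frombuffer(key, dtype=float)
    n_i = buf[:k]
    C = buf[k:].reshape(-1, k)
    denom = np.sqrt((C**2 / n_i).sum(axis=1))  # per-candidate SE factor
    seed = zlib.crc32(key) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_sims, k)) / np.sqrt(n_i)
    s = np.sqrt(rng.chisquare(df, size=n_sims) / df)
    T = (Z @ C.T) / (s[:, None] * denom)
    return np.sort(np.abs(T).max(axis=1))


def mcp_test(
    profile: ResponseProfile,
    candidates: list[CandidateModel] | None = None,
    alpha: float = 0.05,
    n_sims: int = 20000,
) -> dict[str, tuple[float, float, bool]]:
    """Contrast test of each candidate shape against a flat profile.

    Returns ``{name: (t_statistic, adjusted_p, significant)}``.  The
    adjusted p-value is two-sided and multiplicity-corrected over the
    candidate set via the Monte-Carlo max-|t| null distribution.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    xs = profile.condition_values
    if xs.size < 3:
        raise ValueError("need >=3 distinct conditions to form a contrast")
    if candidates is None:
        candidates = default_candidates(profile.x0, profile.cmax)

    n_i = np.array([r.size for r in profile.responses], float)
    ybar = np.array([r.mean() for r in profile.responses])
    df = int(n_i.sum()) - xs.size
    if df < 1:
        raise ValueError("no residual degrees of freedom for the variance estimate")
    rss = sum(float(((r - r.mean()) ** 2).sum()) for r in profile.responses)
    sigma = math.sqrt(rss / df)

    C = np.vstack(
        [
            _optimal_contrast(
                np.asarray(evaluate_model(c.name, xs, c.shape_parameters)), n_i
            )
            for c in candidates
        ]
    )
    num = C @ ybar
    if sigma == 0.0:
        # perfectly replicated responses: a contrast is either exactly met
        # (infinite evidence) or pure numerical dust (no evidence)
        tol = 1e-9 * max(1.0, float(np.abs(ybar).max()))
        t = np.zeros_like(num)
        exceeds = np.abs(num) > tol
        t[exceeds] = np.sign(num[exceeds]) * np.inf
    else:
        denom = sigma * np.sqrt((C**2 / n_i).sum(axis=1))
        t = num / denom

    key = np.concatenate([n_i, C.ravel()]).tobytes()
    null = _max_abs_t_null(key, xs.size, df, n_sims)
    # upper-tail count on the sorted MC sample
    padj = 1.0 - np.searchsorted(null, np.abs(t), side="left") / n_sims
    return {
        c.name: (float(ti), float(pi), bool(pi < alpha))
        for c, ti, pi in zip(candidates, t, padj)
    }


def select_winner(
    profile: ResponseProfile, significant: list[CandidateModel | str]
) -> CandidateModel | None:
    """Fit each significant candidate and return the AIC-minimizing one.

    Ties are broken by candidate list order (stable argmin).  Candidates
    whose fit does not converge are excluded and logged; ``None`` if no
    candidate is significant or fittable.
    """
    if not significant:
        return None
    x, y = profile.flat()
    fits = []
    for cand in significant:
        name = cand if isinstance(cand, str) else cand.name
        m = fit_model(name, x, y)
        if m is None:
            logger.warning("fit failed for %s on gene %s", name, profile.gene_id)
            continue
        fits.append(m)
    if not fits:
        return None
    best = fits[0]
    for m in fits[1:]:
        if m.information_criterion < best.information_criterion:
            best = m
    return best


# ---------------------------------------------------------------------------
# ALEC


def compute_alec(
    model: CandidateModel,
    x0: float,
    cmax: float,
    direction: str,
    grid_step: float | None = None,
    effect: float = DEFAULT_EFFECT,
) -> float | None:
    """Grid-search ALEC: smallest c in [x0, cmax] with f(c) crossing lambda.

    ``lambda = f(x0) + effect`` for ``direction='up'`` and
    ``f(x0) - effect`` for ``'down'``.  The grid has step
    ``(cmax - x0)/10000`` by default and the crossing is refined once by
    bisection within the bracketing grid cell.  ``None`` when the fitted
    response range never reaches lambda on the interval.
    """
    if model.fitted_parameters is None:
        raise ValueError("model must be fitted")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if grid_step is None:
        grid_step = (cmax - x0) / 10000.0
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")

    grid = np.arange(x0, cmax + grid_step / 2, grid_step)
    if grid[-1] < cmax:
        grid = np.append(grid, cmax)
    f = np.asarray(evaluate_model(model.name, grid, model.fitted_parameters))
    lam = f[0] + effect if direction == "up" else f[0] - effect
    hit = f >= lam if direction == "up" else f <= lam
    hit[0] = False  # the baseline itself never counts
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return None
    i = int(idx[0])
    lo, hi = grid[i - 1], grid[i]
    # one bisection refinement pass within the bracketing cell
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        fm = evaluate_model(model.name, mid, model.fitted_parameters)
        ok = fm >= lam if direction == "up" else fm <= lam
        if ok:
            hi = mid
        else:
            lo = mid
        if hi - lo < grid_step * 1e-6:
            break
    return float(min(max(hi, x0), cmax))


def derive_gene_alert(
    up_alec: float | None, down_alec: float | None
) -> tuple[float | None, str]:
    """Combine up- and down-regulation ALECs: only the minimum is retained."""
    if up_alec is not None and down_alec is not None:
        return (up_alec, "up") if up_alec <= down_alec else (down_alec, "down")
    if up_alec is not None:
        return up_alec, "up"
    if down_alec is not None:
        return down_alec, "down"
    return None, "none"


# ---------------------------------------------------------------------------
# count filtering


def nonzero_threshold(n_samples: int, min_fraction: float = 0.5) -> int:
    """Smallest integer strictly exceeding ``min_fraction * n_samples``."""
    return int(math.floor(min_fraction * n_samples)) + 1


def filter_genes(
    counts: pd.DataFrame,
    min_fraction: float = 0.5,
    groups: dict[str, list[str]] | None = None,
) -> list[str]:
    """Genes with nonzero counts in more than ``min_fraction`` of samples.

    ``groups`` maps a group label to its sample (column) names; the rule is
    applied per group with AND across groups.  Default: all columns form
    one group.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0,1]")
    if counts.size == 0:
        raise ValueError("empty count matrix")
    if groups is None:
        groups = {"all": list(counts.columns)}
    keep = pd.Series(True, index=counts.index)
    for cols in groups.values():
        sub = counts[cols]
        thr = nonzero_threshold(len(cols), min_fraction)
        keep &= (sub != 0).sum(axis=1) >= thr
    return list(counts.index[keep])


# ---------------------------------------------------------------------------
# table-level driver and TSV interfaces


def derive_alerts(
    responses: pd.DataFrame,
    candidates: list[CandidateModel] | None = None,
    alpha: float = 0.05,
    effect: float = DEFAULT_EFFECT,
    grid_step: float | None = None,
    direction_policy: str = "both-min",
) -> pd.DataFrame:
    """Run the full gene-wise alert pipeline on a response matrix.

    ``responses`` has genes as rows and one column per replicate; column
    names (or a first header row parsed by :func:`read_response_matrix`)
    carry the numeric condition value, replicates sharing a value.

    Returns a table with columns gene_id, alert, direction, winner_model,
    significant.
    """
    cond = np.asarray([float(c) for c in responses.columns])
    order = np.argsort(cond, kind="stable")
    cond = cond[order]
    levels = np.unique(cond)
    rows = []
    for gene_id, row in responses.iterrows():
        vals = row.to_numpy(float)[order]
        prof = ResponseProfile(
            str(gene_id), levels, [vals[cond == lv] for lv in levels]
        )
        rows.append(derive_single_alert(
            prof, candidates=candidates, alpha=alpha, effect=effect,
            grid_step=grid_step, direction_policy=direction_policy))
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "alert": a.alert if a.alert is not None else np.nan,
                "direction": a.direction,
                "winner_model": a.winner_model.name if a.winner_model else "",
                "significant": a.significant,
            }
            for a in rows
        ]
    )


def derive_single_alert(
    profile: ResponseProfile,
    candidates: list[CandidateModel] | None = None,
    alpha: float = 0.05,
    effect: float = DEFAULT_EFFECT,
    grid_step: float | None = None,
    direction_policy: str = "both-min",
) -> GeneAlert:
    """MCP test -> winner fit -> ALEC for a single gene."""
    if candidates is None:
        candidates = default_candidates(profile.x0, profile.cmax)
    res = mcp_test(profile, candidates, alpha=alpha)
    signif = [c for c in candidates if res[c.name][2]]
    if not signif:
        return GeneAlert(profile.gene_id, significant=False)
    winner = select_winner(profile, signif)
    if winner is None:
        return GeneAlert(profile.gene_id, significant=True)
    up = down = None
    if direction_policy in ("up", "both-min"):
        up = compute_alec(winner, profile.x0, profile.cmax, "up",
                          grid_step=grid_step, effect=effect)
    if direction_policy in ("down", "both-min"):
        down = compute_alec(winner, profile.x0, profile.cmax, "down",
                            grid_step=grid_step, effect=effect)
    alert, direction = derive_gene_alert(up, down)
    return GeneAlert(profile.gene_id, alert, direction, winner, True)


def read_response_matrix(path) -> pd.DataFrame:
    """TSV with gene ids in the first column and condition values as header.

    Replicate columns share a condition value, so the header is parsed
    explicitly (pandas would otherwise deduplicate repeated labels).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cond = [float(c) for c in header[1:]]
    df = pd.read_csv(path, sep="\t", skiprows=1, header=None, index_col=0)
    df.index.name = header[0]
    df.columns = cond
    return df


def write_alert_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_alert_table(path) -> list[GeneAlert]:
    """Alert table TSV: columns gene_id, alert (blank/NaN = none), direction."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        alert = None if pd.isna(r["alert"]) else float(r["alert"])
        out.append(GeneAlert(str(r["gene_id"]), alert, str(r["direction"])))
    return out
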