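"""Running-sum enrichment statistic, permutation null, and global p-values.

For a universe of N genes sorted by prepared alert and a set of size M, the
running sum steps by +sqrt((N-M)/M) when the next gene is a member and by
-sqrt(M/(N-M)) otherwise (the classic Kolmogorov-Smirnov GSEA weights), so
it starts and ends at zero.  The Enrichment Score (ES)
is the maximum of this path over the observable alert window [0, cmax],
floored at zero.  Significance comes from permuting the membership labels
(equivalently: drawing uniform random M-subsets of the gene positions)
P times; the empirical p-value is the plain tail fraction #{ES_i >= ES}/P.

Because permutation p-values are granular and can be exactly zero, a
rectified Gumbel distribution -- the law of max(0, X) for X ~ Gumbel(mu,
beta) -- is fitted to the permuted ES values by maximum likelihood, and
the smooth p-value is one minus its CDF at ES.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .prep import PreparedAlerts


def step_weights(N: int, M: int) -> tuple[float, float]:
    """(member step, non-member step magnitude): sqrt((N-M)/M) and
    sqrt(M/(N-M)); M times the first equals (N-M) times the second, hence
    the zero-sum path."""
    if not 0 < M < N:
        raise ValueError("degenerate set: M must satisfy 0 < M < N")
    return float(np.sqrt((N - M) / M)), float(np.sqrt(M / (N - M)))


@dataclass
class RunningSum:
    sorted_alerts: np.ndarray   # prepared values, increasing
    membership: np.ndarray      # bool, aligned with sorted_alerts
    values: np.ndarray          # cumulative sum after each gene
    M: int

    @property
    def N(self) -> int:
        return self.sorted_alerts.size

    def value_at(self, a: float) -> float:
        """Right-continuous step-function value after all genes with
        prepared alert <= a."""
        k = int(np.searchsorted(self.sorted_alerts, a, side="right"))
        return float(self.values[k - 1]) if k > 0 else 0.0


@dataclass
class NullDistribution:
    """Permutation null of the ES plus everything needed to re-evaluate
    each permuted running sum at arbitrary alert coordinates.

    ``positions`` holds, per permutation, the sorted 0-based positions of
    the permuted members on the fixed sorted-alert axis: enough to
    reconstruct any permutation's running sum exactly.
    """

    es_values: np.ndarray       # (P,)
    positions: np.ndarray       # (P, M) int, sorted within each row
    N: int
    M: int
    window: int                 # number of genes with prepared alert <= cmax
    gumbel_location: float | None = None
    gumbel_scale: float | None = None

    @property
    def P(self) -> int:
        return self.es_values.size

    def values_at_position(self, k: int) -> np.ndarray:
        """Each permutation's running-sum value after the first k genes."""
        m = (self.positions < k).sum(axis=1)
        up, down = step_weights(self.N, self.M)
        return m * up - (k - m) * down


def running_sum(prepared: PreparedAlerts, members) -> RunningSum:
    """Cumulative running sum over genes sorted by prepared alert."""
    member_set = set(members)
    N = prepared.n_genes
    M = len(member_set)
    if M == 0 or M == N:
        raise ValueError("degenerate set: M must satisfy 0 < M < N")
    if not member_set <= prepared.index.keys():
        raise ValueError("members must be a subset of the analyzed universe")
    membership = np.zeros(N, dtype=bool)
    membership[prepared.positions(member_set)] = True
    up, down = step_weights(N, M)
    steps = np.where(membership, up, -down)
    values = np.cumsum(steps)
    assert abs(values[-1]) < 1e-9 * N, "running sum must end at zero"
    return RunningSum(prepared.prepared_values, membership, values, M)


def enrichment_score(rs: RunningSum, cmax: float) -> tuple[float, float]:
    """(ES, argmax_alert): max of the path over alerts <= cmax, floored at 0.

    The argmax alert is the prepared value where the maximum is attained
    (smallest such on ties); for an all-negative path ES = 0 and the
    argmax is reported at the window start.
    """
    k = int(np.searchsorted(rs.sorted_alerts, cmax, side="right"))
    if k == 0:
        return 0.0, float("nan")
    window = rs.values[:k]
    i = int(np.argmax(window))
    es = float(window[i])
    if es <= 0.0:
        return 0.0, float(rs.sorted_alerts[0])
    return es, float(rs.sorted_alerts[i])


_subset_buffer: dict = {}


def _random_subset_positions(
    rng: np.random.Generator, N: int, M: int, P: int
) -> np.ndarray:
    """P uniform M-subsets of range(N) as a (P, M) row-sorted int matrix.

    Vectorized partial Fisher-Yates: M swap rounds over P rows at once.
    The work buffer is reused across calls and re-initialized each time so
    results depend only on the generator state.
    """
    key = (P, N)
    arr = _subset_buffer.get(key)
    if arr is None or len(_subset_buffer) > 4:
        _subset_buffer.clear()
        arr = _subset_buffer.setdefault(key, np.empty((P, N), dtype=np.int32))
    arr[:] = np.arange(N, dtype=np.int32)[None, :]
    rows = np.arange(P)
    for j in range(M):
        r = rng.integers(j, N, size=P)
        tmp = arr[rows, r]
        arr[rows, r] = arr[rows, j]
        arr[rows, j] = tmp
    return np.sort(arr[:, :M], axis=1)


def permutation_null(
    prepared: PreparedAlerts,
    M: int,
    P: int = 1000,
    cmax: float | None = None,
    seed: int | np.random.Generator = 0,
) -> NullDistribution:
    """Permute membership labels P times and collect each permutation's ES.

    The running sum only increases at member genes, so its maximum over
    the window is attained immediately after a member step; the ES of a
    permutation is therefore computed from the member positions alone.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    N = prepared.n_genes
    if not 0 < M < N:
        raise ValueError("degenerate set: M must satisfy 0 < M < N")
    if cmax is None:
        cmax = prepared.cmax
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    window = int(np.searchsorted(prepared.prepared_values, cmax, side="right"))

    pos = _random_subset_positions(rng, N, M, P)
    up, down = step_weights(N, M)
    j = np.arange(M)
    # value right after the (j+1)-th member at position pos[:, j]
    vals = (j + 1) * up - (pos - j) * down
    vals = np.where(pos < window, vals, -np.inf)
    es = np.maximum(vals.max(axis=1, initial=-np.inf), 0.0)
    return NullDistribution(es_values=es, positions=pos, N=N, M=M, window=window)


def permutation_pvalue(es: float, null: NullDistribution) -> float:
    """Tail fraction #{ES_i >= ES} / P -- no small-sample correction, so an
    empirical p-value of exactly zero can occur."""
    return float(np.count_nonzero(null.es_values >= es)) / null.P


# ---------------------------------------------------------------------------
# rectified Gumbel


def _rect_gumbel_negloglik(theta, pos, n_zero):
    """Negative log-likelihood and its gradient in (mu, log beta)."""
    mu, logbeta = theta
    beta = np.exp(logbeta)
    z = (pos - mu) / beta
    ez = np.exp(-z)
    ll_pos = -np.sum(logbeta + z + ez)
    # P(X <= 0) = exp(-exp(mu/beta)) is the probability mass at zero
    emb = np.exp(mu / beta)
    ll_zero = -n_zero * emb
    dmu = np.sum(1.0 - ez) / beta - n_zero * emb / beta
    dlb = np.sum(-1.0 + z - z * ez) + n_zero * emb * mu / beta
    return -(ll_pos + ll_zero), -np.array([dmu, dlb])


def fit_rectified_gumbel(es_values) -> tuple[float, float]:
    """Maximum-likelihood (mu, beta) for max(0, Gumbel(mu, beta)) data.

    Zeros contribute the point mass F(0) = exp(-exp(mu/beta)); positive
    values the Gumbel density.  Optimization runs on (mu, log beta) from a
    moment-based start, with a coarse grid fallback.
    """
    x = np.asarray(es_values, float)
    if x.size < 10:
        raise ValueError("need at least 10 values")
    if np.any(x < 0):
        raise ValueError("rectified data must be non-negative")
    pos = x[x > 0]
    n_zero = int(np.count_nonzero(x == 0))
    if pos.size == 0:
        raise ValueError("all-zero sample: Gumbel parameters unidentifiable")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values equal")

    euler = 0.5772156649015329
    beta0 = max(pos.std() * np.sqrt(6) / np.pi, 1e-6)
    mu0 = pos.mean() - euler * beta0
    res = minimize(
        _rect_gumbel_negloglik,
        x0=np.array([mu0, np.log(beta0)]),
        args=(pos, n_zero),
        method="L-BFGS-B",
        jac=True,
    )
    if not res.success or not np.all(np.isfinite(res.x)):
        # coarse grid fallback around the moment start
        best, best_nll = None, np.inf
        for mu in np.linspace(mu0 - 3 * beta0, mu0 + 3 * beta0, 41):
            for lb in np.log(beta0) + np.linspace(-2, 2, 21):
                nll, _ = _rect_gumbel_negloglik((mu, lb), pos, n_zero)
                if nll < best_nll:
                    best, best_nll = (mu, lb), nll
        if best is None:  # pragma: no cover
            raise RuntimeError(f"rectified-Gumbel fit failed: {res.message}")
        res_x = np.array(best)
    else:
        res_x = res.x
    return float(res_x[0]), float(np.exp(res_x[1]))


def gumbel_pvalue(es: float, mu: float, beta: float) -> float:
    """1 - CDF of Gumbel(mu, beta) at es: strictly positive, strictly
    decreasing in es.  Floored at the smallest subnormal so that even an
    extreme ES never yields the exact zero the smooth p-value exists to
    avoid."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    z = (es - mu) / beta
    p = float(-np.expm1(-np.exp(-z)))
    return p if p > 0.0 else 5e-324
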