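"""Preparation of gene-wise alerts into a single globally ordered vector.

The running-sum statistic needs every analyzed gene on one axis, sorted
increasingly.  Genes with an alert in the intended direction keep their
alert; genes without any alert receive an imputed value drawn uniformly
from [cmax + eps, 2*cmax - eps]; genes with an alert in the opposite
("wrong") direction are mapped to 3*cmax - alert, which reverses their
order.  By interval construction the three blocks never interleave:

    correct (0, cmax]  <  imputed [cmax+eps, 2cmax-eps]  <  wrong (2cmax, 3cmax)

Ties are removed by adding a very small random jitter to duplicated values
only, so the prepared vector is strictly increasing once sorted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ORIGIN_CORRECT = "correct"
ORIGIN_MISSING = "imputed_missing"
ORIGIN_WRONG = "imputed_wrong"


@dataclass
class PreparedAlerts:
    """Globally sorted, tie-free alert vector over all N analyzed genes."""

    gene_ids: np.ndarray      # sorted by prepared value
    prepared_values: np.ndarray
    origin: np.ndarray        # per-gene tag, aligned with gene_ids
    cmax: float
    epsilon: float

    @property
    def n_genes(self) -> int:
        return self.prepared_values.size

    @property
    def index(self) -> dict:
        """gene_id -> position in prepared (sorted) order, built lazily."""
        idx = getattr(self, "_index", None)
        if idx is None:
            idx = {g: i for i, g in enumerate(self.gene_ids)}
            object.__setattr__(self, "_index", idx)
        return idx

    def positions(self, members) -> np.ndarray:
        """Sorted positions (0-based, in prepared order) of the given genes."""
        idx = self.index
        return np.sort(np.array([idx[g] for g in members], dtype=np.int64))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "prepared_value": self.prepared_values,
                "origin": self.origin,
            }
        )


def break_ties(
    values: np.ndarray,
    jitter_scale: float,
    seed: int | np.random.Generator,
    ceiling: float | None = None,
) -> np.ndarray:
    """Make all values distinct by jittering duplicated entries only.

    Duplicates receive an additive uniform jitter in (0, jitter_scale);
    entries equal to ``ceiling`` (e.g. an alert exactly at cmax) are
    jittered downward instead so they cannot leave the valid range.
    Non-duplicated values are returned unchanged.  Deterministic given the
    seed.
    """
    if jitter_scale <= 0:
        raise ValueError("jitter_scale must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.array(values, dtype=float, copy=True)
    for _ in range(100):
        _, inv, counts = np.unique(out, return_inverse=True, return_counts=True)
        dup = counts[inv] > 1
        if not dup.any():
            return out
        jit = rng.uniform(0.0, jitter_scale, size=int(dup.sum()))
        sign = np.ones(jit.size)
        if ceiling is not None:
            sign[np.isclose(out[dup], ceiling)] = -1.0
        out[dup] = out[dup] + sign * jit
    raise RuntimeError("could not break ties")  # pragma: no cover


def impute_missing(
    n_missing: int, cmax: float, epsilon: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Uniform draws on [cmax + eps, 2*cmax - eps] for genes without alert."""
    if epsilon <= 0 or 2 * cmax - epsilon <= cmax + epsilon:
        raise ValueError("need 0 < epsilon < cmax/2 for a nonempty interval")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(cmax + epsilon, 2 * cmax - epsilon, size=n_missing)


def transform_wrong_direction(alert, cmax: float):
    """Map a wrong-direction alert to 3*cmax - alert (order-reversing)."""
    return 3 * cmax - np.asarray(alert, float) if np.ndim(alert) else 3 * cmax - alert


def prepare_alerts(
    alert_table,
    intended_direction: str = "up",
    cmax: float = 48.0,
    epsilon: float | None = None,
    seed: int = 0,
    jitter_scale: float | None = None,
) -> PreparedAlerts:
    """Build the sorted, tie-free prepared alert vector for all genes.

    ``alert_table`` is an iterable of objects with attributes ``gene_id``,
    ``alert`` (float or None) and ``direction`` in {'up','down','none'}.
    Every gene must appear exactly once.  One pipeline ``seed`` governs the
    imputation and jitter substreams.
    """
    if intended_direction not in ("up", "down"):
        raise ValueError("intended_direction must be 'up' or 'down'")
    if epsilon is None:
        epsilon = 0.01 * cmax
    if jitter_scale is None:
        jitter_scale = 1e-9 * cmax

    gene_ids, raw, origin = [], [], []
    seen = set()
    for ga in alert_table:
        if ga.gene_id in seen:
            raise ValueError(f"duplicate gene_id: {ga.gene_id}")
        seen.add(ga.gene_id)
        gene_ids.append(ga.gene_id)
        if ga.alert is None or ga.direction == "none":
            raw.append(np.nan)
            origin.append(ORIGIN_MISSING)
        elif ga.direction == intended_direction:
            raw.append(float(ga.alert))
            origin.append(ORIGIN_CORRECT)
        else:
            raw.append(transform_wrong_direction(float(ga.alert), cmax))
            origin.append(ORIGIN_WRONG)

    raw = np.asarray(raw, float)
    origin = np.asarray(origin, dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)

    ss = np.random.SeedSequence(seed)
    imp_rng, jit_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    miss = origin == ORIGIN_MISSING
    raw[miss] = impute_missing(int(miss.sum()), cmax, epsilon, imp_rng)
    # ties broken after all transforms, globally
    values = break_ties(raw, jitter_scale, jit_rng, ceiling=cmax)

    order = np.argsort(values, kind="stable")
    return PreparedAlerts(
        gene_ids=gene_ids[order],
        prepared_values=values[order],
        origin=origin[order],
        cmax=float(cmax),
        epsilon=float(epsilon),
    )


def write_prepared(prepared: PreparedAlerts, path) -> None:
    prepared.to_frame().to_csv(path, sep="\t", index=False)
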