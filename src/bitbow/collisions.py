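"""Collision-rate estimation for barcode lineage tracing.

"Collision" means two or more lineages in one brain drawing the same code.
Three estimators are provided:

* the uniform closed form (birthday problem with equal code frequencies),
  ``c = n - b * (1 - ((b - 1) / b) ** n)``, collision rate ``c / n``;
* an analytic generalisation to arbitrary code distributions,
  ``c = n - sum_i (1 - (1 - p_i) ** n)``;
* a Monte Carlo simulation drawing i.i.d. code lists and counting repeats.

Experimental cluster-level summaries (fractions of clusters uniquely
labeled vs sharing a code) are a distinct statistic and are computed per
brain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .frequency import CodeDistribution, DegenerateDistributionError, Whitelist

__all__ = [
    "CollisionEstimate",
    "expected_collision_rate_uniform",
    "expected_collision_rate_general",
    "simulate_collision_rate",
    "default_reps",
    "cluster_collision_summary",
    "code_occupancy_summary",
    "labeling_rate",
]


@dataclass(frozen=True)
class CollisionEstimate:
    """Expected collisions ``c`` among ``n`` draws from a pool of ``b`` codes."""

    n: int
    b: int
    expected_collisions: float
    rate: float
    method: str  # closed_form | analytic_general | monte_carlo
    reps: int | None = None
    seed: int | None = None
    se: float | None = None

    @property
    def percent(self) -> float:
        """Collision rate as a percentage, one decimal (round-half-even)."""
        return float(np.round(100.0 * self.rate, 1))

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n": self.n,
            "b": self.b,
            "expected_collisions": self.expected_collisions,
            "rate": self.rate,
        }
        if self.method == "monte_carlo":
            d.update(reps=self.reps, seed=self.seed, se=self.se)
        return d


def expected_collision_rate_uniform(b: int, n: int) -> CollisionEstimate:
    """Birthday-problem expected collision rate for a uniform code pool.

    With ``n`` lineages drawing uniformly from ``b`` codes the expected
    number of distinct codes is ``b * (1 - ((b-1)/b)**n)``; the expected
    collisions are the excess draws, and the rate divides by ``n``.

    >>> expected_collision_rate_uniform(31, 200).percent
    84.5
    """
    if b < 1:
        raise ValueError(f"pool size b must be >= 1, got {b}")
    if n < 0:
        raise ValueError(f"lineage count n must be >= 0, got {n}")
    if n == 0:
        c = 0.0
    else:
        c = n - b * (1.0 - ((b - 1.0) / b) ** n)
    rate = c / n if n > 0 else 0.0
    return CollisionEstimate(n=n, b=b, expected_collisions=c, rate=rate,
                             method="closed_form")


def _effective_probs(
    dist: CodeDistribution,
    whitelist: Whitelist | None,
    mode: str = "renormalize",
) -> np.ndarray:
    """Code probabilities after optional whitelist conditioning."""
    p = dist.probs
    if whitelist is None:
        return p
    if mode != "renormalize":
        raise ValueError(f"unknown whitelist mode {mode!r}")
    mass = whitelist.mass
    if mass <= 0:
        raise DegenerateDistributionError("whitelist retains zero probability mass")
    q = np.where(whitelist.mask, p, 0.0)
    return q / mass


def expected_collision_rate_general(
    dist: CodeDistribution,
    n: int,
    whitelist: Whitelist | None = None,
) -> CollisionEstimate:
    """Exact expected collision rate under an arbitrary code distribution.

    For i.i.d. draws, code ``i`` is seen at least once with probability
    ``1 - (1 - p_i)**n``, so ``E[distinct] = sum_i (1 - (1-p_i)**n)`` and
    ``c = n - E[distinct]``.  Reduces to the uniform closed form when all
    ``p_i = 1/b``.  With a whitelist, probabilities are renormalized to the
    retained codes (draws condition on usable barcodes).
    """
    if n < 0:
        raise ValueError(f"lineage count n must be >= 0, got {n}")
    p = _effective_probs(dist, whitelist)
    c = 0.0 if n == 0 else n - float((1.0 - (1.0 - p) ** n).sum())
    rate = c / n if n > 0 else 0.0
    return CollisionEstimate(
        n=n, b=int((p > 0).sum()), expected_collisions=c, rate=rate,
        method="analytic_general",
    )


def default_reps(n: int) -> int:
    """Replicate-count schedule keyed to the number of lineages drawn.

    100,000 repeats below 100 lineages, 1,000 between 100 and 1,000, and
    10 above — heavier systems get fewer repeats to bound run time.
    """
    if n < 100:
        return 100_000
    if n <= 1000:
        return 1_000
    return 10


def simulate_collision_rate(
    dist: CodeDistribution,
    n: int,
    reps: int | None = None,
    seed: int | None = None,
    whitelist: Whitelist | None = None,
    whitelist_mode: str = "renormalize",
) -> CollisionEstimate:
    """Monte Carlo collision rate: draw ``n`` codes i.i.d., count repeats.

    Per repetition the rate is ``(n - distinct)/n``; the estimate is the
    mean over ``reps`` repetitions with its standard error.  Identical seed
    yields identical output.

    ``whitelist_mode='renormalize'`` conditions the draw distribution on
    the whitelist; ``'filter'`` draws from the full distribution, discards
    non-whitelisted draws, and scores collisions among the survivors.
    """
    if n < 0:
        raise ValueError(f"lineage count n must be >= 0, got {n}")
    if reps is None:
        reps = default_reps(n)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)

    if whitelist is not None and whitelist_mode == "filter":
        p = dist.probs
        keep_mask = whitelist.mask
    else:
        p = _effective_probs(dist, whitelist, whitelist_mode)
        keep_mask = None

    if n == 0:
        return CollisionEstimate(n=0, b=int((p > 0).sum()), expected_collisions=0.0,
                                 rate=0.0, method="monte_carlo", reps=reps,
                                 seed=seed, se=0.0)

    rates = np.empty(reps)
    # chunk repetitions to bound memory at large reps * n
    chunk = max(1, min(reps, int(5e6) // max(n, 1)))
    pos = 0
    while pos < reps:
        k = min(chunk, reps - pos)
        draws = rng.choice(p.size, size=(k, n), p=p)
        if keep_mask is not None:
            for j in range(k):
                kept = draws[j][keep_mask[draws[j]]]
                if kept.size == 0:
                    rates[pos + j] = 0.0
                else:
                    distinct = np.unique(kept).size
                    rates[pos + j] = (kept.size - distinct) / kept.size
        else:
            s = np.sort(draws, axis=1)
            distinct = 1 + (np.diff(s, axis=1) != 0).sum(axis=1)
            rates[pos : pos + k] = (n - distinct) / n
        pos += k
    mean = float(rates.mean())
    se = float(rates.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return CollisionEstimate(
        n=n, b=int((p > 0).sum()), expected_collisions=mean * n, rate=mean,
        method="monte_carlo", reps=reps, seed=seed, se=se,
    )


@dataclass(frozen=True)
class SharingSummary:
    """Per-brain sharing fractions with their mean and SD across brains."""

    per_brain: pd.DataFrame  # index = brain, columns = unique/pairs/three_plus(+rate)
    mean: pd.Series
    sd: pd.Series
    n_brains: int


def _sharing_fractions(codes: Sequence[str], by_cluster: bool) -> tuple[float, float, float]:
    counts = pd.Series(codes).value_counts()
    if by_cluster:
        # weight each cluster by its code's multiplicity bucket
        weights = counts
    else:
        weights = pd.Series(1, index=counts.index)
    total = weights.sum()
    unique = weights[counts == 1].sum() / total
    pairs = weights[counts == 2].sum() / total
    three_plus = weights[counts >= 3].sum() / total
    return float(unique), float(pairs), float(three_plus)


def _summary(clusters: pd.DataFrame, by_cluster: bool) -> SharingSummary:
    if clusters is None or len(clusters) == 0:
        raise ValueError("empty cluster table")
    rows = {}
    for brain, sub in clusters.groupby("brain_id", sort=True):
        u, p, t = _sharing_fractions(sub["code"].tolist(), by_cluster)
        row = {"unique": u, "pairs": p, "three_plus": t}
        if by_cluster:
            row["collision_rate"] = 1.0 - u
        rows[brain] = row
    per_brain = pd.DataFrame.from_dict(rows, orient="index")
    mean = per_brain.mean(axis=0)
    sd = per_brain.std(axis=0, ddof=1) if len(per_brain) > 1 else mean * 0.0
    return SharingSummary(per_brain=per_brain, mean=mean, sd=sd,
                          n_brains=len(per_brain))


def cluster_collision_summary(clusters: pd.DataFrame) -> SharingSummary:
    """Fractions of clusters whose code is unique / shared by 2 / by >=3.

    Sharing is assessed within each brain separately; the experimental
    collision rate is the non-unique fraction, 1 - unique.
    """
    return _summary(clusters, by_cluster=True)


def code_occupancy_summary(clusters: pd.DataFrame) -> SharingSummary:
    """Fractions of observed *codes* appearing in 1 / 2 / >=3 clusters per brain."""
    return _summary(clusters, by_cluster=False)


def labeling_rate(
    clusters: pd.DataFrame | None,
    lineages_per_brain: int,
    n_brains: int | None = None,
) -> float:
    """Fraction of lineages labeled: clusters / (brains x lineages per brain)."""
    if lineages_per_brain < 1:
        raise ValueError("lineages_per_brain must be >= 1")
    n_clusters = 0 if clusters is None else len(clusters)
    if n_brains is None:
        if clusters is None or n_clusters == 0:
            raise ValueError("need n_brains when the cluster table is empty")
        n_brains = clusters["brain_id"].nunique()
    if n_brains < 1:
        raise ValueError("need at least one brain")
    return n_clusters / (n_brains * lineages_per_brain)
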