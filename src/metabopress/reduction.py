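"""Pivot-based correlation-clustering feature reduction.

Untargeted LC-MS feature tables are heavily collinear: adducts, isotopes and
in-source fragments of one compound produce many features whose intensities
move together across samples. The reducer partitions features into
collinearity clusters with a greedy randomized pivot algorithm and keeps one
representative (the pivot, the "hub" feature) per cluster:

1. pick a uniform-random pivot ``i`` from the surviving feature pool;
2. move every surviving feature ``j`` with ``|pearson(i, j)| > t`` into the
   pivot's cluster (strict inequality; direction of correlation is ignored);
3. repeat on the remainder until the pool is empty.

The threshold ``t`` defaults to 0.45. The resulting clusters are disjoint and
exhaustive, every member exceeds the threshold against its pivot, and any two
pivots are at most ``t`` apart in absolute correlation (each later pivot
survived the earlier pivot's stripping step).

Pairwise correlations use pairwise-complete observations; pairs with fewer
than ``min_overlap`` shared samples, and any pair involving a zero-variance
feature, are treated as below threshold (zero-variance features therefore end
up in singleton clusters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterSet",
    "pearson_threshold_check",
    "correlation_cluster",
    "select_representatives",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.45


@dataclass
class ClusterSet:
    """A partition of feature IDs into collinearity clusters.

    ``pivots[k]`` is the pivot of cluster ``k`` and ``members[k]`` its full
    member list (pivot first). ``pivot_order`` records pivots in draw order,
    which together with the feature table and ``t`` makes the run replayable.
    """

    pivots: list[str]
    members: list[list[str]]
    t: float
    seed: int
    pivot_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pivot_order:
            self.pivot_order = list(self.pivots)

    def __len__(self) -> int:
        return len(self.pivots)

    @property
    def feature_ids(self) -> list[str]:
        return [f for cluster in self.members for f in cluster]

    def cluster_of(self) -> dict[str, str]:
        """Map each feature ID to its cluster's pivot ID."""
        return {f: piv for piv, mem in zip(self.pivots, self.members) for f in mem}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "t": self.t,
            "seed": self.seed,
            "pivot_order": self.pivot_order,
            "clusters": [
                {"pivot": p, "members": m} for p, m in zip(self.pivots, self.members)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            pivots=[c["pivot"] for c in payload["clusters"]],
            members=[list(c["members"]) for c in payload["clusters"]],
            t=payload["t"],
            seed=payload["seed"],
            pivot_order=list(payload["pivot_order"]),
        )


def pearson_threshold_check(i: np.ndarray, j: np.ndarray, t: float) -> bool:
    """True iff the absolute Pearson correlation of two vectors exceeds ``t``.

    Strict inequality; ties at exactly ``t`` fail the check. Raises on length
    mismatch, fewer than 3 observations, or zero-variance input (undefined
    correlation).
    """
    x = np.asarray(i, dtype=float)
    y = np.asarray(j, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r = stats.pearsonr(x, y).statistic
    return bool(abs(r) > t)


def _abs_corr(features: pd.DataFrame, min_overlap: int) -> np.ndarray:
    """|Pearson r| matrix, pairwise-complete; undefined entries are NaN."""
    corr = features.corr(method="pearson", min_periods=min_overlap)
    return np.abs(corr.to_numpy())


def correlation_cluster(
    features: pd.DataFrame,
    t: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    min_overlap: int = 10,
) -> ClusterSet:
    """Greedily partition the table's columns into collinearity clusters.

    Parameters
    ----------
    features
        samples x features intensity table; columns are feature IDs.
    t
        absolute-correlation threshold in [0, 1); a feature joins a pivot's
        cluster iff ``|r| > t``.
    seed
        seeds the pivot draws; same table + t + seed gives an identical
        ClusterSet.
    min_overlap
        minimum pairwise-complete sample count for a correlation to be
        trusted; sparser pairs are treated as uncorrelated.
    """
    if not 0 <= t < 1:
        raise ValueError(f"threshold t must be in [0, 1), got {t}")
    ids = list(features.columns)
    if len(ids) == 0:
        return ClusterSet(pivots=[], members=[], t=t, seed=seed)

    absr = _abs_corr(features, min_overlap)
    # NaN (zero variance or insufficient overlap) never exceeds the threshold
    passing = np.nan_to_num(absr, nan=-1.0) > t

    rng = np.random.default_rng(seed)
    remaining = np.arange(len(ids))
    pivots: list[str] = []
    members: list[list[str]] = []
    while remaining.size:
        pivot_pos = rng.integers(remaining.size)
        pivot = remaining[pivot_pos]
        others = np.delete(remaining, pivot_pos)
        hit = passing[pivot, others]
        cluster = [ids[pivot]] + [ids[k] for k in others[hit]]
        pivots.append(ids[pivot])
        members.append(cluster)
        remaining = others[~hit]
    return ClusterSet(pivots=pivots, members=members, t=t, seed=seed)


def select_representatives(
    features: pd.DataFrame, clusters: ClusterSet
) -> pd.DataFrame:
    """Reduce the table to one column per cluster (the pivot, the hub feature).

    Columns appear in pivot draw order. Raises if a cluster references a
    feature absent from the table.
    """
    missing = [f for f in clusters.feature_ids if f not in features.columns]
    if missing:
        raise ValueError(f"clusters reference features absent from table: {missing[:5]}")
    return features.loc[:, clusters.pivots].copy()
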