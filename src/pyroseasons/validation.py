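"""Stability validation by random data partitioning.

The day set is split uniformly at random (optionally blocked by
calendar year) into ``k_parts`` parts; the clustering is re-run on each
part at the same radius, with the minimum cluster size scaled down in
proportion to the part size.  Agreement between each part's labels and
the full-data model's labels (restricted to that part's days) is scored
with the Adjusted Rand Index — a numeric stand-in for the visual
"similar fire-weather planes" comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .mode_clustering import ClusterModel, cluster
from .weather_io import FeatureMatrix


@dataclass
class PartitionStability:
    part_indices: list[np.ndarray]
    part_models: list[ClusterModel | None]
    ari: list[float]

    @property
    def mean_ari(self) -> float:
        return float(np.mean(self.ari)) if self.ari else float("nan")

    @property
    def min_ari(self) -> float:
        return float(np.min(self.ari)) if self.ari else float("nan")


def partition_stability(
    fm: FeatureMatrix,
    R: float,
    CK: int = 50,
    k_parts: int = 4,
    seed: int = 0,
    block_by_year: bool = False,
    full_model: ClusterModel | None = None,
) -> PartitionStability:
    """Re-cluster random day partitions and score label agreement.

    ARI is computed over days labeled (cluster > 0) in both the part
    model and the full model.  Parts whose scaled CK still exceeds half
    the part size are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    n = fm.n
    if full_model is None:
        full_model = cluster(fm.values, R, CK=CK)

    if k_parts == 1:
        parts = [np.arange(n)]
    elif block_by_year:
        years = fm.dates.year.to_numpy()
        uniq = np.unique(years)
        rng.shuffle(uniq)
        groups = np.array_split(uniq, k_parts)
        parts = [np.flatnonzero(np.isin(years, g)) for g in groups]
    else:
        perm = rng.permutation(n)
        parts = [np.sort(p) for p in np.array_split(perm, k_parts)]

    models: list[ClusterModel | None] = []
    scores: list[float] = []
    for idx in parts:
        ck_part = max(5, int(round(CK * len(idx) / n)))
        if len(idx) < 2 * ck_part:
            warnings.warn(f"partition of {len(idx)} day(s) too small; skipped")
            models.append(None)
            continue
        pm = cluster(fm.values[idx], R, CK=ck_part)
        models.append(pm)
        both = (pm.labels > 0) & (full_model.labels[idx] > 0)
        scores.append(
            float(adjusted_rand_score(full_model.labels[idx][both],
                                      pm.labels[both]))
        )
    return PartitionStability(part_indices=parts, part_models=models, ari=scores)
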