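"""Combined selection index (ICO) and rank-stratified sampling.

The breeding programme ranks animals on a weighted combination of their
predicted breeding values for milk, fat and protein (dry matter is left
out as an indirect re-measurement of fat and protein).  The published
economic weights are programme-internal, so the default here is equal
weights on standardized PBVs — a documented placeholder; weights are a
mandatory configuration surface for real use.  The genotyping sample is
drawn from three rank strata: the bottom of the ranking, a window centred
on the median rank, and the top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INDEX_TRAITS = ("milk", "fat", "protein")


@dataclass
class IndexConfig:
    traits: tuple = INDEX_TRAITS
    weights: dict = field(default_factory=lambda: {t: 1.0 for t in INDEX_TRAITS})
    standardize: bool = True

    def __post_init__(self):
        w = [self.weights[t] for t in self.traits]
        if not all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not any(v != 0 for v in w):
            raise ValueError("at least one weight must be non-zero")


def ico_scores(pbv_table: pd.DataFrame, config: IndexConfig = None) -> pd.Series:
    """ICO = sum_t w_t * z(PBV_t) (or raw PBVs when standardize is off).

    `pbv_table` is wide: index animal_id, one column per trait.  z() is the
    usual (x - mean)/sd standardization over the scored animals.
    """
    if config is None:
        config = IndexConfig()
    missing = [t for t in config.traits if t not in pbv_table.columns]
    if missing:
        raise ValueError(f"missing trait PBVs: {missing}")
    score = pd.Series(0.0, index=pbv_table.index)
    for t in config.traits:
        v = pbv_table[t].astype(float)
        if config.standardize:
            sd = v.std(ddof=0)
            v = (v - v.mean()) / sd if sd > 0 else v * 0.0
        score = score + config.weights[t] * v
    score.name = "ico"
    return score


def rank_stratified_sample(
    scores: pd.Series, n_low: int = 236, n_mid: int = 238, n_high: int = 236
) -> pd.DataFrame:
    """Bottom / median-centred / top strata of an ICO ranking.

    Ranking is ascending by score with deterministic tie-breaking by animal
    id, so a shuffled input yields the identical selection.  The middle
    stratum is the ``n_mid`` consecutive ranks centred on the median rank
    (ties resolved toward the lower rank).  Strata must not overlap.

    Returns a frame (animal_id, ico, rank, stratum) covering all scored
    animals; unselected animals carry stratum "unselected".
    """
    k = len(scores)
    if n_low + n_mid + n_high > k:
        raise ValueError("strata larger than the scored population")
    order = sorted(scores.index, key=lambda a: (scores[a], str(a)))
    stratum = pd.Series("unselected", index=pd.Index(order, name="animal_id"))
    low_set = order[:n_low]
    high_set = order[k - n_high :] if n_high else []
    median_rank = (k - 1) // 2
    start = median_rank - (n_mid - 1) // 2
    mid_set = order[start : start + n_mid]
    if set(mid_set) & (set(low_set) | set(high_set)):
        raise ValueError("middle stratum overlaps an extreme stratum")
    stratum[low_set] = "low"
    stratum[mid_set] = "mid"
    stratum[high_set] = "high"
    return pd.DataFrame(
        {
            "animal_id": order,
            "ico": [scores[a] for a in order],
            "rank": np.arange(1, k + 1),
            "stratum": stratum.to_numpy(),
        }
    )
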