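"""Weighted rank-preference indices and flock-structure descriptives.

The index for item m aggregates the proportions X_nm of respondents who
ranked m at position n = 1..4 with decreasing weights a_n (default
4, 3, 2, 1) and normalizes across items:

    index_m = sum_n a_n X_nm / sum_m sum_n a_n X_nm

so the indices sum to one and order items by rank-weighted popularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = ["RankTable", "IndexResult", "rank_index", "FlockShares", "flock_shares"]

DEFAULT_WEIGHTS = (4.0, 3.0, 2.0, 1.0)


@dataclass
class RankTable:
    """Items x ranks matrix of respondent proportions.

    ``proportions`` has one row per item and one column per rank
    (rank 1 first); entries lie in [0, 1] and each rank column may sum to
    less than 1 when some respondents ranked fewer items.  Items a
    respondent group never ranked (dashes in published tables) should be
    omitted rather than zero-filled when they are structurally absent.
    """

    proportions: pd.DataFrame
    weights: tuple = DEFAULT_WEIGHTS

    def __post_init__(self):
        p = self.proportions.to_numpy(dtype=float)
        if p.shape[1] != len(self.weights):
            raise InvalidInputError(
                f"{p.shape[1]} rank columns but {len(self.weights)} weights"
            )
        if (p < 0).any() or (p > 1).any():
            raise InvalidInputError("proportions must lie in [0, 1]")
        if any(w <= 0 for w in self.weights):
            raise InvalidInputError("weights must be positive")

    @classmethod
    def from_counts(cls, counts, weights=DEFAULT_WEIGHTS, n_respondents=None):
        """Build from raw rank counts; proportions are counts / n_respondents
        (defaulting to the largest rank-column total)."""
        counts = pd.DataFrame(counts).astype(float)
        if n_respondents is None:
            n_respondents = counts.sum(axis=0).max()
        if n_respondents <= 0:
            raise InvalidInputError("n_respondents must be positive")
        return cls(proportions=counts / n_respondents, weights=weights)


@dataclass
class IndexResult:
    """Normalized rank-preference indices, one per item (sum to 1)."""

    indices: pd.Series
    weighted_scores: pd.Series = field(repr=False, default=None)

    def sorted(self):
        return self.indices.sort_values(ascending=False)

    def to_frame(self):
        return self.sorted().rename("index").to_frame()


def rank_index(table):
    """Normalized weighted rank index for every item of a RankTable."""
    p = table.proportions.to_numpy(dtype=float)
    w = np.asarray(table.weights, dtype=float)
    scores = p @ w
    total = scores.sum()
    if total <= 0:
        raise InvalidInputError("all rank proportions are zero; index undefined")
    idx = pd.Series(scores / total, index=table.proportions.index, name="index")
    return IndexResult(indices=idx, weighted_scores=pd.Series(scores, index=idx.index))


@dataclass
class FlockShares:
    """Category shares of the overall flock and the ram:ewe ratio."""

    shares_pct: pd.Series  # percentage of total flock per category
    ewes_per_ram: int
    total_mean: float

    @property
    def ram_ewe_ratio(self):
        return f"1:{self.ewes_per_ram}"


def flock_shares(
    table,
    mean_col="overall_mean",
    total_row="total",
    ewe_row="breeding_ewes",
    ram_row="breeding_rams",
):
    """Derived flock-structure quantities from a composition table of means.

    Shares are each category's overall mean divided by the overall total
    mean, in percent; the breeding ratio is 1 : round(ewes per ram).
    """
    if total_row not in table.index:
        raise InvalidInputError(f"table lacks a {total_row!r} row")
    means = table[mean_col].astype(float)
    total = means[total_row]
    if total <= 0:
        raise InvalidInputError("total flock mean must be positive")
    shares = means.drop(total_row) / total * 100.0
    rams = means.get(ram_row, np.nan)
    ewes = means.get(ewe_row, np.nan)
    ratio = int(round(ewes / rams)) if rams and np.isfinite(rams) and rams > 0 else 0
    return FlockShares(shares_pct=shares, ewes_per_ram=ratio, total_mean=float(total))


def weighted_overall_mean(district_means, district_counts):
    """Respondent-weighted overall mean from per-district means."""
    means = np.asarray(list(district_means), dtype=float)
    counts = np.asarray(list(district_counts), dtype=float)
    return float((means * counts).sum() / counts.sum())
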