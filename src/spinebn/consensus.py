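"""Expert-panel consensus mathematics (RAND appropriateness style).

Panelists score candidate relationships on a 0-3 scale (0 = no
relationship, 3 = strong relationship). Consensus per item is summarized by
the median score and an interpercentile range (IPR, 30th-70th by default); a
relationship becomes an edge when the median is high and the IPR low. Rank
aggregation for the variable-selection round uses median ranks.

Percentiles default to the inverted-CDF (closest-rank) convention, which on
small integer panels returns observed scores; the method is configurable
(any numpy.percentile method name, e.g. "linear").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCORES = (0, 1, 2, 3)
DEFAULT_LOW_PCT = 30.0
DEFAULT_HIGH_PCT = 70.0
DEFAULT_MEDIAN_MIN = 2.0
DEFAULT_IPR_MAX = 1.0
DEFAULT_PCT_METHOD = "inverted_cdf"


class RatingError(ValueError):
    """Ratings are empty, out of range, or structurally inconsistent."""


@dataclass
class RatingMatrix:
    """Participants x items integer scores on the 0-3 scale (NaN = missing).

    ``scores`` is a DataFrame with items as the index and participants as
    columns, matching the wide CSV dialect used on disk.
    """

    scores: pd.DataFrame

    @property
    def items(self) -> list[str]:
        return list(self.scores.index)

    @property
    def participants(self) -> list[str]:
        return list(self.scores.columns)

    def item_scores(self, item: str) -> list[int]:
        row = self.scores.loc[item].dropna()
        return [int(v) for v in row]

    def validate(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        present = vals[~np.isnan(vals)]
        if not np.isin(present, VALID_SCORES).all():
            bad = sorted(set(present) - set(VALID_SCORES))
            raise RatingError(f"scores outside the 0-3 scale: {bad}")
        for item in self.items:
            if not self.item_scores(item):
                raise RatingError(f"item {item!r} has no scores")


@dataclass
class ConsensusResult:
    item: str
    median: float
    ipr: float
    decision: str  # "include" | "exclude"
    median_min: float
    ipr_max: float
    low_pct: float = DEFAULT_LOW_PCT
    high_pct: float = DEFAULT_HIGH_PCT


def rating_consensus(
    scores,
    low_pct: float = DEFAULT_LOW_PCT,
    high_pct: float = DEFAULT_HIGH_PCT,
    method: str = DEFAULT_PCT_METHOD,
) -> tuple[float, float]:
    """Median and interpercentile range of one item's panel scores."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise RatingError("cannot take consensus of an empty score list")
    if not np.isin(arr, VALID_SCORES).all():
        raise RatingError(f"scores outside the 0-3 scale: {sorted(set(arr))}")
    median = float(np.median(arr))
    low, high = np.percentile(arr, [low_pct, high_pct], method=method)
    return median, float(high - low)


def edge_decision(
    scores,
    median_min: float = DEFAULT_MEDIAN_MIN,
    ipr_max: float = DEFAULT_IPR_MAX,
    low_pct: float = DEFAULT_LOW_PCT,
    high_pct: float = DEFAULT_HIGH_PCT,
    method: str = DEFAULT_PCT_METHOD,
) -> str:
    """"include" iff median >= median_min and IPR <= ipr_max."""
    median, ipr = rating_consensus(scores, low_pct, high_pct, method)
    return "include" if (median >= median_min and ipr <= ipr_max) else "exclude"


def item_consensus(
    item: str,
    scores,
    median_min: float = DEFAULT_MEDIAN_MIN,
    ipr_max: float = DEFAULT_IPR_MAX,
    low_pct: float = DEFAULT_LOW_PCT,
    high_pct: float = DEFAULT_HIGH_PCT,
    method: str = DEFAULT_PCT_METHOD,
) -> ConsensusResult:
    median, ipr = rating_consensus(scores, low_pct, high_pct, method)
    decision = "include" if (median >= median_min and ipr <= ipr_max) else "exclude"
    return ConsensusResult(
        item=item,
        median=median,
        ipr=ipr,
        decision=decision,
        median_min=median_min,
        ipr_max=ipr_max,
        low_pct=low_pct,
        high_pct=high_pct,
    )


def matrix_consensus(matrix: RatingMatrix, **kwargs) -> list[ConsensusResult]:
    matrix.validate()
    return [item_consensus(item, matrix.item_scores(item), **kwargs) for item in matrix.items]


def grid_consensus(
    grid: dict[tuple[str, str], list[int]], **kwargs
) -> dict[tuple[str, str], ConsensusResult]:
    """Apply the edge decision cell-wise over a (row item, column item) grid.

    Returns statistics for every cell; the included edge set is the subset
    with decision == "include".
    """
    results = {}
    for cell, scores in grid.items():
        if not scores:
            raise RatingError(f"grid cell {cell!r} has no scores")
        results[cell] = item_consensus(f"{cell[0]}->{cell[1]}", scores, **kwargs)
    return results


def included_edges(
    grid: dict[tuple[str, str], list[int]], **kwargs
) -> list[tuple[str, str]]:
    results = grid_consensus(grid, **kwargs)
    return [cell for cell, r in results.items() if r.decision == "include"]


def aggregate_rankings(rankings: list[list[str]]) -> list[tuple[str, float]]:
    """Aggregate per-participant orderings by ascending median rank.

    Every ranking must permute the same item set; ranks are 1-based
    positions. Ties in median rank break lexicographically by item name.
    """
    if not rankings:
        raise RatingError("no rankings supplied")
    item_set = set(rankings[0])
    for r in rankings:
        if set(r) != item_set or len(r) != len(item_set):
            raise RatingError("rankings must all permute the same item set")
    medians = {
        item: float(np.median([r.index(item) + 1 for r in rankings]))
        for item in item_set
    }
    ordered = sorted(medians, key=lambda item: (medians[item], item))
    return [(item, medians[item]) for item in ordered]


def ipras(
    scores, median_min: float = DEFAULT_MEDIAN_MIN, method: str = DEFAULT_PCT_METHOD
) -> str:
    """Optional symmetry-adjusted disagreement rule (IPRAS), off by default.

    An item shows disagreement when its IPR exceeds the IPRAS threshold
    IPRAS = 2.35 + 1.5 * AI, where AI is the asymmetry index — the distance
    from the central point of the IPR to the scale midpoint. Include iff the
    median clears ``median_min`` and the panel does not disagree. Constants
    follow the classic appropriateness-method formulation rescaled to the
    0-3 scale (original 1-9 scale constants divided by 8/3).
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise RatingError("cannot take IPRAS of an empty score list")
    median = float(np.median(arr))
    low, high = np.percentile(arr, [DEFAULT_LOW_PCT, DEFAULT_HIGH_PCT], method=method)
    ipr = float(high - low)
    scale = 3.0 / 8.0  # 0-3 scale relative to the classic 1-9 scale's width
    ipr_central = (low + high) / 2.0
    ai = abs(ipr_central - 1.5)
    ipras_threshold = 2.35 * scale + 1.5 * ai
    disagreement = ipr > ipras_threshold
    return "include" if (median >= median_min and not disagreement) else "exclude"


__all__ = [
    "VALID_SCORES",
    "RatingError",
    "RatingMatrix",
    "ConsensusResult",
    "rating_consensus",
    "edge_decision",
    "item_consensus",
    "matrix_consensus",
    "grid_consensus",
    "included_edges",
    "aggregate_rankings",
    "ipras",
]
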