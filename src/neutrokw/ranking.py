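"""Pooled midranking of interval components with tie bookkeeping.

Both endpoints of every observation are ranked, but separately: the lower
(determinate) endpoints of all k groups are pooled and midranked together,
and independently the upper (indeterminate) endpoints.  Tied values get
the average of the rank positions they occupy.  This component-wise scheme
is what makes the interval statistic reduce to the classical test when all
intervals are degenerate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from neutrokw.interval_data import ComponentPair, GroupedNeutrosophicData

__all__ = ["RankTable", "midranks", "component_ranks", "rank_sums"]


@dataclass(frozen=True)
class RankTable:
    """Midranks per observation (aligned to data order) plus tie-group sizes."""

    ranks_lower: tuple[float, ...]
    ranks_upper: tuple[float, ...]
    tie_groups_lower: tuple[int, ...]  # sizes > 1, sorted
    tie_groups_upper: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.ranks_lower)

    def ranks(self, component: str) -> tuple[float, ...]:
        if component == "lower":
            return self.ranks_lower
        if component == "upper":
            return self.ranks_upper
        raise ValueError(f"component must be 'lower' or 'upper', got {component!r}")

    def to_dict(self) -> dict:
        return {
            "ranks_lower": list(self.ranks_lower),
            "ranks_upper": list(self.ranks_upper),
            "tie_groups_lower": list(self.tie_groups_lower),
            "tie_groups_upper": list(self.tie_groups_upper),
        }


def midranks(values: Sequence[float]) -> list[float]:
    """Ascending ranks with ties replaced by the mean of their positions.

    Comparison is exact on the stored floating-point numbers; no epsilon.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError("all values must be finite")
    return rankdata(arr, method="average").tolist()


def _tie_group_sizes(values: Sequence[float]) -> tuple[int, ...]:
    return tuple(sorted(c for c in Counter(values).values() if c > 1))


def component_ranks(data: GroupedNeutrosophicData) -> RankTable:
    """Midrank each component of the pooled data independently."""
    lower = data.component_values("lower")
    upper = data.component_values("upper")
    return RankTable(
        ranks_lower=tuple(midranks(lower)),
        ranks_upper=tuple(midranks(upper)),
        tie_groups_lower=_tie_group_sizes(lower),
        tie_groups_upper=_tie_group_sizes(upper),
    )


def rank_sums(
    table: RankTable, data: GroupedNeutrosophicData
) -> list[ComponentPair]:
    """Per-group rank-sum pairs R_iN = (sum of lower ranks, sum of upper ranks).

    Each component's sums total n(n+1)/2 across groups (rank conservation).
    """
    if table.n != data.n:
        raise ValueError(
            f"rank table has {table.n} entries but data has {data.n} observations"
        )
    sums: list[ComponentPair] = []
    start = 0
    for size in data.group_sizes:
        stop = start + size
        sums.append(
            ComponentPair(
                float(sum(table.ranks_lower[start:stop])),
                float(sum(table.ranks_upper[start:stop])),
            )
        )
        start = stop
    return sums
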