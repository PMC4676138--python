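"""Two-level dense-rank consensus for multi-criteria library ranking.

Each criterion assigns every library a dense rank: the best value gets 1,
ties share a rank, and the next distinct value gets the previous rank + 1.
A block of criteria is combined by summing the (optionally weighted) ranks
per library and dense-ranking the sums; blocks are combined the same way
into grand totals and final ranks.  Because only the ordering of values
matters, any strictly monotone transform of a criterion leaves every
downstream rank unchanged.

Directions follow the workflow's conventions: filter-failure percentages,
promiscuity percentages, mean internal similarity and overlap percentages
are lower-better; similar-to-active counts are higher-better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .chemio import LibrankError

LOWER_BETTER = "lower_better"
HIGHER_BETTER = "higher_better"


@dataclass
class CriterionTable:
    """Per-library values for one criterion plus its better-direction."""

    name: str
    values: dict[str, float]
    direction: str = LOWER_BETTER

    def __post_init__(self) -> None:
        if self.direction not in (LOWER_BETTER, HIGHER_BETTER):
            raise LibrankError(f"bad direction: {self.direction!r}")
        for lib, v in self.values.items():
            if not math.isfinite(v):
                raise LibrankError(f"criterion {self.name}: non-finite value for {lib!r}")


def dense_rank(values: Mapping[str, float], direction: str = LOWER_BETTER) -> dict[str, int]:
    """Dense ranks: best -> 1, ties share, next distinct value -> rank + 1."""
    for lib, v in values.items():
        if not math.isfinite(v):
            raise LibrankError(f"non-finite value for {lib!r}")
    reverse = direction == HIGHER_BETTER
    distinct = sorted(set(values.values()), reverse=reverse)
    rank_of = {v: r for r, v in enumerate(distinct, start=1)}
    return {lib: rank_of[v] for lib, v in values.items()}


@dataclass
class ConsensusResult:
    """Per-criterion dense ranks, rank sums and block ranks for one block."""

    criterion_ranks: dict[str, dict[str, int]] = field(default_factory=dict)
    rank_sums: dict[str, float] = field(default_factory=dict)
    block_ranks: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        libs = list(self.rank_sums)
        data = {crit: [ranks[l] for l in libs] for crit, ranks in self.criterion_ranks.items()}
        data["rank_sum"] = [self.rank_sums[l] for l in libs]
        data["block_rank"] = [self.block_ranks[l] for l in libs]
        return pd.DataFrame(data, index=pd.Index(libs, name="library"))


def _check_same_libraries(sets: Sequence[set], what: str) -> None:
    base = sets[0]
    for s in sets[1:]:
        if s != base:
            missing = sorted(base ^ s)
            raise LibrankError(f"{what} cover different library sets; differ on {missing}")


def block_consensus(
    tables: Sequence[CriterionTable], weights: Mapping[str, float] | None = None
) -> ConsensusResult:
    """Dense-rank each criterion, sum ranks per library, dense-rank the sums.

    ``weights`` (criterion name -> weight, default 1.0 each) scales each
    criterion's rank before summing.
    """
    if not tables:
        raise LibrankError("block_consensus needs at least one criterion table")
    _check_same_libraries([set(t.values) for t in tables], "criterion tables")
    weights = dict(weights or {})
    result = ConsensusResult()
    libs = list(tables[0].values)
    sums = {lib: 0.0 for lib in libs}
    for t in tables:
        ranks = dense_rank(t.values, t.direction)
        result.criterion_ranks[t.name] = ranks
        w = weights.get(t.name, 1.0)
        for lib in libs:
            sums[lib] += w * ranks[lib]
    result.rank_sums = sums
    result.block_ranks = dense_rank(sums, LOWER_BETTER)
    return result


def total_consensus(
    block_ranks: Sequence[Mapping[str, int]],
) -> tuple[dict[str, int], dict[str, int]]:
    """Sum block ranks into grand totals; final ranks = dense rank of totals."""
    if not block_ranks:
        raise LibrankError("total_consensus needs at least one block")
    _check_same_libraries([set(b) for b in block_ranks], "blocks")
    libs = list(block_ranks[0])
    totals = {lib: sum(int(b[lib]) for b in block_ranks) for lib in libs}
    return totals, dense_rank(totals, LOWER_BETTER)


def overlap_adjusted_rank(
    prior_final_ranks: Mapping[str, int], overlap_table: CriterionTable
) -> tuple[dict[str, int], dict[str, int]]:
    """Fold a cross-library overlap criterion into an existing final ranking.

    combined = prior final rank + dense rank of overlap (lower overlap is
    better); final = dense rank of the combined scores.
    """
    if set(prior_final_ranks) != set(overlap_table.values):
        missing = sorted(set(prior_final_ranks) ^ set(overlap_table.values))
        raise LibrankError(f"overlap table and prior ranks differ on {missing}")
    overlap_ranks = dense_rank(overlap_table.values, overlap_table.direction)
    combined = {lib: int(prior_final_ranks[lib]) + overlap_ranks[lib] for lib in prior_final_ranks}
    return combined, dense_rank(combined, LOWER_BETTER)
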