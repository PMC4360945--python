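"""Consensus scoring: per-criterion ranks, top-fraction votes, shortlist.

Each compound receives one binary vote per criterion on which it ranks
in the top fraction f (default 10%); the cumulative vote (0..K) drives
the shortlist.  Ties use competition ("min") ranking, so rank 1 always
means "no strictly better compound"; boundary ties at the membership
edge are all included.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .score_io import (
    HIGHER_BETTER,
    CriterionSpec,
    HitEntry,
    HitList,
    ScoreTable,
)

__all__ = [
    "DEFAULT_TOP_FRACTION",
    "VoteTable",
    "rank_by_criterion",
    "top_fraction_members",
    "cumulative_votes",
    "build_vote_table",
    "select_top_voted",
    "vote",
]

logger = logging.getLogger(__name__)

DEFAULT_TOP_FRACTION = 0.10


def rank_by_criterion(table: ScoreTable, criterion: str) -> pd.Series:
    """Competition ranks (1 = most favourable) for one criterion.

    Compounds with missing values receive no rank (dropped from the
    returned series).
    """
    spec = table.criterion(criterion)  # KeyError on unknown criterion
    col = table.column(criterion).dropna()
    if col.empty:
        raise ValueError(f"criterion {criterion!r} has no present values")
    vals = col.to_numpy(dtype=float)
    if spec.direction == HIGHER_BETTER:
        vals = -vals
    ranks = rankdata(vals, method="min").astype(int)
    return pd.Series(ranks, index=col.index, name=criterion)


def top_fraction_members(ranks: pd.Series, f: float) -> pd.Series:
    """Boolean membership in the top fraction ``f``.

    Membership size is max(1, floor(f*N)) for distinct scores;
    compounds tied across the boundary are all included (competition
    ranks make this a simple ``rank <= m`` test).
    """
    if not 0.0 < f <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {f}")
    n = len(ranks)
    if n < 1:
        raise ValueError("ranks must be non-empty")
    m = max(1, math.floor(f * n))
    return (ranks <= m).rename(ranks.name)


def cumulative_votes(memberships: pd.DataFrame) -> pd.Series:
    """Per-compound vote = number of criteria with top-fraction membership."""
    return memberships.astype(bool).sum(axis=1).astype(int)


@dataclass(frozen=True)
class VoteTable:
    """Ranks, memberships and cumulative votes over one criterion set.

    Compounds missing any criterion value are excluded from voting
    entirely (``excluded``) rather than scored as non-members.
    """

    criteria: tuple[CriterionSpec, ...]
    f: float
    ranks: pd.DataFrame        # int ranks, voted compounds only
    memberships: pd.DataFrame  # bool flags, voted compounds only
    votes: pd.Series           # int votes, voted compounds only
    n_ranked: pd.Series        # per criterion: how many compounds held a value
    excluded: tuple[str, ...]


def build_vote_table(
    table: ScoreTable,
    criteria: tuple[str, ...] | None = None,
    f: float = DEFAULT_TOP_FRACTION,
) -> VoteTable:
    names = criteria if criteria is not None else tuple(c.name for c in table.criteria)
    specs = tuple(table.criterion(n) for n in names)

    rank_cols = {n: rank_by_criterion(table, n) for n in names}
    member_cols = {n: top_fraction_members(rank_cols[n], f) for n in names}

    voted = table.values.index
    for n in names:
        voted = voted.intersection(rank_cols[n].index, sort=False)
    voted_set = set(voted)
    excluded = tuple(c for c in table.compounds if c not in voted_set)
    if excluded:
        logger.warning(
            "%d compound(s) excluded from voting for missing criterion values: %s%s",
            len(excluded), ", ".join(excluded[:5]), "..." if len(excluded) > 5 else "",
        )

    ranks = pd.DataFrame({n: rank_cols[n].reindex(voted) for n in names}).astype(int)
    memberships = pd.DataFrame({n: member_cols[n].reindex(voted) for n in names})
    return VoteTable(
        criteria=specs,
        f=f,
        ranks=ranks,
        memberships=memberships,
        votes=cumulative_votes(memberships),
        n_ranked=pd.Series({n: len(rank_cols[n]) for n in names}),
        excluded=excluded,
    )


def _tie_break_keys(vt: VoteTable) -> pd.Series:
    """Mean normalized rank (rank / N_ranked, averaged over criteria)."""
    norm = vt.ranks / vt.n_ranked
    return norm.mean(axis=1)


def select_top_voted(vt: VoteTable, m: int) -> HitList:
    """Shortlist of the ``m`` best compounds.

    Ordering: cumulative vote descending, then ascending mean
    normalized rank, then compound id lexicographic.
    """
    if m < 1:
        raise ValueError("shortlist size must be >= 1")
    keys = _tie_break_keys(vt)
    frame = pd.DataFrame({"vote": vt.votes, "key": keys, "cid": vt.votes.index})
    frame = frame.sort_values(["vote", "key", "cid"],
                              ascending=[False, True, True]).head(m)
    names = tuple(c.name for c in vt.criteria)
    rank_rows = vt.ranks.loc[frame.index].to_numpy()
    entries = tuple(
        HitEntry(
            compound_id=cid,
            vote=int(v),
            ranks=tuple(int(r) for r in row),
            tie_break_key=float(k),
        )
        for cid, v, k, row in zip(frame["cid"], frame["vote"], frame["key"], rank_rows)
    )
    return HitList(names, entries)


def vote(
    table: ScoreTable,
    criteria: tuple[str, ...] | None = None,
    f: float = DEFAULT_TOP_FRACTION,
    shortlist: int = 5000,
) -> tuple[HitList, VoteTable]:
    """Rank, vote and shortlist in one call."""
    vt = build_vote_table(table, criteria=criteria, f=f)
    if len(vt.votes) == 0:
        return HitList(tuple(c.name for c in vt.criteria), ()), vt
    return select_top_voted(vt, shortlist), vt


def brute_force_votes(
    table: ScoreTable,
    criteria: tuple[str, ...] | None = None,
    f: float = DEFAULT_TOP_FRACTION,
) -> dict[str, int]:
    """Per-compound re-sorting oracle for the vectorised vote (tests only).

    For every compound and criterion, recounts strictly-better compounds
    to rebuild its competition rank, then applies the membership rule.
    """
    names = criteria if criteria is not None else tuple(c.name for c in table.criteria)
    out: dict[str, int] = {}
    cols = {}
    for n in names:
        spec = table.criterion(n)
        s = table.column(n).dropna()
        cols[n] = (-s if spec.direction == HIGHER_BETTER else s)
    for cid in table.compounds:
        if any(cid not in cols[n].index for n in names):
            continue
        v = 0
        for n in names:
            s = cols[n]
            rank = int((s < s[cid]).sum()) + 1
            m = max(1, math.floor(f * len(s)))
            v += rank <= m
        out[cid] = v
    return out
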