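"""Elo dominance hierarchy from pairwise race outcomes.

The weekly "race to the top" produces a winner per pair; ratings follow the
standard Elo logistic update with expected score
``E_a = 1 / (1 + 10^((r_b - r_a)/400))`` and zero-sum transfer ``K (1 - E)``
from loser to winner.  Defaults: K = 32, initial rating 1000, no draws.

Also provided: cross-group win-percentage consistency for pairs tested in
several group compositions, and triad transitivity via triad-local Elo
recomputation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .session_io import RaceOutcome
from .stats import StatResult, pearson, spearman

DEFAULT_K = 32.0
INITIAL_RATING = 1000.0
ELO_TIE_EPS = 1e-9
#: hierarchy-class boundaries on rating differences used downstream
DELTA_ELO_CLASS_EDGE = 50.0


@dataclass
class EloState:
    """Ratings after sequential updates, with an end-of-week history."""

    ratings: dict[str, float]
    k: float
    history: pd.DataFrame  # columns: week, bat, rating

    def rank_order(self) -> list[str]:
        """Labels sorted from highest to lowest rating (ties by label)."""
        return sorted(self.ratings, key=lambda b: (-self.ratings[b], b))

    def rank_class(self, label: str) -> str:
        order = self.rank_order()
        if label == order[0]:
            return "top"
        if label == order[-1]:
            return "bottom"
        if label not in self.ratings:
            raise DataError(f"unknown bat {label!r}")
        return "intermediate"


def elo_update(
    rating_a: float, rating_b: float, winner_a: bool, k: float = DEFAULT_K
) -> tuple[float, float]:
    """One zero-sum Elo update; returns the new (rating_a, rating_b)."""
    e_a = 1.0 / (1.0 + 10.0 ** ((rating_b - rating_a) / 400.0))
    delta = k * ((1.0 - e_a) if winner_a else -e_a)
    return rating_a + delta, rating_b - delta


def elo_ratings(
    races: list[RaceOutcome],
    k: float = DEFAULT_K,
    *,
    bats: list[str] | None = None,
    initial: float = INITIAL_RATING,
) -> EloState:
    """Sequential Elo over a race log.

    Outcomes are processed in (week, bat_a, bat_b) order — a deterministic
    stand-in for the unrecorded within-week test order.  ``history`` samples
    every bat's rating at the end of each week.
    """
    if bats is not None:
        ratings = {b: initial for b in bats}
        for r in races:
            for lab in (r.bat_a, r.bat_b):
                if lab not in ratings:
                    raise DataError(f"race references unknown bat {lab!r}")
    else:
        ratings = {
            lab: initial for r in races for lab in (r.bat_a, r.bat_b)
        }
    ordered = sorted(races, key=lambda r: (r.week, r.bat_a, r.bat_b))
    rows = []
    for week, week_races in itertools.groupby(ordered, key=lambda r: r.week):
        for r in week_races:
            ra, rb = elo_update(
                ratings[r.bat_a], ratings[r.bat_b], r.winner == r.bat_a, k
            )
            ratings[r.bat_a], ratings[r.bat_b] = ra, rb
        rows.extend((week, lab, ratings[lab]) for lab in sorted(ratings))
    history = pd.DataFrame(rows, columns=["week", "bat", "rating"])
    return EloState(ratings, k, history)


# ---------------------------------------------------------------------------
# Cross-group consistency
# ---------------------------------------------------------------------------


def cross_group_consistency(
    race_logs: dict[str, list[RaceOutcome]]
) -> tuple[pd.DataFrame, StatResult | None, StatResult | None]:
    """Win-percentage consistency for pairs tested in several groups.

    For each pair of bats and each group where the pair raced, the win
    percentage of the lexicographically first bat is computed.  Every
    ordered pair of groups (i < j) sharing a bat-pair contributes one row;
    Pearson and Spearman correlations are computed over the two win-percent
    columns (None when fewer than 3 rows).
    """
    pair_pct: dict[tuple[str, str], dict[str, float]] = {}
    for gid, races in race_logs.items():
        wins: dict[tuple[str, str], list[int]] = {}
        for r in races:
            pair = tuple(sorted((r.bat_a, r.bat_b)))
            wins.setdefault(pair, []).append(1 if r.winner == pair[0] else 0)
        for pair, w in wins.items():
            pair_pct.setdefault(pair, {})[gid] = 100.0 * np.mean(w)
    rows = []
    for pair, by_group in sorted(pair_pct.items()):
        gids = sorted(by_group)
        for gi, gj in itertools.combinations(gids, 2):
            rows.append(
                (pair[0], pair[1], gi, gj, by_group[gi], by_group[gj])
            )
    table = pd.DataFrame(
        rows,
        columns=["bat_a", "bat_b", "group_i", "group_j", "win_pct_i", "win_pct_j"],
    )
    if len(table) < 3:
        return table, None, None
    try:
        r = pearson(table["win_pct_i"], table["win_pct_j"])
        rho = spearman(table["win_pct_i"], table["win_pct_j"])
    except ValidationError:  # zero-variance win percentages
        return table, None, None
    return table, r, rho


# ---------------------------------------------------------------------------
# Triad transitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriadVerdict:
    """Transitivity verdict for one directly comparable triad."""

    triad: tuple[str, str, str]
    transitive: bool
    ratings: dict[str, float] = field(hash=False, default_factory=dict)
    reason: str = ""


def triad_transitivity(
    races: list[RaceOutcome], k: float = DEFAULT_K
) -> tuple[list[TriadVerdict], float]:
    """Transitivity of all directly comparable triads.

    A triad qualifies when every one of its three pairs has at least one
    contest.  Elo ratings are recomputed from that triad's contests only.
    The triad is transitive when the triad-local Elo order agrees with the
    majority-win relation on all three pairs; pairs with equal head-to-head
    wins defer to the triad-local Elo order, and a near-tie in Elo
    (|difference| < 1e-9) renders the triad nontransitive — mirroring how
    nontransitivity arises between closely matched individuals.

    Returns the verdicts and the transitive fraction (NaN if no triads).
    """
    head_to_head: dict[tuple[str, str], dict[str, int]] = {}
    by_pair: dict[tuple[str, str], list[RaceOutcome]] = {}
    for r in races:
        pair = tuple(sorted((r.bat_a, r.bat_b)))
        by_pair.setdefault(pair, []).append(r)
        head_to_head.setdefault(pair, {})[r.winner] = (
            head_to_head.setdefault(pair, {}).get(r.winner, 0) + 1
        )
    bats = sorted({lab for pair in by_pair for lab in pair})
    verdicts = []
    for triad in itertools.combinations(bats, 3):
        pairs = [tuple(sorted(p)) for p in itertools.combinations(triad, 2)]
        if not all(p in by_pair for p in pairs):
            continue
        triad_races = [r for p in pairs for r in by_pair[p]]
        state = elo_ratings(triad_races, k=k, bats=list(triad))
        ratings = state.ratings
        transitive = True
        reason = ""
        for a, b in pairs:
            wins = head_to_head[(a, b)]
            wa, wb = wins.get(a, 0), wins.get(b, 0)
            d_elo = ratings[a] - ratings[b]
            if abs(d_elo) < ELO_TIE_EPS:
                transitive = False
                reason = f"closely matched Elo for pair ({a}, {b})"
                break
            if wa != wb:
                major = a if wa > wb else b
                elo_winner = a if d_elo > 0 else b
                if major != elo_winner:
                    transitive = False
                    reason = f"Elo order contradicts majority wins for ({a}, {b})"
                    break
        verdicts.append(TriadVerdict(triad, transitive, dict(ratings), reason))
    frac = (
        float(np.mean([v.transitive for v in verdicts])) if verdicts else float("nan")
    )
    return verdicts, frac
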