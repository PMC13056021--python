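"""Per-session social networks, their stability over days, and annotator
agreement.

Two network families are supported, following how bat social structure is
measured on the landing nets:

* affiliation networks — complete graphs over co-present bats, edge weight =
  median pairwise distance (metres) across frames where both bats sit on the
  same net (smaller = more affiliated);
* interaction-rate networks — star graphs around the focal (recorded) bat,
  edge weight = events/hour of the selected interaction type(s).

Network structure is summarized by weighted closeness centrality and its
day-to-day stability by the Pearson correlation of each day's centrality
vector with the element-wise median vector across days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConfigError, DataError, ValidationError
from .session_io import InteractionEvent, TrajectorySet
from .stats import pearson

MODE_AFFILIATION = "affiliation"
MODE_ALL = "interactions_all"
MODE_AFFILIATIVE = "interactions_affiliative"
MODE_AGGRESSIVE = "interactions_aggressive"
_INTERACTION_MODES = {
    MODE_ALL: ("affiliative", "aggressive", "joining", "leaving"),
    MODE_AFFILIATIVE: ("affiliative",),
    MODE_AGGRESSIVE: ("aggressive",),
}


@dataclass
class SessionNetwork:
    """Weighted graph over bats for one session.

    ``weights`` maps sorted label pairs to the edge weight: median distance
    (m) in affiliation mode, events/hour in interaction modes.
    """

    session_id: str
    mode: str
    nodes: list[str]
    weights: dict[tuple[str, str], float]
    focal: str | None = None

    def weight(self, a: str, b: str) -> float | None:
        return self.weights.get(tuple(sorted((a, b))))

    def to_graph(self) -> nx.Graph:
        """Graph with a ``length`` attribute usable as shortest-path cost.

        Affiliation distances are lengths directly; interaction rates are
        converted to length 1/rate, zero-rate edges are absent.
        """
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.weights.items():
            if self.mode == MODE_AFFILIATION:
                g.add_edge(a, b, weight=w, length=w)
            elif w > 0:
                g.add_edge(a, b, weight=w, length=1.0 / w)
        return g


@dataclass
class StabilityCurve:
    """Mean day-to-median centrality correlation across groups."""

    days: np.ndarray
    mean_r: np.ndarray
    per_group: dict[str, dict[int, float]] = field(default_factory=dict)


def affiliation_network(traj: TrajectorySet) -> SessionNetwork:
    """Median pairwise on-net distance for every co-present pair."""
    geom = traj.geometry
    net_names = (geom.large_net.name, geom.small_net.name)
    labels = traj.labels
    weights: dict[tuple[str, str], float] = {}
    nodes = set()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            za, zb = traj.zone[a], traj.zone[b]
            co = (za == zb) & np.isin(za, net_names)
            if not co.any():
                continue
            d = np.linalg.norm(
                traj.positions[a][co] - traj.positions[b][co], axis=1
            )
            weights[(a, b)] = float(np.median(d))
            nodes.update((a, b))
    if not weights:
        raise DataError("no pair of bats was ever co-present on a net")
    return SessionNetwork(traj.session_id, MODE_AFFILIATION, sorted(nodes), weights)


def interaction_network(
    events: list[InteractionEvent],
    focal: str,
    mode: str,
    session_duration: float,
    *,
    bats: list[str] | None = None,
    session_id: str = "",
) -> SessionNetwork:
    """Star graph of interaction rates (events/hour) around the focal bat."""
    if mode not in _INTERACTION_MODES:
        raise ConfigError(f"unknown interaction network mode {mode!r}")
    if session_duration <= 0:
        raise ConfigError("session_duration must be positive")
    types = _INTERACTION_MODES[mode]
    hours = session_duration / 3600.0
    counts: dict[str, int] = {}
    partners = set(bats) - {focal} if bats else set()
    for e in events:
        if e.itype not in types:
            continue
        if focal == e.actor:
            other = e.receiver
        elif focal == e.receiver:
            other = e.actor
        else:
            continue
        counts[other] = counts.get(other, 0) + 1
        partners.add(other)
    weights = {
        tuple(sorted((focal, p))): counts.get(p, 0) / hours for p in sorted(partners)
    }
    nodes = sorted(partners | {focal})
    return SessionNetwork(session_id, mode, nodes, weights, focal=focal)


def closeness_centrality(network: SessionNetwork) -> dict[str, float]:
    """Weighted closeness, c(v) = (n_reachable - 1) / sum of path lengths.

    On a disconnected graph, values are computed (and normalized) within
    each component, with a warning.
    """
    g = network.to_graph()
    if g.number_of_nodes() < 2:
        raise DataError("closeness needs at least 2 nodes")
    if not nx.is_connected(g):
        warnings.warn(
            "network is disconnected; closeness computed per component",
            stacklevel=2,
        )
    return nx.closeness_centrality(g, distance="length", wf_improved=False)


def stability_curve(
    groups: dict[str, list[tuple[int, SessionNetwork]]]
) -> StabilityCurve:
    """Per-group day-to-median centrality correlation, averaged over groups.

    ``groups`` maps group id to (day_index, network) pairs.  Within a group
    the comparison is restricted to bats common to all days; groups with
    fewer than 3 common bats or fewer than 3 days are skipped.  Days whose
    centrality vector has zero variance yield a missing value.
    """
    per_group: dict[str, dict[int, float]] = {}
    for gid, day_nets in groups.items():
        if len(day_nets) < 3:
            continue
        cents = {day: closeness_centrality(net) for day, net in day_nets}
        common = set.intersection(*(set(c) for c in cents.values()))
        if len(common) < 3:
            continue
        order = sorted(common)
        vectors = {day: np.array([c[b] for b in order]) for day, c in cents.items()}
        median_vec = np.median(np.stack(list(vectors.values())), axis=0)
        rs: dict[int, float] = {}
        for day, vec in vectors.items():
            if np.std(vec) == 0 or np.std(median_vec) == 0:
                rs[day] = np.nan
                continue
            rs[day] = pearson(vec, median_vec).statistic
        per_group[gid] = rs
    if not per_group:
        raise DataError("no group satisfied the stability-curve preconditions")
    all_days = sorted({d for rs in per_group.values() for d in rs})
    mean_r = np.array(
        [
            np.nanmean([rs[d] for rs in per_group.values() if d in rs])
            for d in all_days
        ]
    )
    return StabilityCurve(np.array(all_days), mean_r, per_group)


@dataclass(frozen=True)
class AgreementReport:
    """Annotator-agreement summary from greedy onset matching."""

    n_a: int
    n_b: int
    n_matched: int
    agreement_rate: float
    mean_onset_diff: float

    def __post_init__(self):
        if not (0.0 <= self.agreement_rate <= 1.0):
            raise ValidationError("agreement rate outside [0, 1]")


def match_annotations(
    log_a: list[InteractionEvent],
    log_b: list[InteractionEvent],
    time_tol: float = 1.0,
) -> AgreementReport:
    """Match two annotators' event logs of the same session.

    Events match when the interaction type is identical and onsets differ by
    at most ``time_tol`` seconds; candidate pairs are taken greedily in order
    of |onset difference|, each event used once.  The agreement rate uses the
    symmetric (Dice-style) denominator ``2 m / (|a| + |b|)``.
    """
    candidates = []
    for i, ea in enumerate(log_a):
        for j, eb in enumerate(log_b):
            if ea.itype == eb.itype and abs(ea.time - eb.time) <= time_tol:
                candidates.append((abs(ea.time - eb.time), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    diffs = []
    for d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        diffs.append(d)
    m = len(diffs)
    total = len(log_a) + len(log_b)
    rate = 2.0 * m / total if total else 1.0
    return AgreementReport(
        len(log_a), len(log_b), m, rate, float(np.mean(diffs)) if diffs else 0.0
    )
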