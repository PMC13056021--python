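"""Hierarchy-linked natural behaviors: food-bowl monopolization and
sleep-cluster geometry.

Food monopolization is measured as each bat's share of total bowl-occupancy
time and of total visit counts per session, correlated against Elo ratings.

Sleep analysis finds, per frame of a light-phase session, the largest
single-linkage cluster of bats, computes its convex hull, and classifies
cluster members as periphery (hull vertices) or middle (strictly interior).
A per-night middle-fraction per bat is then compared across hierarchy
classes (top / intermediate / bottom ranked).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError

from .dominance import EloState
from .errors import DataError, InsufficientSampleError
from .geometry import ZONE_BOWL
from .session_io import TrajectorySet
from .stats import StatResult, pearson, spearman, wilcoxon

DEFAULT_LINK_THRESHOLD = 0.15  # m, about one bat body length
DEFAULT_MIN_GAP = 5.0  # s, bowl visits closer than this merge into one


# ---------------------------------------------------------------------------
# Food occupancy
# ---------------------------------------------------------------------------


@dataclass
class FoodOccupancy:
    """Per-bat bowl occupancy for one session.

    ``table`` columns: bat, time_on_bowl (s), n_visits, normalized_time,
    normalized_visits.  Normalized values are each bat's share of the
    session total and sum to 1 when any occupancy exists (NaN otherwise).
    """

    session_id: str
    table: pd.DataFrame


def _merge_runs(mask: np.ndarray, times: np.ndarray, min_gap: float):
    """Maximal runs of ``mask``; runs separated by < min_gap s are merged."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = []
    start = idx[0]
    for b in breaks:
        runs.append((start, idx[b]))
        start = idx[b + 1]
    runs.append((start, idx[-1]))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if times[s] - times[merged[-1][1]] < min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def food_occupancy(
    traj: TrajectorySet, *, min_gap: float = DEFAULT_MIN_GAP
) -> FoodOccupancy:
    """Bowl time, visit counts and their normalized shares per bat.

    Time on bowl counts frames whose zone label is the bowl region times the
    frame interval; a visit is a maximal occupancy run, with runs separated
    by less than ``min_gap`` seconds merged into one visit.
    """
    dt = traj.frame_interval
    rows = []
    for lab in traj.labels:
        mask = traj.zone[lab] == ZONE_BOWL
        runs = _merge_runs(mask, traj.frame_times, min_gap)
        rows.append((lab, float(mask.sum() * dt), len(runs)))
    df = pd.DataFrame(rows, columns=["bat", "time_on_bowl", "n_visits"])
    tot_t = df["time_on_bowl"].sum()
    tot_v = df["n_visits"].sum()
    df["normalized_time"] = df["time_on_bowl"] / tot_t if tot_t > 0 else np.nan
    df["normalized_visits"] = df["n_visits"] / tot_v if tot_v > 0 else np.nan
    return FoodOccupancy(traj.session_id, df)


def hierarchy_food_correlation(
    occupancies: list[FoodOccupancy], elo: EloState
) -> dict[str, StatResult]:
    """Correlate Elo rating with normalized bowl time and visits.

    Rows are (session x bat); sessions with zero total occupancy contribute
    missing values and are dropped.  Returns Pearson and Spearman results
    for both monopolization indices.
    """
    frames = []
    for occ in occupancies:
        t = occ.table.copy()
        t["rating"] = t["bat"].map(elo.ratings)
        frames.append(t)
    data = pd.concat(frames, ignore_index=True).dropna(
        subset=["rating", "normalized_time", "normalized_visits"]
    )
    if len(data) < 3:
        raise InsufficientSampleError("need >= 3 (session x bat) rows")
    return {
        "time_pearson": pearson(data["rating"], data["normalized_time"]),
        "time_spearman": spearman(data["rating"], data["normalized_time"]),
        "visits_pearson": pearson(data["rating"], data["normalized_visits"]),
        "visits_spearman": spearman(data["rating"], data["normalized_visits"]),
    }


# ---------------------------------------------------------------------------
# Sleep clusters
# ---------------------------------------------------------------------------


@dataclass
class FrameClusters:
    """Single-linkage clusters of one frame; ``largest`` indexes clusters."""

    clusters: list[list[str]]
    largest: int

    @property
    def largest_members(self) -> list[str]:
        return self.clusters[self.largest]


def sleep_clusters(
    traj: TrajectorySet, link_threshold: float = DEFAULT_LINK_THRESHOLD
) -> list[FrameClusters]:
    """Per-frame single-linkage clustering of 2D bat positions.

    Bats closer than ``link_threshold`` (chained transitively) share a
    cluster.  The largest cluster is selected per frame; size ties go to the
    cluster with the smallest total positional variance (the tightest
    huddle).
    """
    out = []
    for t in range(traj.n_frames):
        present = [lab for lab in traj.labels if traj.presence(lab)[t]]
        pts = np.array([traj.positions[lab][t, :2] for lab in present])
        if len(present) == 0:
            out.append(FrameClusters([[]], 0))
            continue
        if len(present) == 1:
            out.append(FrameClusters([present], 0))
            continue
        z = linkage(pts, method="single")
        assign = fcluster(z, t=link_threshold, criterion="distance")
        clusters = []
        for cid in np.unique(assign):
            members = [present[i] for i in np.flatnonzero(assign == cid)]
            clusters.append(members)
        sizes = np.array([len(c) for c in clusters])
        best = np.flatnonzero(sizes == sizes.max())
        if len(best) > 1:
            variances = []
            for b in best:
                cpts = pts[[present.index(m) for m in clusters[b]]]
                variances.append(np.var(cpts, axis=0).sum())
            largest = int(best[int(np.argmin(variances))])
        else:
            largest = int(best[0])
        out.append(FrameClusters(clusters, largest))
    return out


@dataclass
class SleepReport:
    """Middle/periphery classification for one night.

    ``middle_fraction[bat]`` = fraction of frames, among frames where the
    bat belonged to the largest cluster, spent strictly interior to that
    cluster's convex hull.  ``rank_class`` is filled when an Elo state is
    supplied.
    """

    night_id: str
    middle_fraction: dict[str, float]
    frames_in_cluster: dict[str, int]
    rank_class: dict[str, str] = field(default_factory=dict)
    median_positions: dict[str, np.ndarray] = field(default_factory=dict)


def _hull_interior(points: np.ndarray) -> np.ndarray:
    """Boolean mask of points strictly interior to the convex hull.

    Collinear (degenerate) point sets have no interior: all False.
    """
    n = len(points)
    interior = np.zeros(n, dtype=bool)
    if n < 4:
        return interior
    try:
        hull = ConvexHull(points)
    except QhullError:
        return interior
    interior[:] = True
    interior[hull.vertices] = False
    return interior


def middle_periphery(
    traj: TrajectorySet,
    *,
    link_threshold: float = DEFAULT_LINK_THRESHOLD,
    elo: EloState | None = None,
    median_positions: bool = False,
) -> SleepReport:
    """Classify bats as sleep-cluster middle or periphery.

    Frame-wise mode (default): per frame, members of the largest cluster
    that are vertices of its convex hull are periphery, strictly interior
    members are middle; fractions are time-averaged per bat.  With
    ``median_positions=True`` the classification is done once per night on
    each bat's median position (middle_fraction is then 0 or 1).
    """
    labels = traj.labels
    med = {
        lab: np.nanmedian(traj.positions[lab][:, :2], axis=0) for lab in labels
    }
    if median_positions:
        present = [lab for lab in labels if not np.isnan(med[lab][0])]
        pts = np.array([med[lab] for lab in present])
        z = linkage(pts, method="single") if len(present) > 1 else None
        if z is not None:
            from scipy.cluster.hierarchy import fcluster as _fc

            assign = _fc(z, t=link_threshold, criterion="distance")
            counts = np.bincount(assign)
            largest_id = counts.argmax()
            members = [p for p, a in zip(present, assign) if a == largest_id]
        else:
            members = present
        interior = _hull_interior(np.array([med[m] for m in members]))
        mf = {lab: np.nan for lab in labels}
        fic = {lab: 0 for lab in labels}
        for m, is_mid in zip(members, interior):
            mf[m] = 1.0 if is_mid else 0.0
            fic[m] = 1
    else:
        per_frame = sleep_clusters(traj, link_threshold)
        in_cluster = {lab: 0 for lab in labels}
        in_middle = {lab: 0 for lab in labels}
        for t, fc_t in enumerate(per_frame):
            members = fc_t.largest_members
            if len(members) < 3:
                for m in members:
                    in_cluster[m] += 1
                continue
            pts = np.array([traj.positions[m][t, :2] for m in members])
            interior = _hull_interior(pts)
            for m, is_mid in zip(members, interior):
                in_cluster[m] += 1
                if is_mid:
                    in_middle[m] += 1
        mf = {
            lab: (in_middle[lab] / in_cluster[lab]) if in_cluster[lab] else np.nan
            for lab in labels
        }
        fic = in_cluster
    rank_class = {}
    if elo is not None:
        rank_class = {lab: elo.rank_class(lab) for lab in labels if lab in elo.ratings}
    return SleepReport(traj.session_id, mf, fic, rank_class, med)


def sleep_rank_test(
    reports: list[SleepReport], elo: EloState | None = None
) -> dict[str, object]:
    """Compare middle-fractions across hierarchy classes over nights.

    Wilcoxon rank-sum tests of top-vs-intermediate, bottom-vs-intermediate
    and top-vs-bottom on the per-(night, bat) middle fractions, each with a
    Bonferroni factor of 2 (two comparisons per class), p capped at 1.
    Also reports mean +/- SEM per class.
    """
    if len(reports) < 2:
        raise InsufficientSampleError("need >= 2 nights")
    samples: dict[str, list[float]] = {"top": [], "intermediate": [], "bottom": []}
    for rep in reports:
        classes = rep.rank_class or (
            {lab: elo.rank_class(lab) for lab in rep.middle_fraction} if elo else None
        )
        if not classes:
            raise DataError("reports lack rank classes and no EloState given")
        for lab, frac in rep.middle_fraction.items():
            if np.isnan(frac) or lab not in classes:
                continue
            samples[classes[lab]].append(frac)
    results: dict[str, object] = {"samples": samples}
    for name, (a, b) in {
        "top_vs_intermediate": ("top", "intermediate"),
        "bottom_vs_intermediate": ("bottom", "intermediate"),
        "top_vs_bottom": ("top", "bottom"),
    }.items():
        if not samples[a] or not samples[b]:
            warnings.warn(f"empty class for {name}; test skipped", stacklevel=2)
            results[name] = None
            continue
        results[name] = wilcoxon(
            samples[a], samples[b], mode="rank_sum", correction_factor=2.0
        )
    results["summary"] = {
        cls: {
            "mean": float(np.mean(v)) if v else np.nan,
            "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
            "n": len(v),
        }
        for cls, v in samples.items()
    }
    return results
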