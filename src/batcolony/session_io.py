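"""Shared data model and CSV session I/O.

A recording session is exchanged as a small set of plain CSV files plus a JSON
metadata sidecar:

``trajectories.csv``
    long format — ``time, bat, x, y, z, head_dir, zone``; one row per
    (frame, present bat).  Positions in metres (room frame, origin at a room
    corner), head direction in allocentric degrees in [0, 360) and defined
    only while the bat is on a net (empty otherwise).
``interactions.csv``
    ``time, actor, receiver, type`` with type in {affiliative, aggressive,
    joining, leaving}.
``spikes.csv``
    ``neuron, host, time`` — spike times in seconds, per neuron.
``races.csv``
    ``week, bat_a, bat_b, winner`` (written by :func:`write_races`).
``meta.json``
    session id, phase, frame rate and the bat roster with sexes.

All timestamps share the session clock, in seconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ValidationError
from .geometry import DEFAULT_GEOMETRY, RoomGeometry

SEXES = ("male", "female")
INTERACTION_TYPES = ("affiliative", "aggressive", "joining", "leaving")
PHASES = ("dark", "light")


@dataclass(frozen=True)
class Bat:
    """A colony member: short label (e.g. ``"3"``, ``"O"``) and sex."""

    label: str
    sex: str

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r} for bat {self.label!r}")


@dataclass(frozen=True)
class InteractionEvent:
    """A typed, timestamped dyadic social interaction."""

    time: float
    actor: str
    receiver: str
    itype: str

    def __post_init__(self):
        if self.actor == self.receiver:
            raise ValidationError("interaction actor == receiver")
        if self.itype not in INTERACTION_TYPES:
            raise ValidationError(f"unknown interaction type {self.itype!r}")


@dataclass
class SpikeTrain:
    """Sorted spike times of one neuron recorded from ``host``."""

    neuron_id: str
    host: str
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            self.times = np.sort(self.times)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RaceOutcome:
    """One pairwise dominance race: who reached the top first."""

    week: int
    bat_a: str
    bat_b: str
    winner: str

    def __post_init__(self):
        if self.bat_a == self.bat_b:
            raise ValidationError("race between a bat and itself")
        if self.winner not in (self.bat_a, self.bat_b):
            raise ValidationError(
                f"winner {self.winner!r} is neither {self.bat_a!r} nor {self.bat_b!r}"
            )


@dataclass
class TrajectorySet:
    """Time-indexed positions, head directions and zones for all bats.

    ``positions[label]`` is a (T, 3) float array with NaN rows while the bat
    is untracked; ``head_direction[label]`` is (T,) degrees with NaN when
    undefined (bat absent or off-net); ``zone[label]`` is a (T,) object array
    of zone labels with ``""`` when absent.
    """

    session_id: str
    phase: str
    frame_times: np.ndarray
    bats: list[Bat]
    positions: dict[str, np.ndarray]
    head_direction: dict[str, np.ndarray]
    zone: dict[str, np.ndarray]
    geometry: RoomGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.frame_times.size > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        labels = [b.label for b in self.bats]
        if len(set(labels)) != len(labels):
            raise ValidationError("bat labels must be unique")
        T = self.frame_times.size
        for lab in labels:
            for attr in ("positions", "head_direction", "zone"):
                arr = getattr(self, attr).get(lab)
                if arr is None:
                    raise ValidationError(f"bat {lab!r} missing from {attr}")
                if len(arr) != T:
                    raise ValidationError(f"{attr}[{lab!r}] length != n_frames")

    # -- convenience -------------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bats]

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    @property
    def duration(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.frame_times[-1] - self.frame_times[0] + self.frame_interval)

    @property
    def frame_interval(self) -> float:
        if self.n_frames < 2:
            return 1.0 / self.geometry.frame_rate
        return float(np.median(np.diff(self.frame_times)))

    def sex_of(self, label: str) -> str:
        for b in self.bats:
            if b.label == label:
                return b.sex
        raise DataError(f"unknown bat {label!r}")

    def presence(self, label: str) -> np.ndarray:
        return ~np.isnan(self.positions[label][:, 0])

    def on_net(self, label: str, net: str | None = None) -> np.ndarray:
        z = self.zone[label]
        if net is None:
            return (z == self.geometry.large_net.name) | (z == self.geometry.small_net.name)
        return z == net


InteractionLog = list  # list[InteractionEvent]
RaceLog = list  # list[RaceOutcome]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_TRAJ_COLS = ["time", "bat", "x", "y", "z", "head_dir", "zone"]
_INT_COLS = ["time", "actor", "receiver", "type"]
_SPIKE_COLS = ["neuron", "host", "time"]
_RACE_COLS = ["week", "bat_a", "bat_b", "winner"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"{fname}: missing required column {c!r}")


def write_session(
    session: TrajectorySet,
    interactions: Iterable[InteractionEvent],
    spikes: Iterable[SpikeTrain],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a session as the documented CSV set; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for lab in session.labels:
        pres = session.presence(lab)
        idx = np.flatnonzero(pres)
        pos = session.positions[lab][idx]
        hd = session.head_direction[lab][idx]
        zone = session.zone[lab][idx]
        for k, i in enumerate(idx):
            rows.append(
                (
                    session.frame_times[i],
                    lab,
                    pos[k, 0],
                    pos[k, 1],
                    pos[k, 2],
                    "" if math.isnan(hd[k]) else hd[k],
                    zone[k],
                )
            )
    traj = pd.DataFrame(rows, columns=_TRAJ_COLS).sort_values(["time", "bat"])
    paths = {"trajectories": out / "trajectories.csv"}
    traj.to_csv(paths["trajectories"], index=False, float_format="%.9f")

    ev = sorted(interactions, key=lambda e: (e.time, e.actor, e.receiver))
    idf = pd.DataFrame(
        [(e.time, e.actor, e.receiver, e.itype) for e in ev], columns=_INT_COLS
    )
    paths["interactions"] = out / "interactions.csv"
    idf.to_csv(paths["interactions"], index=False, float_format="%.9f")

    srows = []
    for st in spikes:
        for t in st.times:
            srows.append((st.neuron_id, st.host, t))
    sdf = pd.DataFrame(srows, columns=_SPIKE_COLS)
    paths["spikes"] = out / "spikes.csv"
    sdf.to_csv(paths["spikes"], index=False, float_format="%.9f")

    meta = {
        "session_id": session.session_id,
        "phase": session.phase,
        "frame_rate": round(1.0 / session.frame_interval, 9),
        "n_frames": session.n_frames,
        "t0": float(session.frame_times[0]) if session.n_frames else 0.0,
        "bats": [{"label": b.label, "sex": b.sex} for b in session.bats],
    }
    paths["meta"] = out / "meta.json"
    paths["meta"].write_text(json.dumps(meta, indent=1))
    return paths


def load_session(
    in_dir: str | Path, geometry: RoomGeometry | None = None
) -> tuple[TrajectorySet, list[InteractionEvent], list[SpikeTrain]]:
    """Load a session written by :func:`write_session`.

    Zone labels are recomputed from positions and ``geometry`` (they are a
    pure function of both), so a stored file with stale labels is corrected
    on load.
    """
    src = Path(in_dir)
    geometry = geometry or DEFAULT_GEOMETRY
    meta = json.loads((src / "meta.json").read_text())
    bats = [Bat(b["label"], b["sex"]) for b in meta["bats"]]
    geometry = RoomGeometry(
        room_size=tuple(geometry.room_size),
        large_net=geometry.large_net,
        small_net=geometry.small_net,
        bowl_center=geometry.bowl_center,
        bowl_radius=geometry.bowl_radius,
        bowl_z_max=geometry.bowl_z_max,
        net_z_min=geometry.net_z_min,
        frame_rate=float(meta.get("frame_rate", geometry.frame_rate)),
    )

    traj = pd.read_csv(src / "trajectories.csv", dtype={"bat": str, "zone": str})
    _require_columns(traj, _TRAJ_COLS, "trajectories.csv")
    n_frames = int(meta["n_frames"])
    dt = 1.0 / geometry.frame_rate
    t0 = float(meta.get("t0", 0.0))
    frame_times = t0 + np.arange(n_frames) * dt
    if traj.shape[0]:
        tmin, tmax = traj["time"].min(), traj["time"].max()
        if tmin < t0 - 1e-6 or tmax > frame_times[-1] + 1e-6:
            raise ValidationError("trajectory timestamps outside session span")
    frame_idx = np.round((traj["time"].to_numpy() - t0) / dt).astype(int)
    if np.any(np.abs(traj["time"].to_numpy() - (t0 + frame_idx * dt)) > dt / 4):
        raise ValidationError("trajectory timestamps off the frame grid")

    labels = [b.label for b in bats]
    positions = {lab: np.full((n_frames, 3), np.nan) for lab in labels}
    head_dir = {lab: np.full(n_frames, np.nan) for lab in labels}
    for lab, grp in traj.groupby("bat", sort=False):
        if lab not in positions:
            raise DataError(f"trajectories.csv references unknown bat {lab!r}")
        gi = frame_idx[grp.index.to_numpy()]
        order = np.argsort(gi)
        gi_sorted = gi[order]
        if np.any(np.diff(gi_sorted) < 0):
            raise ValidationError(f"non-monotonic timestamps for bat {lab!r}")
        positions[lab][gi] = grp[["x", "y", "z"]].to_numpy()
        head_dir[lab][gi] = pd.to_numeric(grp["head_dir"], errors="coerce").to_numpy()
    zone = {lab: geometry.zone_of(positions[lab]) for lab in labels}
    # head direction only defined on nets
    for lab in labels:
        off_net = ~np.isin(
            zone[lab], [geometry.large_net.name, geometry.small_net.name]
        )
        head_dir[lab][off_net] = np.nan

    session = TrajectorySet(
        session_id=meta["session_id"],
        phase=meta["phase"],
        frame_times=frame_times,
        bats=bats,
        positions=positions,
        head_direction=head_dir,
        zone=zone,
        geometry=geometry,
    )

    idf = pd.read_csv(src / "interactions.csv", dtype={"actor": str, "receiver": str})
    _require_columns(idf, _INT_COLS, "interactions.csv")
    events = [
        InteractionEvent(float(r.time), r.actor, r.receiver, r.type)
        for r in idf.itertuples()
    ]

    spike_path = src / "spikes.csv"
    spike_trains: list[SpikeTrain] = []
    if spike_path.exists():
        sdf = pd.read_csv(spike_path, dtype={"neuron": str, "host": str})
        _require_columns(sdf, _SPIKE_COLS, "spikes.csv")
        for (nid, host), grp in sdf.groupby(["neuron", "host"], sort=True):
            spike_trains.append(SpikeTrain(nid, host, grp["time"].to_numpy()))
    return session, events, spike_trains


def write_races(races: Iterable[RaceOutcome], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(r.week, r.bat_a, r.bat_b, r.winner) for r in races], columns=_RACE_COLS
    )
    df.to_csv(path, index=False)
    return path


def load_races(path: str | Path) -> list[RaceOutcome]:
    df = pd.read_csv(path, dtype={"bat_a": str, "bat_b": str, "winner": str})
    _require_columns(df, _RACE_COLS, str(path))
    return [
        RaceOutcome(int(r.week), r.bat_a, r.bat_b, r.winner) for r in df.itertuples()
    ]
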