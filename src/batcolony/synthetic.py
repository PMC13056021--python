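"""Synthetic colony generator with known ground truth.

Every analysis stage in this package has a recovery test against data whose
generative parameters are known: pairwise affiliation structure (attraction
between bats on the nets), latent dominance ranks (drive race outcomes,
aggression and food-bowl monopolization), sleep-cluster geometry (who sits
interior to the huddle), and egocentrically tuned spike trains (von Mises
direction tuning x Gaussian distance tuning toward a specific conspecific).

All generators are pure functions of (config, seed): the same seed yields
byte-identical output.

Movement model
--------------
Bats alternate between dwell epochs on one of the two landing nets and short
flight epochs through the room (a two-state semi-Markov switch with
exponential durations).  On a net, positions follow an Ornstein-Uhlenbeck
walk pulled toward the net centre plus an affinity-weighted pairwise
attraction: the drift on bat *i* includes ``k_att * sum_j a_ij (x_j - x_i)``
over co-present bats *j*, so higher-affinity pairs sit closer on average.
Optionally bats make food-bowl visits at a rank-dependent rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .angles import egocentric_angle, wrap_positive
from .errors import ConfigError
from .geometry import DEFAULT_GEOMETRY, RoomGeometry
from .session_io import (
    Bat,
    InteractionEvent,
    RaceOutcome,
    SpikeTrain,
    TrajectorySet,
)

_STATE_LARGE, _STATE_SMALL, _STATE_FLIGHT, _STATE_BOWL = 0, 1, 2, 3


@dataclass(frozen=True)
class ColonyConfig:
    """A synthetic colony: roster, latent ranks and affiliation structure.

    ``latent_rank`` maps label -> real rank score (higher = more dominant);
    ``affinity`` is a symmetric matrix in [0, 1] with unit diagonal, indexed
    like ``bats``.
    """

    bats: tuple[Bat, ...]
    latent_rank: dict[str, float]
    affinity: np.ndarray
    n_sessions: int = 1
    session_duration: float = 1800.0
    phase: str = "dark"
    seed: int = 0
    geometry: RoomGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self):
        n = len(self.bats)
        if n < 2:
            raise ConfigError("a colony needs at least 2 bats")
        A = np.asarray(self.affinity, dtype=float)
        if A.shape != (n, n):
            raise ConfigError("affinity must be n_bats x n_bats")
        if not np.allclose(A, A.T) or not np.allclose(np.diag(A), 1.0):
            raise ConfigError("affinity must be symmetric with unit diagonal")
        if A.min() < 0 or A.max() > 1:
            raise ConfigError("affinity entries must lie in [0, 1]")
        missing = [b.label for b in self.bats if b.label not in self.latent_rank]
        if missing:
            raise ConfigError(f"latent_rank missing for bats {missing}")
        object.__setattr__(self, "affinity", A)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bats]


def make_colony(
    n_bats: int = 5,
    seed: int = 0,
    affinity: np.ndarray | None = None,
    **kwargs,
) -> ColonyConfig:
    """Convenience constructor: alternating sexes, evenly spaced latent ranks
    in [0, 1], random symmetric affinity unless one is given."""
    if not 2 <= n_bats <= 26:
        raise ConfigError("n_bats out of range")
    rng = np.random.default_rng(seed)
    labels = [chr(ord("A") + i) for i in range(n_bats)]
    bats = tuple(
        Bat(lab, "female" if i % 2 == 0 else "male") for i, lab in enumerate(labels)
    )
    ranks = {lab: 1.0 - i / max(n_bats - 1, 1) for i, lab in enumerate(labels)}
    if affinity is None:
        affinity = random_affinity(n_bats, rng)
    return ColonyConfig(bats, ranks, np.asarray(affinity, float), seed=seed, **kwargs)


def random_affinity(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric affinity matrix in [0, 1] with unit diagonal."""
    A = np.eye(n)
    iu = np.triu_indices(n, 1)
    vals = rng.uniform(0.0, 1.0, size=len(iu[0]))
    A[iu] = vals
    A[(iu[1], iu[0])] = vals
    return A


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def _epoch_states(
    rng: np.random.Generator,
    n_frames: int,
    dt: float,
    large_net_prob: float,
    dwell_mean: float,
    flight_mean: float,
) -> np.ndarray:
    """Per-frame state codes for one bat (semi-Markov dwell/flight switch)."""
    states = np.empty(n_frames, dtype=np.int8)
    t = 0
    while t < n_frames:
        net = _STATE_LARGE if rng.random() < large_net_prob else _STATE_SMALL
        n_dwell = max(1, int(round(rng.exponential(dwell_mean) / dt)))
        states[t : t + n_dwell] = net
        t += n_dwell
        if t >= n_frames:
            break
        n_fly = max(1, int(round(rng.exponential(flight_mean) / dt)))
        states[t : t + n_fly] = _STATE_FLIGHT
        t += n_fly
    return states[:n_frames]


def simulate_trajectories(
    config: ColonyConfig,
    seed: int,
    *,
    duration: float | None = None,
    frame_rate: float | None = None,
    affinity: np.ndarray | None = None,
    session_id: str = "synthetic",
    large_net_prob: float = 0.85,
    dwell_mean: float = 600.0,
    flight_mean: float = 4.0,
    ou_theta: float = 0.8,
    ou_sigma: float = 0.15,
    attraction_strength: float = 2.0,
    hd_sigma: float = 60.0,
    bowl_rate_per_hour: float = 0.0,
    bowl_rank_gain: float = 0.0,
    bowl_visit_mean: float = 25.0,
) -> TrajectorySet:
    """Simulate one dark-phase session of colony movement.

    ``bowl_rate_per_hour`` > 0 adds food-bowl visits at per-bat rate
    ``bowl_rate_per_hour * (1 + bowl_rank_gain * rank)`` visits/h with
    exponential visit durations, so higher-ranked bats monopolize the bowl
    when ``bowl_rank_gain`` > 0.
    """
    geom = config.geometry
    fr = frame_rate if frame_rate is not None else geom.frame_rate
    if fr != geom.frame_rate:
        geom = replace(geom, frame_rate=fr)
    dur = duration if duration is not None else config.session_duration
    dt = 1.0 / fr
    n_frames = int(round(dur * fr))
    if n_frames < 2:
        raise ConfigError("session too short for the requested frame rate")
    labels = config.labels
    n = len(labels)
    A = np.asarray(affinity if affinity is not None else config.affinity, float)
    if A.shape != (n, n):
        raise ConfigError("affinity must be n_bats x n_bats")
    rng = np.random.default_rng(seed)

    # per-bat state schedule
    states = np.stack(
        [
            _epoch_states(rng, n_frames, dt, large_net_prob, dwell_mean, flight_mean)
            for _ in range(n)
        ],
        axis=1,
    )  # (T, n)

    # rank-dependent bowl visits override the schedule
    if bowl_rate_per_hour > 0:
        ranks = np.array([config.latent_rank[lab] for lab in labels])
        rates = bowl_rate_per_hour * (1.0 + bowl_rank_gain * ranks) / 3600.0
        if np.any(rates < 0):
            raise ConfigError("negative bowl visit rate")
        for i in range(n):
            n_visits = rng.poisson(rates[i] * dur)
            starts = np.sort(rng.uniform(0, dur, size=n_visits))
            for s in starts:
                length = rng.exponential(bowl_visit_mean)
                i0 = int(s * fr)
                i1 = min(n_frames, i0 + max(1, int(length * fr)))
                states[i0:i1, i] = _STATE_BOWL

    nets = (geom.large_net, geom.small_net)
    centers = [net.center_local() for net in nets]
    local = np.full((n_frames, n, 2), np.nan)
    cur = np.empty((n, 2))
    prev_state = np.full(n, -1, dtype=np.int8)
    noise = rng.standard_normal((n_frames, n, 2)) * (ou_sigma * np.sqrt(dt))
    entry_offsets = rng.uniform(-1.0, 1.0, size=(n_frames, n, 2))
    sqdt = np.sqrt(dt)

    for t in range(n_frames):
        st = states[t]
        for code in (_STATE_LARGE, _STATE_SMALL):
            net = nets[code]
            c = centers[code]
            on = st == code
            if not on.any():
                continue
            entered = on & (prev_state != code)
            if entered.any():
                half = np.array([net.width, net.height]) * 0.35
                cur[entered] = c + entry_offsets[t, entered] * half
            idx = np.flatnonzero(on)
            x = cur[idx]
            drift = ou_theta * (c - x)
            if attraction_strength > 0 and len(idx) > 1:
                diff = x[None, :, :] - x[:, None, :]  # j - i
                w = A[np.ix_(idx, idx)].copy()
                np.fill_diagonal(w, 0.0)
                drift = drift + attraction_strength * np.einsum("ij,ijk->ik", w, diff)
            x = x + drift * dt + noise[t, idx]
            np.clip(x[:, 0], 0.01, net.width - 0.01, out=x[:, 0])
            np.clip(x[:, 1], 0.01, net.height - 0.01, out=x[:, 1])
            cur[idx] = x
            local[t, idx] = x
        prev_state = st

    # room-frame positions
    positions = {}
    frame_times = np.arange(n_frames) * dt
    for i, lab in enumerate(labels):
        pos = np.empty((n_frames, 3))
        st = states[:, i]
        for code, net in ((_STATE_LARGE, nets[0]), (_STATE_SMALL, nets[1])):
            m = st == code
            pos[m, 0] = local[m, i, 0] + net.origin[0]
            pos[m, 1] = local[m, i, 1] + net.origin[1]
            pos[m, 2] = net.z
        m = st == _STATE_FLIGHT
        if m.any():
            pos[m, 0] = geom.room_size[0] / 2 + 0.3 * rng.standard_normal(m.sum())
            pos[m, 1] = geom.room_size[1] / 2 + 0.3 * rng.standard_normal(m.sum())
            pos[m, 2] = 1.3
        m = st == _STATE_BOWL
        if m.any():
            r = geom.bowl_radius * 0.5
            pos[m, 0] = geom.bowl_center[0] + r * (rng.random(m.sum()) - 0.5)
            pos[m, 1] = geom.bowl_center[1] + r * (rng.random(m.sum()) - 0.5)
            pos[m, 2] = 0.3
        positions[lab] = pos

    # head direction: wrapped random walk, defined only on nets
    head_dir = {}
    for i, lab in enumerate(labels):
        steps = hd_sigma * sqdt * rng.standard_normal(n_frames)
        hd = wrap_positive(rng.uniform(0, 360) + np.cumsum(steps))
        on_net = (states[:, i] == _STATE_LARGE) | (states[:, i] == _STATE_SMALL)
        hd[~on_net] = np.nan
        head_dir[lab] = hd

    zone = {lab: geom.zone_of(positions[lab]) for lab in labels}
    return TrajectorySet(
        session_id=session_id,
        phase=config.phase,
        frame_times=frame_times,
        bats=list(config.bats),
        positions=positions,
        head_direction=head_dir,
        zone=zone,
        geometry=geom,
    )


def simulate_colony_sessions(
    config: ColonyConfig,
    seed: int,
    *,
    formation_k: int | None = None,
    **traj_kwargs,
) -> list[TrajectorySet]:
    """Simulate ``config.n_sessions`` daily sessions.

    With ``formation_k`` set, the affinity structure "forms" over the first
    *k* sessions: session *s* uses ``(1 - w) * R_s + w * A`` with
    ``w = min(1, s / k)``, where ``R_s`` is a fresh random affinity matrix
    per day and ``A`` the configured final matrix.  Early networks are thus
    decorrelated day to day and the structure stabilizes after *k* days,
    emulating group formation.
    """
    rng = np.random.default_rng(seed)
    n = len(config.bats)
    sessions = []
    for s in range(config.n_sessions):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if formation_k:
            w = min(1.0, s / formation_k)
            R = random_affinity(n, rng)
            A = (1.0 - w) * R + w * config.affinity
            np.fill_diagonal(A, 1.0)
        else:
            A = config.affinity
        sessions.append(
            simulate_trajectories(
                config,
                sub_seed,
                affinity=A,
                session_id=f"day{s:02d}",
                **traj_kwargs,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionRates:
    """Base rates (events/hour) of the four annotated interaction types.

    ``affiliative_per_affinity`` scales with pair affinity; ``aggressive_per_rank_gap``
    scales with |rank difference|; joining/leaving are flat while co-located.
    Defaults are order-of-magnitude choices for a small fruit-bat colony.
    """

    affiliative_per_affinity: float = 6.0
    aggressive_per_rank_gap: float = 4.0
    joining: float = 1.5
    leaving: float = 1.5

    def __post_init__(self):
        for name in (
            "affiliative_per_affinity",
            "aggressive_per_rank_gap",
            "joining",
            "leaving",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"negative interaction rate: {name}")


def simulate_interactions(
    traj: TrajectorySet,
    affinity: np.ndarray,
    rank: dict[str, float],
    rates: InteractionRates,
    seed: int,
) -> list[InteractionEvent]:
    """Draw dyadic events from inhomogeneous Poisson processes.

    Events occur only while both bats of a pair are on the same net.  The
    affiliative rate grows with affinity, the aggressive rate with the pair's
    |rank difference| (the higher-ranked bat is the aggressor).
    """
    rng = np.random.default_rng(seed)
    labels = traj.labels
    n = len(labels)
    A = np.asarray(affinity, float)
    dt_h = traj.frame_interval / 3600.0
    on_net_code = {}
    for lab in labels:
        z = traj.zone[lab]
        code = np.zeros(traj.n_frames, dtype=np.int8)
        code[z == traj.geometry.large_net.name] = 1
        code[z == traj.geometry.small_net.name] = 2
        on_net_code[lab] = code

    events: list[InteractionEvent] = []
    times = traj.frame_times
    for i in range(n):
        for j in range(i + 1, n):
            li, lj = labels[i], labels[j]
            co = (on_net_code[li] == on_net_code[lj]) & (on_net_code[li] > 0)
            if not co.any():
                continue
            idx = np.flatnonzero(co)
            gap = abs(rank[li] - rank[lj])
            p = {
                "affiliative": rates.affiliative_per_affinity * A[i, j] * dt_h,
                "aggressive": rates.aggressive_per_rank_gap * gap * dt_h,
                "joining": rates.joining * dt_h,
                "leaving": rates.leaving * dt_h,
            }
            for itype, prob in p.items():
                if prob <= 0:
                    continue
                hits = idx[rng.random(idx.size) < prob]
                for t_idx in hits:
                    if itype == "aggressive":
                        actor, recv = (li, lj) if rank[li] >= rank[lj] else (lj, li)
                    else:
                        actor, recv = (li, lj) if rng.random() < 0.5 else (lj, li)
                    events.append(
                        InteractionEvent(float(times[t_idx]), actor, recv, itype)
                    )
    events.sort(key=lambda e: (e.time, e.actor, e.receiver))
    return events


# ---------------------------------------------------------------------------
# Races
# ---------------------------------------------------------------------------


def simulate_races(
    rank: dict[str, float], weeks: int, slope: float, seed: int
) -> list[RaceOutcome]:
    """Weekly round-robin dominance races.

    Every pair races once per week; A beats B with probability
    ``logistic(slope * (rank_A - rank_B))``.
    """
    labels = sorted(rank)
    if len(labels) < 2:
        raise ConfigError("need at least 2 bats to race")
    rng = np.random.default_rng(seed)
    races = []
    for w in range(weeks):
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                p_a = 1.0 / (1.0 + np.exp(-slope * (rank[a] - rank[b])))
                winner = a if rng.random() < p_a else b
                races.append(RaceOutcome(w, a, b, winner))
    return races


# ---------------------------------------------------------------------------
# Sleep sessions
# ---------------------------------------------------------------------------


def simulate_sleep_session(
    config: ColonyConfig,
    middle_bats: set[str],
    seed: int,
    *,
    duration: float = 3600.0,
    frame_rate: float = 1.0,
    jitter: float = 0.005,
    ring_radius: float = 0.10,
    session_id: str = "sleep",
) -> TrajectorySet:
    """One light-phase session: a tight sleeping huddle on the large net.

    Bats outside ``middle_bats`` sit on an ellipse (the huddle periphery);
    ``middle_bats`` sit near the centre, interior to the others' convex hull
    in essentially every frame for small ``jitter``.  ``jitter`` is the
    per-frame positional noise SD in metres; 0 freezes the arrangement.
    """
    labels = config.labels
    middle = set(middle_bats)
    unknown = middle - set(labels)
    if unknown:
        raise ConfigError(f"middle_bats not in colony: {sorted(unknown)}")
    n_periph = len(labels) - len(middle)
    if middle and (len(labels) < 4 or n_periph < 3):
        raise ConfigError(
            "geometric infeasibility: need >= 3 peripheral bats to enclose a middle bat"
        )
    geom = config.geometry
    if frame_rate != geom.frame_rate:
        geom = replace(geom, frame_rate=frame_rate)
    net = geom.large_net
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * frame_rate))
    dt = 1.0 / frame_rate
    center = net.center_local()
    periph = [lab for lab in labels if lab not in middle]
    base = {}
    for k, lab in enumerate(periph):
        ang = 2 * np.pi * k / len(periph)
        base[lab] = center + np.array(
            [1.3 * ring_radius * np.cos(ang), 0.8 * ring_radius * np.sin(ang)]
        )
    for k, lab in enumerate(sorted(middle)):
        ang = rng.uniform(0, 2 * np.pi)
        r = 0.15 * ring_radius
        base[lab] = center + np.array([r * np.cos(ang), r * np.sin(ang)])

    positions = {}
    head_dir = {}
    frame_times = np.arange(n_frames) * dt
    for lab in labels:
        xy = np.tile(base[lab], (n_frames, 1))
        if jitter > 0:
            xy = xy + jitter * rng.standard_normal((n_frames, 2))
        pos = np.empty((n_frames, 3))
        pos[:, 0] = np.clip(xy[:, 0], 0.01, net.width - 0.01) + net.origin[0]
        pos[:, 1] = np.clip(xy[:, 1], 0.01, net.height - 0.01) + net.origin[1]
        pos[:, 2] = net.z
        positions[lab] = pos
        head_dir[lab] = np.full(n_frames, float(rng.uniform(0, 360)))
    zone = {lab: geom.zone_of(positions[lab]) for lab in labels}
    return TrajectorySet(
        session_id=session_id,
        phase="light",
        frame_times=frame_times,
        bats=list(config.bats),
        positions=positions,
        head_direction=head_dir,
        zone=zone,
        geometry=geom,
    )


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TuningSpec:
    """Generative tuning of one synthetic neuron.

    In ``egocentric`` mode the firing rate is
    ``baseline * exp(gain * (f_angle + f_dist))`` with
    ``f_angle = exp(kappa * (cos(theta - preferred_angle) - 1))`` (a von
    Mises bump normalized to peak 1) and
    ``f_dist = exp(-(d - preferred_distance)^2 / (2 sd^2))``, evaluated on
    the egocentric bearing/distance of ``target`` from ``host``; baseline
    applies whenever the pair is not co-present on a net.  ``allocentric``
    mode uses a Gaussian bump over the target's position on the large net.
    ``none`` (or kappa = gain = 0) is a homogeneous Poisson process.
    """

    neuron_id: str
    host: str
    target: str
    mode: str = "egocentric"  # egocentric | allocentric | none
    preferred_angle: float = 45.0
    kappa: float = 4.0
    preferred_distance: float = 0.3
    distance_sd: float = 0.12
    baseline_rate: float = 2.0
    gain: float = 1.0
    allo_center: tuple[float, float] = (0.25, 0.25)
    allo_sd: float = 0.12

    def __post_init__(self):
        if self.mode not in ("egocentric", "allocentric", "none"):
            raise ConfigError(f"unknown tuning mode {self.mode!r}")
        if self.kappa < 0 or self.gain < 0 or self.baseline_rate < 0:
            raise ConfigError("kappa, gain and baseline_rate must be >= 0")

    def max_rate(self) -> float:
        if self.mode == "egocentric":
            return self.baseline_rate * float(np.exp(2.0 * self.gain))
        if self.mode == "allocentric":
            return self.baseline_rate * float(np.exp(self.gain))
        return self.baseline_rate


def simulate_spike_train(
    traj: TrajectorySet,
    spec: TuningSpec,
    seed: int,
    *,
    max_rate_cap: float = 200.0,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes by thinning against the frame-wise rate.

    The realized mean rate matches the intended intensity (thinning is
    exact given the piecewise-constant per-frame rate).
    """
    bound = spec.max_rate()
    if bound > max_rate_cap:
        raise ConfigError(
            f"gain too large: peak rate {bound:.1f} Hz exceeds cap {max_rate_cap} Hz"
        )
    rng = np.random.default_rng(seed)
    rate = _frame_rate_profile(traj, spec)
    t0 = float(traj.frame_times[0])
    span = traj.n_frames * traj.frame_interval
    n_cand = rng.poisson(bound * span)
    cand = np.sort(rng.uniform(t0, t0 + span, size=n_cand))
    frame_idx = np.minimum(
        ((cand - t0) / traj.frame_interval).astype(int), traj.n_frames - 1
    )
    keep = rng.random(n_cand) * bound < rate[frame_idx]
    return SpikeTrain(spec.neuron_id, spec.host, cand[keep])


def _frame_rate_profile(traj: TrajectorySet, spec: TuningSpec) -> np.ndarray:
    """Intended firing rate (Hz) at each frame."""
    T = traj.n_frames
    rate = np.full(T, spec.baseline_rate)
    if spec.mode == "none" or spec.gain == 0.0:
        return rate
    geom = traj.geometry
    if spec.host not in traj.positions or spec.target not in traj.positions:
        raise ConfigError("host or target bat not in trajectory set")
    hp = traj.positions[spec.host]
    tp = traj.positions[spec.target]
    if spec.mode == "egocentric":
        zh, zt = traj.zone[spec.host], traj.zone[spec.target]
        hd = traj.head_direction[spec.host]
        co = (
            (zh == zt)
            & np.isin(zh, [geom.large_net.name, geom.small_net.name])
            & ~np.isnan(hd)
        )
        if not co.any():
            raise ConfigError("host and target never co-present on a net")
        theta = egocentric_angle(hp[co, :2], hd[co], tp[co, :2])
        d = np.linalg.norm(tp[co, :2] - hp[co, :2], axis=1)
        f_ang = np.exp(
            spec.kappa * (np.cos(np.radians(theta - spec.preferred_angle)) - 1.0)
        )
        f_dist = np.exp(
            -((d - spec.preferred_distance) ** 2) / (2.0 * spec.distance_sd**2)
        )
        rate[co] = spec.baseline_rate * np.exp(spec.gain * (f_ang + f_dist))
    else:  # allocentric
        net = geom.large_net
        on = (traj.zone[spec.target] == net.name) & (
            traj.zone[spec.host] == net.name
        )
        if not on.any():
            raise ConfigError("host and target never co-present on the large net")
        loc = net.to_local(tp[on, :2])
        mu = np.asarray(spec.allo_center)
        f = np.exp(-np.sum((loc - mu) ** 2, axis=1) / (2.0 * spec.allo_sd**2))
        rate[on] = spec.baseline_rate * np.exp(spec.gain * f)
    return rate
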