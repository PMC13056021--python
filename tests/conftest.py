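"""Shared fixtures: small synthetic colonies and hand-built sessions."""

from __future__ import annotations

import numpy as np
import pytest

from batcolony import encoding as enc
from batcolony import synthetic as syn
from batcolony.geometry import DEFAULT_GEOMETRY
from batcolony.session_io import Bat, TrajectorySet


@pytest.fixture(scope="session")
def colony5():
    return syn.make_colony(5, seed=11)


@pytest.fixture(scope="session")
def colony3():
    return syn.make_colony(3, seed=7)


def make_static_session(
    positions_by_bat: dict[str, np.ndarray],
    n_frames: int = 10,
    head_dir: dict[str, float] | None = None,
    phase: str = "dark",
    frame_rate: float = 25.0,
    session_id: str = "fixture",
) -> TrajectorySet:
    """A session where every bat holds a fixed position (NaN rows allowed).

    ``positions_by_bat`` maps label -> (3,) room-frame position or a
    (n_frames, 3) array for per-frame control.
    """
    geom = DEFAULT_GEOMETRY
    labels = sorted(positions_by_bat)
    bats = [Bat(lab, "female" if i % 2 == 0 else "male") for i, lab in enumerate(labels)]
    frame_times = np.arange(n_frames) / frame_rate
    positions, hd, zone = {}, {}, {}
    for lab in labels:
        p = np.asarray(positions_by_bat[lab], dtype=float)
        if p.ndim == 1:
            p = np.tile(p, (n_frames, 1))
        positions[lab] = p
        z = geom.zone_of(p)
        zone[lab] = z
        on_net = np.isin(z, [geom.large_net.name, geom.small_net.name])
        h = np.full(n_frames, float((head_dir or {}).get(lab, 0.0)))
        h[~on_net] = np.nan
        hd[lab] = h
    return TrajectorySet(
        session_id=session_id,
        phase=phase,
        frame_times=frame_times,
        bats=bats,
        positions=positions,
        head_direction=hd,
        zone=zone,
        geometry=geom,
    )


def encoding_run(
    mode: str,
    seed: int,
    *,
    n_bats: int = 5,
    duration: float = 1800.0,
    frame_rate: float = 10.0,
    host: str = "A",
    target: str = "B",
    **tuning_kwargs,
):
    """Simulate one encoding session and bin it: (frame, counts, spec)."""
    cfg = syn.make_colony(n_bats, seed=0)
    traj = syn.simulate_trajectories(
        cfg,
        seed=seed,
        duration=duration,
        frame_rate=frame_rate,
        large_net_prob=1.0,
        flight_mean=2.0,
    )
    spec = syn.TuningSpec("n0", host=host, target=target, mode=mode, **tuning_kwargs)
    spikes = syn.simulate_spike_train(traj, spec, seed=seed + 10000)
    frame = enc.build_covariates(traj, host)
    return frame, frame.count_spikes(spikes), spec
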