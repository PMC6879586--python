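"""Permeation-event counting, current estimation, and cavity census.

Crossings of the selectivity filter are detected with a per-particle
three-state machine (below | between | above) with a hysteresis margin, an
optional on-axis radial check, and periodic-wrap suppression.  Event counts
convert to current via the elementary charge (160.2176634 pA per net
crossing per ns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnnotationError, GeometryError
from .stats import bootstrap_ci
from .trajio import ChannelAnnotation, Replica, TrajectoryEnsemble
from .units import ELEMENTARY_CHARGE_PA_NS

__all__ = [
    "PermeationEvent",
    "CurrentEstimate",
    "compute_voltage",
    "count_crossings",
    "count_events_z",
    "compute_current",
    "cavity_census",
]


@dataclass(frozen=True)
class PermeationEvent:
    particle: int
    species: str  # "ion" | "water"
    direction: int  # +1 outward (toward extracellular), -1 inward
    entry_frame: int
    completion_frame: int
    replica: int = 0

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.completion_frame < self.entry_frame:
            raise ValueError("completion_frame must be >= entry_frame")


@dataclass
class CurrentEstimate:
    n_out: int
    n_in: int
    t_total: float  # ns
    current: float  # pA
    ci_low: float
    ci_high: float
    per_replica: dict[int, float] = field(default_factory=dict)
    level: float = 0.95


def compute_voltage(field_mv_per_nm: float, l_z: float) -> float:
    """Membrane voltage (mV) from applied field (mV/nm) and box length (nm)."""
    if l_z <= 0:
        raise ValueError("box length must be positive")
    return field_mv_per_nm * l_z


def count_events_z(
    z: np.ndarray,
    z_low: np.ndarray | float,
    z_high: np.ndarray | float,
    box_z: np.ndarray | float,
    delta: float = 0.1,
    rdist: np.ndarray | None = None,
    r_cut: float = 0.6,
    radial_check: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core crossing detector on raw z-coordinates.

    Parameters
    ----------
    z : (frames, particles) particle z-coordinates, nm.
    z_low, z_high : filter bounds per frame (scalar or (frames,) arrays),
        cavity side and extracellular side.
    box_z : box length along z per frame; a consecutive-frame |Δz| greater
        than box_z/2 is treated as a periodic wrap, never a crossing.
    delta : hysteresis margin (nm); a particle is "below" only under
        z_low−delta and "above" only over z_high+delta.
    rdist : (frames, particles) distance from the pore axis, required when
        ``radial_check`` is on: a transit with at least one frame strictly
        between the bounds must pass within ``r_cut`` of the axis.  A direct
        below→above jump with no observed in-between frame still counts.

    Returns
    -------
    (particle, direction, entry_frame, completion_frame) arrays, ordered by
    completion frame then particle index.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2:
        raise ValueError("z must have shape (frames, particles)")
    n_frames, n_part = z.shape
    z_low = np.broadcast_to(np.asarray(z_low, dtype=float), (n_frames,))
    z_high = np.broadcast_to(np.asarray(z_high, dtype=float), (n_frames,))
    box_z = np.broadcast_to(np.asarray(box_z, dtype=float), (n_frames,))
    if np.any(z_low >= z_high):
        raise GeometryError("z_low must be strictly below z_high in every frame")
    if radial_check and rdist is None:
        raise ValueError("radial_check requires rdist")

    state = np.zeros(n_part, dtype=np.int8)  # latched side: -1 below, +1 above, 0 unknown
    was_inside = np.zeros(n_part, dtype=bool)
    ok_radial = np.zeros(n_part, dtype=bool)
    last_side_frame = np.full(n_part, -1, dtype=np.int64)

    ev_particle: list[np.ndarray] = []
    ev_dir: list[np.ndarray] = []
    ev_entry: list[np.ndarray] = []
    ev_done: list[np.ndarray] = []

    prev_z = z[0]
    for t in range(n_frames):
        zt = z[t]
        wrap = (
            np.abs(zt - prev_z) > box_z[t] / 2.0 if t > 0 else np.zeros(n_part, dtype=bool)
        )
        region = np.zeros(n_part, dtype=np.int8)
        region[zt < z_low[t] - delta] = -1
        region[zt > z_high[t] + delta] = +1
        inside = (zt > z_low[t]) & (zt < z_high[t])

        # periodic wraps reset the latch without producing events
        if wrap.any():
            state[wrap] = region[wrap]
            was_inside[wrap] = False
            ok_radial[wrap] = False
            side_wrap = wrap & (region != 0)
            last_side_frame[side_wrap] = t

        ok = ~wrap
        track = ok & inside
        if track.any():
            was_inside[track] = True
            if radial_check:
                near = track & (rdist[t] < r_cut)
                ok_radial[near] = True

        arrived = ok & (region != 0)
        if arrived.any():
            crossing = arrived & (state == -region) & (state != 0)
            if radial_check:
                completed = crossing & (ok_radial | ~was_inside)
            else:
                completed = crossing
            if completed.any():
                idx = np.flatnonzero(completed)
                ev_particle.append(idx)
                ev_dir.append(region[idx].astype(np.int64))
                ev_entry.append(last_side_frame[idx].copy())
                ev_done.append(np.full(idx.size, t, dtype=np.int64))
            state[arrived] = region[arrived]
            was_inside[arrived] = False
            ok_radial[arrived] = False
            last_side_frame[arrived] = t
        prev_z = zt

    if ev_particle:
        particle = np.concatenate(ev_particle)
        direction = np.concatenate(ev_dir)
        entry = np.concatenate(ev_entry)
        done = np.concatenate(ev_done)
    else:
        particle = np.empty(0, dtype=np.int64)
        direction = np.empty(0, dtype=np.int64)
        entry = np.empty(0, dtype=np.int64)
        done = np.empty(0, dtype=np.int64)
    return particle, direction, entry, done


def _auto_bounds(rep: Replica, annotation: ChannelAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame filter bounds: T-OG1 ring mean z (bottom) to G2-O ring mean z (top)."""
    low_idx = annotation.role_indices("T_OG1")
    high_idx = annotation.role_indices("G2_O")
    z_low = rep.coords[:, low_idx, 2].mean(axis=1)
    z_high = rep.coords[:, high_idx, 2].mean(axis=1)
    return z_low, z_high


def _axis_rdist(rep: Replica, annotation: ChannelAnnotation, particles: np.ndarray) -> np.ndarray:
    """Distance of each particle from the pore axis (per frame)."""
    sf_idx = np.concatenate([annotation.role_indices(r) for r in ("T_OG1", "G2_O")])
    center = rep.coords[:, sf_idx, :2].mean(axis=1)  # (F, 2)
    xy = rep.coords[:, particles, :2]  # (F, P, 2)
    return np.linalg.norm(xy - center[:, None, :], axis=-1)


def count_crossings(
    replica: Replica,
    annotation: ChannelAnnotation,
    sf_bounds: tuple[float, float] | str = "auto",
    species: str = "ion",
    delta: float = 0.1,
    radial_check: bool = True,
    r_cut: float = 0.6,
    replica_id: int = 0,
) -> list[PermeationEvent]:
    """Detect completed filter crossings of ions or waters in one replica."""
    if species == "ion":
        particles = annotation.ion_indices
    elif species == "water":
        particles = annotation.water_oxygen_indices
    else:
        raise ValueError("species must be 'ion' or 'water'")
    if particles.size == 0:
        return []
    if isinstance(sf_bounds, str):
        if sf_bounds != "auto":
            raise ValueError("sf_bounds must be 'auto' or a (z_low, z_high) pair")
        z_low, z_high = _auto_bounds(replica, annotation)
    else:
        z_low, z_high = float(sf_bounds[0]), float(sf_bounds[1])
        if z_low >= z_high:
            raise GeometryError("z_low must be strictly below z_high")
    z = replica.coords[:, particles, 2]
    rdist = _axis_rdist(replica, annotation, particles) if radial_check else None
    pid, direction, entry, done = count_events_z(
        z,
        z_low,
        z_high,
        replica.box[:, 2],
        delta=delta,
        rdist=rdist,
        r_cut=r_cut,
        radial_check=radial_check,
    )
    return [
        PermeationEvent(
            particle=int(particles[p]),
            species=species,
            direction=int(d),
            entry_frame=int(e),
            completion_frame=int(c),
            replica=replica_id,
        )
        for p, d, e, c in zip(pid, direction, entry, done)
    ]


def compute_current(
    events: list[PermeationEvent],
    replica_times: dict[int, float] | float,
    level: float = 0.95,
    n_boot: int = 20_000,
    seed: int = 0,
) -> CurrentEstimate:
    """Net-count current with a replica-level bootstrap CI.

    ``replica_times`` maps replica id → sampled time (ns), or is a single
    total time for a one-replica estimate.  The point estimate uses pooled
    counts over pooled time; the CI resamples per-replica currents.
    """
    if isinstance(replica_times, (int, float)):
        replica_times = {0: float(replica_times)}
    t_total = float(sum(replica_times.values()))
    if t_total <= 0:
        raise ValueError("total sampled time must be positive")
    n_out = sum(1 for e in events if e.direction == +1)
    n_in = sum(1 for e in events if e.direction == -1)
    current = ELEMENTARY_CHARGE_PA_NS * (n_out - n_in) / t_total

    per_replica: dict[int, float] = {}
    for rid, t in replica_times.items():
        if t <= 0:
            raise ValueError(f"replica {rid} has non-positive time")
        net = sum(e.direction for e in events if e.replica == rid)
        per_replica[rid] = ELEMENTARY_CHARGE_PA_NS * net / t

    if len(per_replica) >= 2:
        res = bootstrap_ci(
            list(per_replica.values()), n_boot=n_boot, level=level, seed=seed
        )
        ci_low, ci_high = res.ci_low, res.ci_high
    else:
        ci_low = ci_high = current
    return CurrentEstimate(
        n_out=n_out,
        n_in=n_in,
        t_total=t_total,
        current=current,
        ci_low=ci_low,
        ci_high=ci_high,
        per_replica=per_replica,
        level=level,
    )


def cavity_census(
    frame: np.ndarray,
    annotation: ChannelAnnotation,
    radius: float = 1.0,
) -> tuple[int, int]:
    """Count (water oxygens, ions) within ``radius`` of the A88 CA centre of mass."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if "A88" not in annotation.gate:
        raise AnnotationError("cavity census needs the A88 gate role")
    frame = np.asarray(frame, dtype=float)
    com = frame[annotation.role_indices("A88")].mean(axis=0)
    n_water = n_ion = 0
    if annotation.water_oxygen_indices.size:
        d = np.linalg.norm(frame[annotation.water_oxygen_indices] - com, axis=1)
        n_water = int(np.sum(d < radius))
    if annotation.ion_indices.size:
        d = np.linalg.norm(frame[annotation.ion_indices] - com, axis=1)
        n_ion = int(np.sum(d < radius))
    return n_water, n_ion
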