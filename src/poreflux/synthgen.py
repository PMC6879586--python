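"""Synthetic channel ensembles with ground-truth logs.

Builds a pseudo-atom tetramer (filter oxygen rings defining sites S4–S0,
gate beads, helix beads, ions, waters) whose ions hop between compartments
{bulk below, cavity, S4…S0, bulk above} under a barrier model with a voltage
tilt.  The filter spread at the threonine ring is linearly coupled to the
gate opening; the S4/S3 barrier shrinks as the filter opens, and water may
enter (and block) filter sites at large openings.  Every stochastic output
is reproducible bit-exact from the seed, and a ground-truth hop log is
returned alongside the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .errors import ConfigError
from .trajio import (
    ChannelAnnotation,
    Replica,
    ReplicaMeta,
    TopologySpec,
    TrajectoryEnsemble,
)

__all__ = [
    "SynthSpec",
    "GroundTruthLog",
    "COMPARTMENTS",
    "generate_ensemble",
    "build_topology",
    "generate_fma_ensemble",
    "gating_curve_experiment",
    "edge_barriers",
    "rate_matrix",
    "stationary_distribution",
]

#: Ion compartments, cavity side first.  Sites S4…S0 are compartments 2…6.
COMPARTMENTS = ("bulk_below", "cavity", "S4", "S3", "S2", "S1", "S0", "bulk_above")
_SITE_COMP = {"S4": 2, "S3": 3, "S2": 4, "S1": 5, "S0": 6}


@dataclass
class SynthSpec:
    """Full parameterisation of the synthetic channel (units: nm, ns, kT)."""

    n_subunits: int = 4
    plane_offsets: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9, 1.2, 1.5)
    # gate and coupling
    gate_opening: float = 1.6  # A88 CA cross-distance (opposite pairs)
    gate_jitter: float = 0.03  # per-frame SD of the opening
    coupling_intercept: float = 0.20  # s = a + c*g + eps
    coupling_slope: float = 0.25
    coupling_noise: float = 0.005
    # hop-rate model
    barrier_base: float = 2.0  # B0: S4/S3 barrier at optimal opening
    barrier_curvature: float = 300.0  # kappa (kT/nm^2), closed-side growth
    s_opt: float = 0.62  # filter spread of minimal S4/S3 barrier
    barrier_other: float = 1.5
    barrier_bulk: float = 1.0
    voltage_tilt: float = 2.0  # Delta, kT per step (outward bias)
    attempt_rate: float = 1.0  # k0, 1/ns
    recycle_rate: float = 1.0  # bulk_above -> bulk_below teleport, 1/ns
    # water model
    water_entry_max: float = 0.0  # site entry rate at full opening, 1/ns
    water_midpoint: float | None = None  # sigmoid midpoint; default s_opt + 0.05
    water_width: float = 0.04
    water_exit_rate: float = 2.0
    # scripted-rate mode (overrides the hop model when set)
    net_rate: float | None = None  # planted net crossings/ns per replica
    # particles and sampling
    n_ions: int = 4
    n_cavity_waters: int = 40
    n_site_waters: int = 5
    sigma_xyz: float = 0.01
    ion_jitter_z: float = 0.04
    n_frames: int = 1000
    dt: float = 0.5  # ns between frames
    n_replicas: int = 1
    voltage_mv: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits != 4:
            raise ConfigError("the synthetic channel is a tetramer (n_subunits=4)")
        if len(self.plane_offsets) != 6 or np.any(np.diff(self.plane_offsets) <= 0):
            raise ValueError("plane_offsets must be 6 strictly increasing values")
        if self.net_rate is not None and self.net_rate < 0:
            raise ValueError("net_rate must be non-negative")
        if not 0 <= self.water_entry_max:
            raise ValueError("water_entry_max must be non-negative")
        if self.n_frames < 2 or self.dt <= 0:
            raise ValueError("need n_frames >= 2 and dt > 0")

    @property
    def mean_spread(self) -> float:
        return self.coupling_intercept + self.coupling_slope * self.gate_opening

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.dt


@dataclass
class GroundTruthLog:
    """Hop-level record of what the generator actually did."""

    hops: pd.DataFrame  # columns: replica, particle, frame, from_comp, to_comp
    stationary: np.ndarray | None  # hop-chain stationary distribution (8,)
    net_rate: float | None  # expected net crossings/ns (all ions)
    net_crossings: list[int] = field(default_factory=list)  # per replica
    n_cavity_waters: int = 0

    def net_crossings_from_hops(self, replica: int) -> int:
        h = self.hops[self.hops["replica"] == replica]
        out = int(((h["from_comp"] == 6) & (h["to_comp"] == 7)).sum())
        inw = int(((h["from_comp"] == 7) & (h["to_comp"] == 6)).sum())
        return out - inw


def _net_crossings_from_states(states: np.ndarray) -> int:
    """Net filter crossings implied by compartment labels, latch bookkeeping.

    Sides: bulk_below/cavity → −1, bulk_above → +1, filter sites → 0.  An
    outward event is a latched −1 side followed (through the filter) by +1;
    the bulk_above → bulk_below recycling teleport resets the latch without
    an event (it corresponds to a periodic wrap in coordinates).  Ions whose
    first known side is inside the filter contribute nothing until they
    first reach a bulk side — matching the counter's semantics.
    """
    side = np.where(states <= 1, -1, np.where(states == 7, 1, 0)).astype(np.int8)
    net = 0
    n_frames, n_ions = states.shape
    for i in range(n_ions):
        latch = 0
        for t in range(n_frames):
            s = side[t, i]
            if s == 0:
                continue
            teleport = t > 0 and states[t - 1, i] == 7 and states[t, i] == 0
            if not teleport and latch == -s:
                net += int(s)
            latch = s
    return net


# ---------------------------------------------------------------------------
# Hop-chain model
# ---------------------------------------------------------------------------


def edge_barriers(spec: SynthSpec, s: float) -> np.ndarray:
    """Barrier heights (kT) for the 7 edges between consecutive compartments."""
    b = np.array(
        [
            spec.barrier_bulk,  # bulk_below - cavity
            spec.barrier_other,  # cavity - S4
            0.0,  # S4 - S3 (filled below)
            spec.barrier_other,
            spec.barrier_other,
            spec.barrier_other,
            spec.barrier_bulk,  # S0 - bulk_above
        ]
    )
    b[2] = spec.barrier_base + spec.barrier_curvature * max(spec.s_opt - s, 0.0) ** 2
    return b


def _edge_rates(spec: SynthSpec, s: float) -> tuple[np.ndarray, np.ndarray]:
    """(forward, backward) rates per edge: k0·exp(−B ± Δ/2)."""
    b = edge_barriers(spec, s)
    fwd = spec.attempt_rate * np.exp(-b + spec.voltage_tilt / 2.0)
    bwd = spec.attempt_rate * np.exp(-b - spec.voltage_tilt / 2.0)
    return fwd, bwd


def rate_matrix(spec: SynthSpec, s: float | None = None) -> np.ndarray:
    """Generator matrix of the single-ion hop chain (8 compartments)."""
    if s is None:
        s = spec.mean_spread
    fwd, bwd = _edge_rates(spec, s)
    q = np.zeros((8, 8))
    for e in range(7):
        q[e, e + 1] = fwd[e]
        q[e + 1, e] = bwd[e]
    q[7, 0] += spec.recycle_rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_distribution(spec: SynthSpec, s: float | None = None) -> np.ndarray:
    """Stationary distribution π of the hop chain (πQ = 0, π ≥ 0, Σπ = 1)."""
    q = rate_matrix(spec, s)
    ns = null_space(q.T)
    if ns.shape[1] != 1:
        raise ValueError("hop chain is not irreducible")
    pi = np.abs(ns[:, 0])
    return pi / pi.sum()


def planted_net_rate(spec: SynthSpec, s: float | None = None) -> float:
    """Stationary net crossing rate (crossings/ns, all ions) of the hop model."""
    if spec.net_rate is not None:
        return spec.net_rate
    if s is None:
        s = spec.mean_spread
    pi = stationary_distribution(spec, s)
    fwd, bwd = _edge_rates(spec, s)
    return spec.n_ions * float(pi[6] * fwd[6] - pi[7] * bwd[6])


def _water_entry_rate(spec: SynthSpec, s: np.ndarray | float) -> np.ndarray | float:
    mid = spec.s_opt + 0.05 if spec.water_midpoint is None else spec.water_midpoint
    return spec.water_entry_max / (1.0 + np.exp(-(np.asarray(s) - mid) / spec.water_width))


def _check_step_validity(spec: SynthSpec) -> None:
    """The per-frame Euler chain needs total leave probabilities < 1."""
    for s in (spec.mean_spread - 0.2, spec.mean_spread, spec.mean_spread + 0.2):
        q = rate_matrix(spec, max(s, 0.05))
        worst = float(np.max(-np.diag(q))) * spec.dt
        if worst > 0.95:
            raise ValueError(
                f"dt={spec.dt} too large for the hop rates (max leave prob {worst:.2f})"
            )


# ---------------------------------------------------------------------------
# Topology and coordinates
# ---------------------------------------------------------------------------

_CHAIN_IDS = ("A", "B", "C", "D")

# z anchors of the 8 ion compartments (bulk anchors are separated from the
# channel by more than half the box so recycling registers as a periodic
# wrap, never as an inward crossing).
_COMP_Z = np.array([-2.6, -0.8, 0.15, 0.45, 0.75, 1.05, 1.35, 2.6])
_BOX = np.array([4.0, 4.0, 6.0])
_PARK_XY = np.array([1.8, 1.8])  # parked site-water location (off-axis)
_PARK_Z = 2.4


class _AtomTable:
    """Accumulates atoms with per-frame radial/z placement rules."""

    def __init__(self) -> None:
        self.names: list[str] = []
        self.resnames: list[str] = []
        self.resids: list[int] = []
        self.chains: list[str] = []
        self.angle: list[float] = []
        self.kind: list[tuple] = []  # placement rule

    def add(self, name, resname, resid, chain, angle, rule) -> int:
        self.names.append(name)
        self.resnames.append(resname)
        self.resids.append(resid)
        self.chains.append(chain)
        self.angle.append(angle)
        self.kind.append(rule)
        return len(self.names) - 1


def _protein_atoms(spec: SynthSpec) -> tuple[_AtomTable, dict]:
    """Protein pseudo-atoms plus the role → per-subunit index map.

    Placement rules are ("rz", radius_kind, z) where radius_kind selects a
    per-frame radius: fixed value, gate-opening driven, or spread driven.
    """
    tab = _AtomTable()
    roles: dict[str, list[int]] = {
        r: [] for r in (
            "T_OG1", "T_O", "V_O", "G1_O", "Y_O", "G2_O", "T_CA", "V_C", "T59_CG",
            "P19", "F97", "A88", "I84_tip",
        )
    }
    z0, z1, z2, z3, z4, z5 = spec.plane_offsets
    for k in range(spec.n_subunits):
        ch = _CHAIN_IDS[k]
        ang = np.pi / 2.0 * k + np.pi / 4.0
        # gate / helix region (ordered by resid)
        roles["P19"].append(tab.add("CA", "PRO", 19, ch, ang, ("g", 0.4, -2.0)))
        for j in range(5):  # M1 helix beads
            frac = j / 4.0
            tab.add("CA", "LEU", 30 + j, ch, ang + 0.25, ("mix", 0.4, 0.35, frac, -2.2 + 1.9 * frac))
        # selectivity filter TVGYG
        roles["T_CA"].append(tab.add("CA", "THR", 59, ch, ang, ("s", 0.0, z0 - 0.15)))
        roles["T59_CG"].append(tab.add("CG2", "THR", 59, ch, ang, ("s", 0.2, z0 - 0.15)))
        roles["T_OG1"].append(tab.add("OG1", "THR", 59, ch, ang, ("fix", 0.2, z0)))
        roles["T_O"].append(tab.add("O", "THR", 59, ch, ang, ("fix", 0.2, z1)))
        roles["V_C"].append(tab.add("C", "VAL", 60, ch, ang, ("fix", 0.3, z2 - 0.05)))
        roles["V_O"].append(tab.add("O", "VAL", 60, ch, ang, ("fix", 0.2, z2)))
        roles["G1_O"].append(tab.add("O", "GLY", 61, ch, ang, ("fix", 0.2, z3)))
        roles["Y_O"].append(tab.add("O", "TYR", 62, ch, ang, ("fix", 0.2, z4)))
        roles["G2_O"].append(tab.add("O", "GLY", 63, ch, ang, ("fix", 0.2, z5)))
        roles["I84_tip"].append(tab.add("CD", "ILE", 84, ch, ang, ("s", 0.2, z0 - 0.60)))
        roles["A88"].append(tab.add("CA", "ALA", 88, ch, ang, ("g", 0.0, -1.4)))
        for j in range(5):  # M2 helix beads
            frac = j / 4.0
            tab.add("CA", "LEU", 90 + j, ch, ang - 0.25, ("mix", 0.0, 0.3, frac, -2.0 + 1.5 * frac))
        roles["F97"].append(tab.add("CA", "PHE", 97, ch, ang, ("g", 0.2, -1.0)))
    return tab, roles


def _protein_coords(tab: _AtomTable, g_t: np.ndarray, s_t: np.ndarray) -> np.ndarray:
    """Noise-free protein coordinates, (frames, atoms, 3)."""
    n_frames = g_t.shape[0]
    n_atoms = len(tab.names)
    radius = np.empty((n_frames, n_atoms))
    zpos = np.empty((n_frames, n_atoms))
    for i, rule in enumerate(tab.kind):
        if rule[0] == "fix":
            radius[:, i] = rule[1]
            zpos[:, i] = rule[2]
        elif rule[0] == "g":  # cross-distance (g + pad) → ring radius
            radius[:, i] = (g_t + rule[1]) / 2.0
            zpos[:, i] = rule[2]
        elif rule[0] == "s":
            radius[:, i] = (s_t + rule[1] * 2.0) / 2.0
            zpos[:, i] = rule[2]
        elif rule[0] == "mix":  # helix bead: interpolate gate-driven → fixed
            _, pad, top_r, frac, z = rule
            bottom = (g_t + pad) / 2.0
            radius[:, i] = (1.0 - frac) * bottom + frac * top_r
            zpos[:, i] = z
        else:  # pragma: no cover
            raise ValueError(f"unknown placement rule {rule}")
    ang = np.asarray(tab.angle)
    out = np.empty((n_frames, n_atoms, 3))
    out[:, :, 0] = radius * np.cos(ang)
    out[:, :, 1] = radius * np.sin(ang)
    out[:, :, 2] = zpos
    return out


def build_topology(spec: SynthSpec) -> TopologySpec:
    """Atom-level topology (names/resnames/resids/chains) of the system."""
    tab, _ = _protein_atoms(spec)
    names = list(tab.names)
    resnames = list(tab.resnames)
    resids = list(tab.resids)
    chains = list(tab.chains)
    next_resid = 1
    for _ in range(spec.n_ions):
        names.append("K")
        resnames.append("K")
        resids.append(next_resid)
        chains.append("I")
        next_resid += 1
    n_waters = spec.n_cavity_waters + spec.n_site_waters
    for _ in range(n_waters):
        names.append("OW")
        resnames.append("SOL")
        resids.append(next_resid)
        chains.append("W")
        next_resid += 1
    return TopologySpec(names=names, resnames=resnames, resids=resids, chains=chains)


# ---------------------------------------------------------------------------
# Ion dynamics
# ---------------------------------------------------------------------------


def _simulate_hop_chain(
    spec: SynthSpec, s_t: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    """Markov ion states and per-site water occupancy, frame by frame.

    Returns (ion_states (F, n_ions), water_occ (F, 5) bool, hops).
    Ions are independent walkers except that a water in a filter site blocks
    ion entry into it, and waters only enter ion-free sites.
    """
    n_frames = spec.n_frames
    n_ions = spec.n_ions
    states = np.empty((n_frames, n_ions), dtype=np.int8)
    water = np.zeros((n_frames, 5), dtype=bool)
    pi0 = stationary_distribution(spec, float(s_t[0]))
    states[0] = rng.choice(8, size=n_ions, p=pi0)
    hops: list[tuple] = []

    dt = spec.dt
    lam_out = spec.water_exit_rate
    for t in range(1, n_frames):
        s = float(s_t[t])
        fwd, bwd = _edge_rates(spec, s)
        prev = states[t - 1]
        # --- water update (uses ion positions of the previous frame)
        occ = water[t - 1].copy()
        if spec.water_entry_max > 0:
            lam_in = float(_water_entry_rate(spec, s))
            ion_in_site = np.array([(prev == c).any() for c in range(2, 7)])
            u = rng.random(5)
            enter = (~occ) & (~ion_in_site) & (u < lam_in * dt)
            leave = occ & (u < lam_out * dt)
            occ = (occ | enter) & ~leave
        water[t] = occ
        # --- ion moves
        up_rate = np.where(prev < 7, fwd[np.minimum(prev, 6)], spec.recycle_rate)
        down_rate = np.where(prev > 0, bwd[np.maximum(prev - 1, 0)], 0.0)
        dest_up = np.where(prev < 7, prev + 1, 0)
        dest_down = np.maximum(prev - 1, 0)
        if occ.any():
            blocked_up = (dest_up >= 2) & (dest_up <= 6) & occ[np.clip(dest_up - 2, 0, 4)]
            blocked_down = (dest_down >= 2) & (dest_down <= 6) & occ[np.clip(dest_down - 2, 0, 4)]
            up_rate = np.where(blocked_up, 0.0, up_rate)
            down_rate = np.where(blocked_down, 0.0, down_rate)
        p_up = up_rate * dt
        p_down = down_rate * dt
        u = rng.random(n_ions)
        go_up = u < p_up
        go_down = (~go_up) & (u < p_up + p_down)
        new = prev.copy()
        new[go_up] = dest_up[go_up]
        new[go_down] = dest_down[go_down]
        moved = np.flatnonzero(new != prev)
        for i in moved:
            hops.append((int(i), t, int(prev[i]), int(new[i])))
        states[t] = new
    return states, water, hops


def _simulate_scripted(
    spec: SynthSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[tuple], int]:
    """Poisson-scheduled full transits at the planted net rate.

    Each event moves one ion bulk_below → … → bulk_above over 7 frames; the
    ion is recycled below (a periodic wrap) a few frames later.  Returns the
    number of transits completed within the replica.
    """
    n_frames, n_ions = spec.n_frames, spec.n_ions
    states = np.zeros((n_frames, n_ions), dtype=np.int8)
    water = np.zeros((n_frames, 5), dtype=bool)
    hops: list[tuple] = []
    rate = spec.net_rate or 0.0
    completed = 0
    if rate > 0:
        t_ev = []
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate)
            if t >= spec.duration:
                break
            t_ev.append(t)
        free_at = np.zeros(n_ions, dtype=np.int64)
        for te in t_ev:
            f0 = int(np.ceil(te / spec.dt))
            i = int(np.argmin(free_at))
            f0 = max(f0, int(free_at[i]))
            if f0 + 6 > n_frames - 1:
                continue
            for step in range(7):  # below → cavity → S4…S0 → above
                frame = f0 + step
                states[frame:, i] = step + 1
                hops.append((i, frame, step, step + 1))
            back = min(f0 + 12, n_frames - 1)
            if back > f0 + 6:
                states[back:, i] = 0
                hops.append((i, back, 7, 0))
            free_at[i] = back + 1
            completed += 1
    return states, water, hops, completed


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------


def generate_ensemble(
    spec: SynthSpec,
) -> tuple[TrajectoryEnsemble, ChannelAnnotation, GroundTruthLog]:
    """Generate a full synthetic ensemble with its ground-truth log."""
    if spec.net_rate is None:
        _check_step_validity(spec)
    tab, roles = _protein_atoms(spec)
    n_prot = len(tab.names)
    ion_ix = np.arange(n_prot, n_prot + spec.n_ions)
    wat_cav_ix = np.arange(ion_ix[-1] + 1 if spec.n_ions else n_prot, n_prot + spec.n_ions + spec.n_cavity_waters)
    wat_site_ix = np.arange(
        n_prot + spec.n_ions + spec.n_cavity_waters,
        n_prot + spec.n_ions + spec.n_cavity_waters + spec.n_site_waters,
    )
    water_ix = np.concatenate([wat_cav_ix, wat_site_ix])

    annotation = ChannelAnnotation(
        n_subunits=spec.n_subunits,
        sf={r: tuple(roles[r]) for r in ("T_OG1", "T_O", "V_O", "G1_O", "Y_O", "G2_O", "T_CA", "V_C", "T59_CG")},
        gate={r: tuple(roles[r]) for r in ("P19", "F97", "A88", "I84_tip")},
        ion_indices=ion_ix,
        water_oxygen_indices=water_ix,
    )

    site_mid = np.array([0.5 * (spec.plane_offsets[i] + spec.plane_offsets[i + 1]) for i in range(5)])
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(spec.n_replicas)

    replicas: list[Replica] = []
    all_hops: list[dict] = []
    net_crossings: list[int] = []
    for r, cs in enumerate(child_seeds):
        rng = np.random.default_rng(cs)
        g_t = spec.gate_opening + spec.gate_jitter * rng.standard_normal(spec.n_frames)
        s_t = (
            spec.coupling_intercept
            + spec.coupling_slope * g_t
            + spec.coupling_noise * rng.standard_normal(spec.n_frames)
        )
        s_t = np.maximum(s_t, 0.05)

        if spec.net_rate is not None:
            states, water_occ, hops, _completed = _simulate_scripted(spec, rng)
        else:
            states, water_occ, hops = _simulate_hop_chain(spec, s_t, rng)
        net_crossings.append(_net_crossings_from_states(states))
        for (i, t, a, b) in hops:
            all_hops.append(
                {"replica": r, "particle": int(ion_ix[i]), "frame": t, "from_comp": a, "to_comp": b}
            )

        n_atoms = n_prot + spec.n_ions + spec.n_cavity_waters + spec.n_site_waters
        coords = np.empty((spec.n_frames, n_atoms, 3))
        coords[:, :n_prot] = _protein_coords(tab, g_t, s_t)

        # ions: compartment anchor + jitter
        if spec.n_ions:
            zi = _COMP_Z[states]  # (F, I)
            coords[:, ion_ix, 0] = 0.0
            coords[:, ion_ix, 1] = 0.0
            coords[:, ion_ix, 2] = zi + spec.ion_jitter_z * rng.standard_normal(zi.shape)
        # cavity waters: static cloud near the A88 centre of mass
        if spec.n_cavity_waters:
            phi = rng.uniform(0, 2 * np.pi, spec.n_cavity_waters)
            rad = 0.45 * np.sqrt(rng.uniform(0, 1, spec.n_cavity_waters))
            zw = rng.uniform(-1.6, -1.0, spec.n_cavity_waters)
            base = np.column_stack([rad * np.cos(phi), rad * np.sin(phi), zw])
            coords[:, wat_cav_ix] = base[None, :, :]
        # site waters: parked off-axis above, or placed at their site centre
        if spec.n_site_waters:
            park = np.column_stack(
                [
                    np.full(spec.n_site_waters, _PARK_XY[0]),
                    np.full(spec.n_site_waters, _PARK_XY[1]),
                    _PARK_Z + 0.1 * np.arange(spec.n_site_waters),
                ]
            )
            coords[:, wat_site_ix] = park[None, :, :]
            n_assign = min(5, spec.n_site_waters)
            for site in range(n_assign):  # water j serves site j
                occ_frames = np.flatnonzero(water_occ[:, site])
                if occ_frames.size:
                    coords[occ_frames, wat_site_ix[site], 0] = 0.0
                    coords[occ_frames, wat_site_ix[site], 1] = 0.0
                    coords[occ_frames, wat_site_ix[site], 2] = site_mid[site]

        if spec.sigma_xyz > 0:
            coords += spec.sigma_xyz * rng.standard_normal(coords.shape)

        times = np.arange(spec.n_frames, dtype=float) * spec.dt
        box = np.broadcast_to(_BOX, (spec.n_frames, 3)).copy()
        meta = ReplicaMeta(
            forcefield="synthetic",
            voltage_mv=spec.voltage_mv,
            restraint=f"g={spec.gate_opening:g}",
            seed=int(cs.generate_state(1)[0] % 2**31),
        )
        replicas.append(Replica(coords=coords, box=box, times=times, meta=meta))

    hops_df = pd.DataFrame(
        all_hops, columns=["replica", "particle", "frame", "from_comp", "to_comp"]
    )
    stationary = None if spec.net_rate is not None else stationary_distribution(spec)
    log = GroundTruthLog(
        hops=hops_df,
        stationary=stationary,
        net_rate=planted_net_rate(spec),
        net_crossings=net_crossings,
        n_cavity_waters=spec.n_cavity_waters,
    )
    return TrajectoryEnsemble(replicas=replicas), annotation, log


def generate_fma_ensemble(
    n_frames: int,
    n_atoms: int,
    planted_mode: np.ndarray,
    snr: float,
    seed: int = 0,
    coord_noise: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Planted-mode ensemble for FMA testing.

    Frames are ``mean + q(t)·mode + isotropic noise`` with q ~ N(0, 1); the
    target is ``q + noise`` with signal-to-noise ratio ``snr`` (so the
    generative R² is snr/(1+snr)).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    mode = np.asarray(planted_mode, dtype=float).ravel()
    if mode.size != 3 * n_atoms:
        raise ValueError("planted_mode must have length 3*n_atoms")
    if abs(np.linalg.norm(mode) - 1.0) > 1e-8:
        raise ValueError("planted_mode must be unit-norm")
    rng = np.random.default_rng(seed)
    mean = rng.normal(scale=1.0, size=(n_atoms, 3))
    q = rng.standard_normal(n_frames)
    coords = (
        mean[None, :, :]
        + q[:, None, None] * mode.reshape(1, n_atoms, 3)
        + coord_noise * rng.standard_normal((n_frames, n_atoms, 3))
    )
    target = q + np.sqrt(1.0 / snr) * rng.standard_normal(n_frames)
    info = {"generative_r2": snr / (1.0 + snr), "q": q}
    return coords, target, info


def gating_curve_experiment(
    spec_series: Sequence[SynthSpec],
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full pipeline over a series of opening levels.

    Returns a tidy table with one row per (opening, metric[, site, species]):
    current with CI, per-site occupancy fractions, and the cavity census.
    """
    from . import filter_state, permeation  # local import avoids a cycle

    if not spec_series:
        raise ValueError("spec series is empty")
    rows: list[dict] = []
    for spec in spec_series:
        ensemble, annotation, log = generate_ensemble(spec)
        events = []
        times = {}
        for r, rep in enumerate(ensemble.replicas):
            events.extend(
                permeation.count_crossings(rep, annotation, replica_id=r, species="ion")
            )
            times[r] = rep.duration
        est = permeation.compute_current(events, times, n_boot=n_boot, seed=seed)
        g = spec.gate_opening
        rows.append(
            {
                "opening": g, "metric": "current", "site": "", "species": "",
                "value": est.current, "ci_low": est.ci_low, "ci_high": est.ci_high,
            }
        )
        occ = filter_state.occupancy_table(
            ensemble, annotation, n_boot=n_boot, seed=seed
        )
        for rec in occ:
            for species, frac, ci in (
                ("ion", rec.fraction_ion, rec.ci_ion),
                ("water", rec.fraction_water, rec.ci_water),
                ("vacant", rec.fraction_vacant, rec.ci_vacant),
            ):
                rows.append(
                    {
                        "opening": g, "metric": "occupancy", "site": rec.site,
                        "species": species, "value": frac,
                        "ci_low": ci[0], "ci_high": ci[1],
                    }
                )
        census = [
            permeation.cavity_census(rep.coords[t], annotation)
            for rep in ensemble.replicas
            for t in range(0, rep.n_frames, max(1, rep.n_frames // 50))
        ]
        nw = float(np.mean([c[0] for c in census]))
        ni = float(np.mean([c[1] for c in census]))
        rows.append(
            {"opening": g, "metric": "cavity_waters", "site": "", "species": "water",
             "value": nw, "ci_low": np.nan, "ci_high": np.nan}
        )
        rows.append(
            {"opening": g, "metric": "cavity_ions", "site": "", "species": "ion",
             "value": ni, "ci_low": np.nan, "ci_high": np.nan}
        )
    return pd.DataFrame(rows)


def spec_series_over_openings(
    base: SynthSpec, openings: Sequence[float]
) -> list[SynthSpec]:
    """Copies of ``base`` varying only the gate opening (seeds offset per level)."""
    return [
        replace(base, gate_opening=float(g), seed=base.seed + 1000 * i)
        for i, g in enumerate(openings)
    ]
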