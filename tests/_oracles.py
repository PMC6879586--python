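"""Independent brute-force oracles used to cross-check the package.

These deliberately re-implement the rules in the plainest possible way
(per-particle sequential loops, exhaustive grid searches) so they share no
code path with the vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _crossing_oracle_core(z, z_low, z_high, box_z, delta, rdist, r_cut, radial_check):
    n_frames, n_part = z.shape
    cap = 1024
    out = np.empty((cap, 4), dtype=np.int64)
    n_ev = 0
    for p in range(n_part):
        state = 0
        was_inside = False
        ok_radial = False
        lsf = -1
        for t in range(n_frames):
            zt = z[t, p]
            wrap = t > 0 and abs(zt - z[t - 1, p]) > box_z[t] / 2.0
            region = 0
            if zt < z_low[t] - delta:
                region = -1
            elif zt > z_high[t] + delta:
                region = 1
            inside = (zt > z_low[t]) and (zt < z_high[t])
            if wrap:
                state = region
                was_inside = False
                ok_radial = False
                if region != 0:
                    lsf = t
                continue
            if inside:
                was_inside = True
                if radial_check and rdist[t, p] < r_cut:
                    ok_radial = True
            if region != 0:
                if state == -region and state != 0:
                    if (not radial_check) or ok_radial or (not was_inside):
                        if n_ev == cap:
                            cap *= 2
                            grown = np.empty((cap, 4), dtype=np.int64)
                            grown[:n_ev] = out
                            out = grown
                        out[n_ev, 0] = p
                        out[n_ev, 1] = region
                        out[n_ev, 2] = lsf
                        out[n_ev, 3] = t
                        n_ev += 1
                state = region
                was_inside = False
                ok_radial = False
                lsf = t
    return out[:n_ev]


def crossing_oracle(
    z,
    z_low,
    z_high,
    box_z,
    delta=0.1,
    rdist=None,
    r_cut=0.6,
    radial_check=True,
):
    """Brute-force crossing enumerator; returns (n_events, 4) int64 rows
    (particle, direction, entry_frame, completion_frame)."""
    z = np.ascontiguousarray(z, dtype=np.float64)
    n_frames = z.shape[0]
    z_low = np.ascontiguousarray(np.broadcast_to(np.asarray(z_low, float), (n_frames,)))
    z_high = np.ascontiguousarray(np.broadcast_to(np.asarray(z_high, float), (n_frames,)))
    box_z = np.ascontiguousarray(np.broadcast_to(np.asarray(box_z, float), (n_frames,)))
    if rdist is None:
        rdist = np.zeros_like(z)
        radial_check = False
    rdist = np.ascontiguousarray(rdist, dtype=np.float64)
    return _crossing_oracle_core(
        z, z_low, z_high, box_z, float(delta), rdist, float(r_cut), bool(radial_check)
    )


def events_to_set(events):
    """Canonical comparable form for PermeationEvent lists or oracle rows."""
    rows = []
    for e in events:
        if hasattr(e, "direction"):
            rows.append((e.particle, e.direction, e.entry_frame, e.completion_frame))
        else:
            rows.append(tuple(int(x) for x in e))
    return sorted(rows)


def pore_radius_grid_oracle(atoms, vdw, z, extent=1.0, step=0.01, r_max=1.5):
    """Exhaustive 2-D grid search (disc of radius ``extent`` around the axis)
    for the largest clearance sphere centred at height z."""
    atoms = np.asarray(atoms, dtype=float)
    vdw = np.asarray(vdw, dtype=float)
    xs = np.arange(-extent, extent + step / 2, step)
    best = -np.inf
    for cx in xs:
        dx2 = (atoms[:, 0] - cx) ** 2
        for cy in xs:
            if cx * cx + cy * cy > extent * extent:
                continue
            d = np.sqrt(dx2 + (atoms[:, 1] - cy) ** 2 + (atoms[:, 2] - z) ** 2)
            val = np.min(d - vdw)
            if val > best:
                best = val
    return min(max(best, 0.0), r_max)


def cross_distance_brute(points, mode):
    """Direct pairwise re-computation of the cross-distance definitions.

    The diagonal pairing is found by exhaustive enumeration of the three
    perfect matchings, taking the one with the largest summed distance.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    if mode == "mean_all_pairs":
        iu = np.triu_indices(n, k=1)
        return float(d[iu].mean())
    best, pairing = -np.inf, None
    for (a, b), (c, e) in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
        total = d[a, b] + d[c, e]
        if total > best:
            best, pairing = total, ((a, b), (c, e))
    (a, b), (c, e) = pairing
    if mode == "opposite":
        return float(0.5 * (d[a, b] + d[c, e]))
    if mode == "adjacent":
        pairs = [(a, c), (c, b), (b, e), (e, a)]
        return float(np.mean([d[i, k] for i, k in pairs]))
    raise ValueError(mode)
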