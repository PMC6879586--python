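"""Axial ion-density / free-energy profiles and HOLE-style pore radius profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .stats import coverage_ci

__all__ = [
    "FreeEnergyProfile",
    "PoreProfile",
    "DEFAULT_VDW_NM",
    "kde_profile",
    "profile_ci",
    "average_profiles",
    "pore_radius_profile",
    "constriction_report",
]

#: Element-keyed van der Waals radii (nm).  A declared dialect choice; HOLE's
#: own table differs slightly.
DEFAULT_VDW_NM = {"H": 0.12, "C": 0.17, "N": 0.155, "O": 0.152, "S": 0.18}


@dataclass
class FreeEnergyProfile:
    z: np.ndarray  # nm, relative to the chosen reference plane
    density: np.ndarray  # 1/nm, integrates to 1 on the grid
    free_energy: np.ndarray  # kT, minimum 0 at the density maximum
    bandwidth: float  # nm
    n_samples: int
    ci: np.ndarray | None = None  # pointwise half-width, kT


@dataclass
class PoreProfile:
    z: np.ndarray
    radius: np.ndarray  # nm, clipped to [0, r_max]
    status: list[bool]  # per-slice optimiser convergence
    r_max: float


def kde_profile(
    z_samples: np.ndarray,
    grid: np.ndarray,
    bandwidth: float | None = None,
) -> FreeEnergyProfile:
    """Gaussian-KDE density on ``grid`` plus −ln(density/max) free energy.

    The default bandwidth is Scott's rule (n^(−1/5) × sample SD); pass a
    fixed ``bandwidth`` (nm) for comparability across opening levels.  The
    density is renormalised to integrate to exactly 1 on the grid.
    """
    z_samples = np.asarray(z_samples, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float)
    if z_samples.size < 2:
        raise ValueError("kde_profile needs at least 2 samples")
    sd = z_samples.std(ddof=1)
    if sd == 0:
        raise ValueError("samples have zero variance")
    if bandwidth is None:
        kde = sps.gaussian_kde(z_samples, bw_method="scott")
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        kde = sps.gaussian_kde(z_samples, bw_method=bandwidth / sd)
    h = float(kde.factor * sd)
    density = kde(grid)
    norm = np.trapezoid(density, grid)
    if norm <= 0:
        raise ValueError("grid does not cover the sample range")
    density = density / norm
    dmax = density.max()
    with np.errstate(divide="ignore"):
        free_energy = -np.log(density / dmax)
    return FreeEnergyProfile(
        z=grid,
        density=density,
        free_energy=free_energy,
        bandwidth=h,
        n_samples=z_samples.size,
    )


def profile_ci(per_replica_values: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Pointwise coverage-factor CI half-widths across replica profiles.

    ``per_replica_values`` is (n_replicas, n_grid); returns (n_grid,)
    half-widths: t-quantile(level, n−1) × SEM.
    """
    values = np.asarray(per_replica_values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("profile_ci needs >= 2 replica profiles on a common grid")
    return np.array([coverage_ci(values[:, j], level=level) for j in range(values.shape[1])])


def average_profiles(
    profiles: list[FreeEnergyProfile], level: float = 0.95
) -> FreeEnergyProfile:
    """Average per-replica free-energy profiles and attach coverage CIs.

    Profiles are averaged on the free-energy scale (after each replica's own
    minimum-zero normalisation), then re-zeroed at the pooled minimum.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    grid = profiles[0].z
    for p in profiles[1:]:
        if not np.array_equal(p.z, grid):
            raise ValueError("profiles must share one grid")
    f = np.vstack([p.free_energy for p in profiles])
    mean_f = f.mean(axis=0)
    mean_f = mean_f - mean_f.min()
    density = np.exp(-mean_f)
    density /= np.trapezoid(density, grid)
    ci = profile_ci(f, level=level) if len(profiles) >= 2 else None
    return FreeEnergyProfile(
        z=grid,
        density=density,
        free_energy=mean_f,
        bandwidth=float(np.mean([p.bandwidth for p in profiles])),
        n_samples=int(sum(p.n_samples for p in profiles)),
        ci=ci,
    )


def _slice_radius(
    atoms: np.ndarray,
    vdw: np.ndarray,
    z: float,
    start_centers: list[np.ndarray],
    r_max: float,
    axis_xy: np.ndarray,
    extent: float,
) -> tuple[float, np.ndarray, bool]:
    """Largest sphere centred in the plane at height z not overlapping any atom.

    The centre search is confined to a disc of radius ``extent`` around the
    pore axis (a quadratic penalty outside), otherwise the optimiser escapes
    through side gaps into open solvent.
    """

    def clearance(c: np.ndarray) -> float:
        d = np.sqrt(
            (atoms[:, 0] - c[0]) ** 2 + (atoms[:, 1] - c[1]) ** 2 + (atoms[:, 2] - z) ** 2
        )
        off_axis = np.hypot(c[0] - axis_xy[0], c[1] - axis_xy[1])
        penalty = 1e3 * max(0.0, off_axis - extent) ** 2
        return float(np.min(d - vdw)) - penalty

    best_val, best_c, converged = -np.inf, None, False
    for c0 in start_centers:
        res = optimize.minimize(
            lambda c: -clearance(c),
            np.asarray(c0[:2], dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        if -res.fun > best_val:
            best_val = -res.fun
            best_c = res.x
            converged = bool(res.success)
    return min(max(best_val, 0.0), r_max), best_c, converged


def pore_radius_profile(
    atoms: np.ndarray,
    vdw_radii: np.ndarray,
    grid: np.ndarray,
    r_max: float = 1.5,
    axis_xy: tuple[float, float] = (0.0, 0.0),
    extent: float = 1.0,
    n_extra_starts: int = 4,
    start_spread: float = 0.2,
) -> PoreProfile:
    """HOLE-style pore radius along z.

    Per slice the radius is the maximum over in-plane centres (within
    ``extent`` of the axis) of the minimal atom clearance (3-D distance
    minus vdW radius), found by multi-start Nelder-Mead seeded on the
    previous slice's centre plus fixed offsets.
    """
    atoms = np.asarray(atoms, dtype=float)
    grid = np.asarray(grid, dtype=float)
    vdw_radii = np.asarray(vdw_radii, dtype=float)
    if atoms.size == 0:
        return PoreProfile(
            z=grid, radius=np.full(grid.shape, r_max), status=[True] * len(grid), r_max=r_max
        )
    if atoms.shape[0] != vdw_radii.shape[0]:
        raise ValueError("need one vdW radius per atom")

    offsets = [np.zeros(2)] + [
        start_spread * np.array([np.cos(a), np.sin(a)])
        for a in np.linspace(0, 2 * np.pi, n_extra_starts, endpoint=False)
    ]
    axis = np.asarray(axis_xy, dtype=float)
    center = axis.copy()
    radius = np.empty(len(grid))
    status = []
    for j, z in enumerate(grid):
        starts = [center + off for off in offsets]
        r, c, ok = _slice_radius(atoms, vdw_radii, float(z), starts, r_max, axis, extent)
        radius[j] = r
        status.append(ok)
        if c is not None and r < r_max:
            center = c  # seed the next slice
    return PoreProfile(z=grid, radius=radius, status=status, r_max=r_max)


def constriction_report(
    profile: PoreProfile, threshold: float = 0.4
) -> tuple[float, float, bool]:
    """(minimum radius, z at the minimum, radius-below-threshold flag)."""
    j = int(np.argmin(profile.radius))
    r_min = float(profile.radius[j])
    return r_min, float(profile.z[j]), bool(r_min < threshold)
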