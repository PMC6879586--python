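"""Selectivity-filter site geometry, occupancy classification, carbonyl flips.

Sites are the cages between consecutive oxygen-ring planes, labelled S4
(bottom, threonine hydroxyl/backbone cage) to S0 (top); Scav is a vestibule
of width ``w_cav`` below the hydroxyl plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AnnotationError, PorefluxError
from .stats import bootstrap_ci
from .trajio import SF_ROLES, ChannelAnnotation, Replica, TrajectoryEnsemble

__all__ = [
    "SITE_NAMES",
    "SiteGeometry",
    "OccupancyRecord",
    "FlipSeries",
    "site_boundaries",
    "classify_site",
    "occupancy_table",
    "detect_flips",
]

logger = logging.getLogger(__name__)

SITE_NAMES = ("S4", "S3", "S2", "S1", "S0")


@dataclass
class SiteGeometry:
    plane_z: np.ndarray  # (6,) mean z of the oxygen rings, cavity side first
    sites: dict[str, tuple[float, float]]
    axis_point: np.ndarray  # (3,)
    axis_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    r_site: float = 0.35
    valid: bool = True

    def center(self, site: str) -> np.ndarray:
        lo, hi = self.sites[site]
        zc = 0.5 * (lo + hi)
        return self.axis_point + (zc - self.axis_point[2]) * self.axis_dir


@dataclass
class OccupancyRecord:
    site: str
    fraction_ion: float
    fraction_water: float
    fraction_vacant: float
    ci_ion: tuple[float, float]
    ci_water: tuple[float, float]
    ci_vacant: tuple[float, float]
    n_frames: int

    def __post_init__(self) -> None:
        total = self.fraction_ion + self.fraction_water + self.fraction_vacant
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancy fractions sum to {total}, not 1")


@dataclass
class FlipSeries:
    role: str
    flipped: list[np.ndarray]  # one (frames, subunits) bool array per replica
    theta_flip: float

    @property
    def fraction(self) -> float:
        return float(np.mean(np.concatenate([f.reshape(-1) for f in self.flipped])))


def site_boundaries(
    frame: np.ndarray,
    annotation: ChannelAnnotation,
    w_cav: float = 0.4,
    r_site: float = 0.35,
) -> SiteGeometry:
    """Per-frame oxygen-plane z values and the S4…S0 (+Scav) intervals.

    Non-monotonic planes mark the frame invalid (excluded from occupancy
    statistics with a logged warning) instead of raising.
    """
    frame = np.asarray(frame, dtype=float)
    plane_z = np.array(
        [frame[annotation.role_indices(role), 2].mean() for role in SF_ROLES]
    )
    sf_idx = np.concatenate([annotation.role_indices(r) for r in SF_ROLES])
    axis_point = np.array([*frame[sf_idx, :2].mean(axis=0), plane_z[0]])
    valid = bool(np.all(np.diff(plane_z) > 0))
    if not valid:
        logger.warning("non-monotonic SF oxygen planes %s; frame flagged", plane_z)
    sites = {
        "S4": (plane_z[0], plane_z[1]),
        "S3": (plane_z[1], plane_z[2]),
        "S2": (plane_z[2], plane_z[3]),
        "S1": (plane_z[3], plane_z[4]),
        "S0": (plane_z[4], plane_z[5]),
        "Scav": (plane_z[0] - w_cav, plane_z[0]),
    }
    return SiteGeometry(
        plane_z=plane_z, sites=sites, axis_point=axis_point, r_site=r_site, valid=valid
    )


def _particles_in_site(
    frame: np.ndarray, geom: SiteGeometry, site: str, indices: np.ndarray
) -> np.ndarray:
    if indices.size == 0:
        return indices
    lo, hi = geom.sites[site]
    pos = frame[indices]
    in_z = (pos[:, 2] >= lo) & (pos[:, 2] < hi)
    rd = np.linalg.norm(pos[:, :2] - geom.axis_point[:2], axis=1)
    return indices[in_z & (rd < geom.r_site)]


def classify_site(
    frame: np.ndarray,
    geom: SiteGeometry,
    site: str,
    annotation: ChannelAnnotation,
) -> str:
    """Classify one site in one frame as ``ion``, ``water`` or ``vacant``.

    A particle occupies the site when its z lies in the site interval and it
    is within ``r_site`` of the pore axis; with both species present the
    particle nearest the site centre wins.
    """
    frame = np.asarray(frame, dtype=float)
    if site not in geom.sites:
        raise PorefluxError(f"unknown site {site!r}")
    ions = _particles_in_site(frame, geom, site, annotation.ion_indices)
    waters = _particles_in_site(frame, geom, site, annotation.water_oxygen_indices)
    if ions.size == 0 and waters.size == 0:
        return "vacant"
    center = geom.center(site)
    d_ion = np.min(np.linalg.norm(frame[ions] - center, axis=1)) if ions.size else np.inf
    d_wat = np.min(np.linalg.norm(frame[waters] - center, axis=1)) if waters.size else np.inf
    return "ion" if d_ion <= d_wat else "water"


def _replica_fractions(
    rep: Replica,
    annotation: ChannelAnnotation,
    sites: tuple[str, ...],
    w_cav: float,
    r_site: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """(n_sites, 3) occupancy fractions [ion, water, vacant] and valid-frame count."""
    counts = np.zeros((len(sites), 3))
    n_valid = 0
    for t in range(rep.n_frames):
        geom = site_boundaries(rep.coords[t], annotation, w_cav=w_cav, r_site=r_site)
        if not geom.valid:
            continue
        n_valid += 1
        for s, site in enumerate(sites):
            label = classify_site(rep.coords[t], geom, site, annotation)
            counts[s, {"ion": 0, "water": 1, "vacant": 2}[label]] += 1
    if n_valid == 0:
        return counts, np.full((len(sites), 3), np.nan), 0
    return counts, counts / n_valid, n_valid


def occupancy_table(
    ensemble: TrajectoryEnsemble,
    annotation: ChannelAnnotation,
    sites: tuple[str, ...] = SITE_NAMES,
    w_cav: float = 0.4,
    r_site: float = 0.35,
    n_boot: int = 20_000,
    level: float = 0.95,
    seed: int = 0,
) -> list[OccupancyRecord]:
    """Per-site ion/water/vacant fractions with replica-bootstrap CIs."""
    per_rep: list[np.ndarray] = []
    counts_total = np.zeros((len(sites), 3))
    n_frames_total = 0
    for rep in ensemble.replicas:
        counts, fractions, n_valid = _replica_fractions(rep, annotation, sites, w_cav, r_site)
        if n_valid > 0:
            per_rep.append(fractions)
            counts_total += counts
            n_frames_total += n_valid
    if n_frames_total == 0:
        raise PorefluxError("no valid frames: all SF geometries were flagged")
    pooled = counts_total / n_frames_total

    records = []
    for s, site in enumerate(sites):
        cis = []
        for k in range(3):
            vals = [fr[s, k] for fr in per_rep]
            if len(vals) >= 2:
                res = bootstrap_ci(vals, n_boot=n_boot, level=level, seed=seed + s * 3 + k)
                cis.append((res.ci_low, res.ci_high))
            else:
                cis.append((pooled[s, k], pooled[s, k]))
        # guard against float drift in the pooled normalisation
        frac = pooled[s] / pooled[s].sum()
        records.append(
            OccupancyRecord(
                site=site,
                fraction_ion=float(frac[0]),
                fraction_water=float(frac[1]),
                fraction_vacant=float(frac[2]),
                ci_ion=cis[0],
                ci_water=cis[1],
                ci_vacant=cis[2],
                n_frames=n_frames_total,
            )
        )
    return records


def detect_flips(
    ensemble: TrajectoryEnsemble,
    annotation: ChannelAnnotation,
    role_c: str = "V_C",
    role_o: str = "V_O",
    theta_flip: float = 90.0,
) -> FlipSeries:
    """Carbonyl flips: C→O orientation departing from its reference by > theta.

    The reference orientation is the per-subunit median C→O direction over
    the first replica.
    """
    try:
        ic = annotation.role_indices(role_c)
        io = annotation.role_indices(role_o)
    except AnnotationError as exc:
        raise AnnotationError(f"carbonyl roles missing: {exc}") from exc

    def co_unit(rep: Replica) -> np.ndarray:
        v = rep.coords[:, io] - rep.coords[:, ic]  # (F, S, 3)
        norm = np.linalg.norm(v, axis=-1, keepdims=True)
        if np.any(norm < 1e-12):
            raise AnnotationError("coincident carbonyl C and O atoms")
        return v / norm

    ref = co_unit(ensemble.replicas[0])
    ref_dir = np.median(ref, axis=0)  # (S, 3)
    norms = np.linalg.norm(ref_dir, axis=-1, keepdims=True)
    # A bimodal orientation mix collapses the component-wise median; fall
    # back to the first observed orientation for such subunits.
    degenerate = norms[:, 0] < 0.5
    if degenerate.any():
        ref_dir[degenerate] = ref[0, degenerate]
        norms = np.linalg.norm(ref_dir, axis=-1, keepdims=True)
    ref_dir = ref_dir / norms

    cos_thresh = np.cos(np.radians(theta_flip))
    flipped = []
    for rep in ensemble.replicas:
        u = co_unit(rep)
        cosang = np.einsum("fsd,sd->fs", u, ref_dir)
        flipped.append(cosang < cos_thresh)
    return FlipSeries(role=role_c, flipped=flipped, theta_flip=theta_flip)
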