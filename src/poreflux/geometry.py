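"""Order parameters: cross-subunit distances, contacts, helix bend, superposition."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnnotationError
from .trajio import ChannelAnnotation, Replica, TrajectoryEnsemble

__all__ = [
    "OrderParameterSeries",
    "opposite_pairs",
    "cross_distance",
    "cross_distance_series",
    "contact_distance",
    "contact_distance_series",
    "helix_bend",
    "superpose",
    "kabsch",
]


@dataclass
class OrderParameterSeries:
    name: str
    values: list[np.ndarray]  # one array per replica, one value per frame
    unit: str = "nm"

    def __post_init__(self) -> None:
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        for v in self.values:
            if not np.all(np.isfinite(v)):
                raise ValueError(f"series {self.name!r} contains non-finite values")

    @property
    def per_replica_mean(self) -> np.ndarray:
        return np.array([v.mean() for v in self.values])

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.values)


def opposite_pairs(points: np.ndarray) -> tuple[tuple[int, int], tuple[int, int]]:
    """Diagonal pairing of 4 subunit points: partner = farthest point.

    Determined once (typically from the first frame) and held fixed so that
    thermal noise cannot flip the pairing mid-series.
    """
    points = np.asarray(points, dtype=float)
    if points.shape != (4, 3):
        raise ValueError("opposite_pairs needs exactly 4 points")
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    # of the 3 perfect matchings, the diagonal one maximises the summed
    # pair distances for any convex quadrilateral
    matchings = (
        ((0, 1), (2, 3)),
        ((0, 2), (1, 3)),
        ((0, 3), (1, 2)),
    )
    return max(matchings, key=lambda m: d[m[0]] + d[m[1]])


def _role_points(frame: np.ndarray, annotation: ChannelAnnotation, role: str) -> np.ndarray:
    try:
        idx = annotation.role_indices(role)
    except AnnotationError:
        raise
    return frame[idx]


def cross_distance(
    frame: np.ndarray,
    annotation: ChannelAnnotation,
    role: str,
    mode: str = "opposite",
    pairing: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> float:
    """Cross-subunit distance for ``role`` atoms in one frame (nm).

    ``opposite``: mean of the two diagonal pair distances (tetramer; for a
    dimer the single pair).  ``adjacent``: mean of the four neighbour pairs.
    ``mean_all_pairs``: mean over all unordered pairs.
    """
    pts = _role_points(np.asarray(frame, dtype=float), annotation, role)
    n = len(pts)
    if n < 2:
        raise AnnotationError(f"role {role!r} needs >= 2 subunits")
    if n == 2:
        return float(np.linalg.norm(pts[0] - pts[1]))
    if mode == "mean_all_pairs":
        iu = np.triu_indices(n, k=1)
        return float(np.linalg.norm(pts[iu[0]] - pts[iu[1]], axis=1).mean())
    if pairing is None:
        pairing = opposite_pairs(pts)
    (a, b), (c, d) = pairing
    if mode == "opposite":
        return float(
            0.5 * (np.linalg.norm(pts[a] - pts[b]) + np.linalg.norm(pts[c] - pts[d]))
        )
    if mode == "adjacent":
        pairs = [(a, c), (c, b), (b, d), (d, a)]
        return float(np.mean([np.linalg.norm(pts[i] - pts[j]) for i, j in pairs]))
    raise ValueError(f"unknown mode {mode!r}")


def _series_over(ensemble, fn) -> list[np.ndarray]:
    replicas = ensemble.replicas if isinstance(ensemble, TrajectoryEnsemble) else [ensemble]
    return [np.array([fn(rep.coords[t]) for t in range(rep.n_frames)]) for rep in replicas]


def cross_distance_series(
    ensemble: TrajectoryEnsemble | Replica,
    annotation: ChannelAnnotation,
    role: str,
    mode: str = "opposite",
) -> OrderParameterSeries:
    """Per-frame cross distance; diagonal pairing fixed from the first frame."""
    replicas = ensemble.replicas if isinstance(ensemble, TrajectoryEnsemble) else [ensemble]
    idx = annotation.role_indices(role)
    pairing = None
    if len(idx) == 4:
        pairing = opposite_pairs(replicas[0].coords[0][idx])
    values = []
    for rep in replicas:
        pts = rep.coords[:, idx]  # (F, S, 3)
        if len(idx) == 2:
            v = np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1)
        elif mode == "mean_all_pairs":
            iu = np.triu_indices(len(idx), k=1)
            v = np.linalg.norm(pts[:, iu[0]] - pts[:, iu[1]], axis=-1).mean(axis=1)
        else:
            (a, b), (c, d) = pairing
            if mode == "opposite":
                v = 0.5 * (
                    np.linalg.norm(pts[:, a] - pts[:, b], axis=1)
                    + np.linalg.norm(pts[:, c] - pts[:, d], axis=1)
                )
            elif mode == "adjacent":
                pairs = [(a, c), (c, b), (b, d), (d, a)]
                v = np.mean(
                    [np.linalg.norm(pts[:, i] - pts[:, j], axis=1) for i, j in pairs], axis=0
                )
            else:
                raise ValueError(f"unknown mode {mode!r}")
        values.append(v)
    return OrderParameterSeries(name=f"{role}_{mode}", values=values)


def contact_distance(
    frame: np.ndarray,
    annotation: ChannelAnnotation,
    role_a: str,
    role_b: str,
) -> float:
    """Mean over subunits of the within-subunit role_a–role_b distance (nm)."""
    a = _role_points(np.asarray(frame, dtype=float), annotation, role_a)
    b = _role_points(np.asarray(frame, dtype=float), annotation, role_b)
    return float(np.linalg.norm(a - b, axis=1).mean())


def contact_distance_series(
    ensemble: TrajectoryEnsemble | Replica,
    annotation: ChannelAnnotation,
    role_a: str,
    role_b: str,
) -> OrderParameterSeries:
    ia = annotation.role_indices(role_a)
    ib = annotation.role_indices(role_b)
    replicas = ensemble.replicas if isinstance(ensemble, TrajectoryEnsemble) else [ensemble]
    values = [
        np.linalg.norm(rep.coords[:, ia] - rep.coords[:, ib], axis=-1).mean(axis=1)
        for rep in replicas
    ]
    return OrderParameterSeries(name=f"{role_a}-{role_b}", values=values)


def helix_bend(landmarks: np.ndarray) -> float:
    """Bend angle (degrees) from (n_subunits, 3, 3) start/hinge/end landmarks.

    Defined as 180° minus the angle at the hinge, averaged over subunits;
    a straight helix gives 0°.
    """
    landmarks = np.asarray(landmarks, dtype=float)
    if landmarks.ndim == 2:
        landmarks = landmarks[None]
    if landmarks.shape[1:] != (3, 3):
        raise ValueError("landmarks must have shape (n_subunits, 3, 3)")
    angles = []
    for start, hinge, end in landmarks:
        u = start - hinge
        v = end - hinge
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            raise ValueError("degenerate landmarks: coincident points")
        cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
        angles.append(180.0 - np.degrees(np.arccos(cosang)))
    return float(np.mean(angles))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimising |R·mobile + t − reference|.

    Reflections are excluded (det(R) = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    a = mobile - cm
    b = reference - cr
    if len(a) < 3 or np.linalg.matrix_rank(a, tol=1e-10) < 2:
        raise ValueError("need >= 3 non-collinear fit atoms")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cr - rot @ cm
    return rot, t


def superpose(
    coords: np.ndarray,
    reference: np.ndarray,
    fit_atoms: np.ndarray | None = None,
) -> np.ndarray:
    """Rigid-body least-squares fit of one frame (or a stack) onto a reference.

    ``fit_atoms`` restricts the fit to a subset of atom indices; the full
    coordinate set is transformed.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    single = coords.ndim == 2
    frames = coords[None] if single else coords
    fit = np.arange(frames.shape[1]) if fit_atoms is None else np.asarray(fit_atoms, dtype=int)
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        rot, t = kabsch(frame[fit], reference[fit])
        out[i] = frame @ rot.T + t
    return out[0] if single else out


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))
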