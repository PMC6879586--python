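"""Partial-least-squares functional mode analysis (PLS-FMA).

Finds the collective coordinate motion maximally correlated with a scalar
order parameter, reports the maximally correlated mode (MCM) and its
ensemble-weighted variant (ewMCM, covariance-projected regression vector),
with a contiguous half/half train–validation split and a PCA comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import superpose
from .trajio import TrajectoryEnsemble

__all__ = [
    "CollectiveMode",
    "fit_pls_fma",
    "cross_validate",
    "interpolate_mode",
    "pca_modes",
]


@dataclass
class CollectiveMode:
    mean_structure: np.ndarray  # (atoms, 3) train-set mean of superposed coords
    mcm: np.ndarray  # (3M,) unit vector, beta direction
    ewmcm: np.ndarray  # (3M,) unit vector, C @ beta direction
    beta: np.ndarray  # (3M,) regression vector
    y_mean: float
    n_components: int
    r_train: float
    r_valid: float
    proj_min: float
    proj_max: float

    def __post_init__(self) -> None:
        for v, name in ((self.mcm, "mcm"), (self.ewmcm, "ewmcm")):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError(f"{name} must be unit-norm")
        for r in (self.r_train, self.r_valid):
            if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
                raise ValueError("correlations must lie in [-1, 1]")


def _as_xy(ensemble, target) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Flatten an ensemble + target into (X (F,3M), y (F,), replica frame counts)."""
    if isinstance(ensemble, TrajectoryEnsemble):
        coords = np.concatenate([r.coords for r in ensemble.replicas], axis=0)
        counts = [r.n_frames for r in ensemble.replicas]
    else:
        coords = np.asarray(ensemble, dtype=float)
        counts = [coords.shape[0]]
    if hasattr(target, "concatenated"):
        y = target.concatenated
    else:
        y = np.asarray(target, dtype=float).ravel()
    if coords.shape[0] != y.size:
        raise ValueError("target length must equal total frame count")
    return coords, y, counts


def _split_contiguous(counts: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """First half of each replica → train, second half → validation."""
    train, valid = [], []
    offset = 0
    for n in counts:
        half = n // 2
        train.extend(range(offset, offset + half))
        valid.extend(range(offset + half, offset + n))
        offset += n
    return np.asarray(train), np.asarray(valid)


def _pls1(X: np.ndarray, y: np.ndarray, k: int, tol: float = 1e-12, max_iter: int = 500):
    """PLS1 (NIPALS) on centred X, y; returns the regression vector beta.

    Deterministic: each component's weight vector starts from X^T y.  Stops
    early when the remaining X or y variance is numerically exhausted.
    """
    Xd = X.copy()
    yd = y.copy()
    W, P, Q = [], [], []
    for _ in range(k):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < tol:
            break
        w = w / nw
        # For a univariate response NIPALS converges in one pass; iterate to
        # the stated tolerance anyway for numerical symmetry.
        for _ in range(max_iter):
            t_scores = Xd @ w
            tt = t_scores @ t_scores
            if tt < tol:
                break
            w_new = Xd.T @ yd
            n_new = np.linalg.norm(w_new)
            if n_new < tol:
                break
            w_new /= n_new
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t_scores = Xd @ w
        tt = t_scores @ t_scores
        if tt < tol:
            break
        p = Xd.T @ t_scores / tt
        q = (yd @ t_scores) / tt
        Xd = Xd - np.outer(t_scores, p)
        yd = yd - q * t_scores
        W.append(w)
        P.append(p)
        Q.append(q)
    if not W:
        raise ValueError("target has no covariance with the coordinates")
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.asarray(Q)
    beta = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
    return beta, len(W)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.clip(a @ b / denom, -1.0, 1.0))


def fit_pls_fma(
    ensemble,
    target,
    n_components: int = 30,
    split: str = "contiguous_half",
    do_superpose: bool = True,
) -> CollectiveMode:
    """Fit the PLS-FMA model and extract MCM/ewMCM.

    ``ensemble`` is a :class:`TrajectoryEnsemble` or a (frames, atoms, 3)
    array; ``target`` an :class:`~poreflux.geometry.OrderParameterSeries` or
    a flat array.  Frames are rigid-body superposed onto their mean before
    the regression.  Training uses the first half of each replica's frames;
    the second half is reserved for validation.
    """
    coords, y, counts = _as_xy(ensemble, target)
    n_frames, n_atoms, _ = coords.shape
    if np.std(y) == 0:
        raise ValueError("target is constant (zero variance)")
    if split != "contiguous_half":
        raise ValueError("only the contiguous_half split is implemented")
    train_ix, valid_ix = _split_contiguous(counts)
    if len(train_ix) < 10 or len(valid_ix) < 10:
        raise ValueError("need at least 10 frames in each half")

    if do_superpose:
        mean = coords.mean(axis=0)
        coords = superpose(coords, mean)
        mean = coords.mean(axis=0)
        coords = superpose(coords, mean)

    X = coords.reshape(n_frames, 3 * n_atoms)
    x_mean = X[train_ix].mean(axis=0)
    y_mean = float(y[train_ix].mean())
    Xc = X[train_ix] - x_mean
    yc = y[train_ix] - y_mean

    rank = min(Xc.shape)
    k = n_components
    if k > rank:
        warnings.warn(
            f"n_components={n_components} exceeds data rank {rank}; reduced", stacklevel=2
        )
        k = rank
    beta, k_used = _pls1(Xc, yc, k)

    mcm = beta / np.linalg.norm(beta)
    # ewMCM: ensemble covariance applied to beta, computed without forming C
    ew = Xc.T @ (Xc @ beta) / max(len(train_ix) - 1, 1)
    ew_norm = np.linalg.norm(ew)
    if ew_norm < 1e-300:
        raise ValueError("degenerate covariance projection")
    ewmcm = ew / ew_norm

    y_hat = (X - x_mean) @ beta + y_mean
    r_train = _pearson(y_hat[train_ix], y[train_ix])
    r_valid = _pearson(y_hat[valid_ix], y[valid_ix])

    # Orient the ewMCM so increasing projection increases the target.
    proj = (X - x_mean) @ ewmcm
    if _pearson(proj[train_ix], y[train_ix]) < 0:
        ewmcm = -ewmcm
        proj = -proj

    return CollectiveMode(
        mean_structure=x_mean.reshape(n_atoms, 3),
        mcm=mcm,
        ewmcm=ewmcm,
        beta=beta,
        y_mean=y_mean,
        n_components=k_used,
        r_train=r_train,
        r_valid=r_valid,
        proj_min=float(proj.min()),
        proj_max=float(proj.max()),
    )


def cross_validate(mode: CollectiveMode, ensemble, target) -> tuple[float, float]:
    """Re-evaluate a fitted mode: Pearson r of model vs target on each half.

    Validation frames never touch the fit; the model prediction uses only
    the training-set means stored in the mode.
    """
    coords, y, counts = _as_xy(ensemble, target)
    train_ix, valid_ix = _split_contiguous(counts)
    if len(train_ix) < 10 or len(valid_ix) < 10:
        raise ValueError("need at least 10 frames in each half")
    mean = coords.mean(axis=0)
    coords = superpose(coords, mean)
    mean = coords.mean(axis=0)
    coords = superpose(coords, mean)
    X = coords.reshape(coords.shape[0], -1)
    y_hat = (X - mode.mean_structure.reshape(-1)) @ mode.beta + mode.y_mean
    return _pearson(y_hat[train_ix], y[train_ix]), _pearson(y_hat[valid_ix], y[valid_ix])


def interpolate_mode(mode: CollectiveMode, n_structures: int = 21) -> np.ndarray:
    """Structures mean + α·ewMCM for α spanning the observed projection range.

    Returns (n_structures, atoms, 3); the end structures sit exactly at the
    minimum and maximum observed frame projections.
    """
    if n_structures < 2:
        raise ValueError("need at least 2 interpolation structures")
    alphas = np.linspace(mode.proj_min, mode.proj_max, n_structures)
    flat = mode.mean_structure.reshape(-1)[None, :] + alphas[:, None] * mode.ewmcm[None, :]
    return flat.reshape(n_structures, *mode.mean_structure.shape)


def pca_modes(ensemble, n_modes: int, do_superpose: bool = True):
    """PCA of superposed coordinates.

    Returns (modes (n_modes, 3M) unit-norm, eigenvalues (min(F−1, 3M),)
    non-increasing, mean structure (atoms, 3)).
    """
    if isinstance(ensemble, TrajectoryEnsemble):
        coords = np.concatenate([r.coords for r in ensemble.replicas], axis=0)
    else:
        coords = np.asarray(ensemble, dtype=float)
    n_frames, n_atoms, _ = coords.shape
    if n_modes > 3 * n_atoms:
        raise ValueError("n_modes exceeds coordinate dimensionality")
    if do_superpose:
        mean = coords.mean(axis=0)
        coords = superpose(coords, mean)
        mean = coords.mean(axis=0)
        coords = superpose(coords, mean)
    X = coords.reshape(n_frames, -1)
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n_frames - 1)
    return vt[:n_modes], eigvals, X.mean(axis=0).reshape(n_atoms, 3)
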