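"""Replica-level resampling statistics.

All confidence intervals in the package funnel through two primitives:

* :func:`bootstrap_ci` — percentile bootstrap over *replicas* (never over
  frames, which are autocorrelated),
* :func:`coverage_ci` — Student-t coverage-factor half-width of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["BootstrapResult", "bootstrap_ci", "coverage_ci"]


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    level: float
    seed: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


def bootstrap_ci(
    per_replica_values: Sequence[float] | np.ndarray,
    statistic: Callable[[np.ndarray], float] | None = None,
    n_boot: int = 20_000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap CI of ``statistic`` over replica-level values.

    Replicas are resampled with replacement ``n_boot`` times; the CI is the
    percentile interval of the resampled statistics.  Deterministic for a
    fixed ``seed``.
    """
    values = np.asarray(per_replica_values, dtype=float)
    if values.ndim != 1:
        raise ValueError("per_replica_values must be one-dimensional")
    n = values.size
    if n < 2:
        raise ValueError("bootstrap_ci requires at least 2 replicas")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    resampled = values[idx]
    if statistic is None or statistic is np.mean:
        stat_fn: Callable[[np.ndarray], float] = np.mean
        boot = resampled.mean(axis=1)
    else:
        stat_fn = statistic
        boot = np.apply_along_axis(statistic, 1, resampled)

    alpha = (1.0 - level) / 2.0
    ci_low, ci_high = np.quantile(boot, [alpha, 1.0 - alpha])
    return BootstrapResult(
        estimate=float(stat_fn(values)),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        level=level,
        seed=seed,
    )


def coverage_ci(values: Sequence[float] | np.ndarray, level: float = 0.95) -> float:
    """Coverage-factor half-width: t-quantile(level, n-1) × SEM."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    n = values.size
    if n < 2:
        raise ValueError("coverage_ci requires at least 2 values")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    sem = values.std(ddof=1) / np.sqrt(n)
    t = sps.t.ppf(0.5 + level / 2.0, df=n - 1)
    return float(t * sem)
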