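"""Preliminary-campaign screening simulation.

European workplace-measurement strategy (EN 689) allows a short
preliminary campaign - a few measured days - to decide whether further
measurement is needed.  When ceiling-value exceedances occur on only a
small fraction of workdays, such a campaign will usually miss them.
This module estimates the probability that a k-day campaign observes at
least one exceedance day, both by seeded resampling from an empirical
day pool and in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np


@dataclass(frozen=True)
class ScreeningConfig:
    """Campaign resampling parameters (defaults: 100 draws of 3 days)."""

    k_days: int = 3
    n_draws: int = 100
    replacement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_days < 1 or self.n_draws < 1:
            raise ValueError("k_days and n_draws must be >= 1")


@dataclass(frozen=True)
class ScreeningResult:
    detect_fraction: float
    analytic_prob: float
    n_population: int
    n_positive: int
    k_days: int
    n_draws: int
    seed: int


def analytic_detection_prob(
    n_positive: int, n_population: int, k: int, replacement: bool = False
) -> float:
    """Probability that a k-day sample contains >= 1 flagged day.

    With replacement ``1 - (1 - p)^k``; without replacement the
    hypergeometric complement ``1 - C(n-x, k) / C(n, k)``.
    """
    if not (0 <= n_positive <= n_population):
        raise ValueError("need 0 <= n_positive <= n_population")
    if k < 1:
        raise ValueError("k must be >= 1")
    if replacement:
        p = n_positive / n_population
        return 1.0 - (1.0 - p) ** k
    if k > n_population:
        raise ValueError("k exceeds population without replacement")
    if n_positive == 0:
        return 0.0
    if k > n_population - n_positive:
        return 1.0
    return 1.0 - comb(n_population - n_positive, k) / comb(n_population, k)


def _distinct_draws(rng: np.random.Generator, n: int, k: int, n_draws: int) -> np.ndarray:
    """Uniform distinct k-subsets as an (n_draws, k) index array.

    Rejection-samples rows with duplicate indices, which is cheap for
    k << n and leaves the distribution uniform over distinct tuples.
    """
    idx = rng.integers(0, n, size=(n_draws, k))
    while True:
        dup = (np.sort(idx, axis=1)[:, 1:] == np.sort(idx, axis=1)[:, :-1]).any(axis=1)
        if not dup.any():
            return idx
        idx[dup] = rng.integers(0, n, size=(int(dup.sum()), k))


def simulate_detection_rate(day_flags, cfg: ScreeningConfig = ScreeningConfig()) -> ScreeningResult:
    """Resample k-day campaigns from a pool of exceedance flags.

    Repeats ``n_draws`` times: draw ``k_days`` days (distinct workdays by
    default) and record whether any is flagged.  Reproducible under
    ``cfg.seed``.
    """
    flags = np.asarray(day_flags, dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError("empty day population")
    if not cfg.replacement and cfg.k_days > n:
        raise ValueError("k_days exceeds population without replacement")
    rng = np.random.default_rng(cfg.seed)
    if cfg.replacement:
        idx = rng.integers(0, n, size=(cfg.n_draws, cfg.k_days))
    else:
        idx = _distinct_draws(rng, n, cfg.k_days, cfg.n_draws)
    detected = flags[idx].any(axis=1)
    n_positive = int(flags.sum())
    return ScreeningResult(
        detect_fraction=float(detected.mean()),
        analytic_prob=analytic_detection_prob(n_positive, n, cfg.k_days, cfg.replacement),
        n_population=n,
        n_positive=n_positive,
        k_days=cfg.k_days,
        n_draws=cfg.n_draws,
        seed=cfg.seed,
    )
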