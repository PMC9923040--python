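"""Statistics for heavily left-censored day-level exposure data.

Over 80% of person-days in this kind of cohort carry no detectable
reading, so ordinary location/scale summaries are dominated by the
censored mass.  The tools here make the censoring explicit: a censored
ECDF that stacks the non-detect mass at the LOD, rank tests run with and
without non-detects (ties at zero), Beta-Binomial contrasts of
exceedance proportions, a nested logistic-regression decomposition of
detection probability into SEG and worker components, and lag-1
autocorrelation of day series under different imputation schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from statsmodels.stats.diagnostic import lilliefors

from .day_assembly import WorkdayGrid


@dataclass
class CensoredSample:
    """Values with parallel left/right censoring flags."""

    values: np.ndarray
    lod: float = 1.6
    overload_code: float = 101.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def censored_below(self) -> np.ndarray:
        return self.values < self.lod

    @property
    def censored_above(self) -> np.ndarray:
        return self.values >= self.overload_code


class CensoredEcdf:
    """Step function of cumulative fractions with a censored block at the LOD."""

    def __init__(self, x: np.ndarray, f: np.ndarray, frac_censored: float):
        self.x = x
        self.f = f
        self.frac_censored = frac_censored

    def __call__(self, q) -> np.ndarray:
        idx = np.searchsorted(self.x, np.asarray(q, dtype=float), side="right")
        out = np.where(idx == 0, 0.0, self.f[np.maximum(idx - 1, 0)])
        return out if out.ndim else float(out)


def cen_ecdf(sample: CensoredSample) -> CensoredEcdf:
    """Censored empirical CDF.

    Below-LOD observations are represented as a single block of mass at
    the LOD (their true values are unknown but bounded above by it); the
    function is nondecreasing and reaches 1 at the sample maximum.
    """
    v = sample.values
    if v.size == 0:
        raise ValueError("empty sample")
    shown = np.where(sample.censored_below, sample.lod, v)
    xs, counts = np.unique(shown, return_counts=True)
    f = np.cumsum(counts) / v.size
    return CensoredEcdf(xs, f, float(sample.censored_below.mean()))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_groups: int
    includes_nondetects: bool


def group_location_test(
    groups, include_nondetects: bool = True, lod: float = 1.6, detect_flags=None
) -> TestResult:
    """Kruskal-Wallis rank test across SEG-level samples.

    With ``include_nondetects`` non-detect days enter as ties at 0 (the
    coded non-detect value); without, they are dropped first.  Whether an
    observation is a non-detect comes from ``detect_flags`` (parallel
    boolean arrays, needed when the tested metric - e.g. TWA - is not
    itself on the LOD scale) or, by default, from ``value >= lod``.
    Ties are corrected in the H statistic; p comes from the chi-square
    approximation.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if detect_flags is None:
        detect_flags = [a >= lod for a in arrays]
    else:
        detect_flags = [np.asarray(f, dtype=bool) for f in detect_flags]
        if [f.size for f in detect_flags] != [a.size for a in arrays]:
            raise ValueError("detect_flags must parallel the groups")
    if include_nondetects:
        arrays = [np.where(f, a, 0.0) for a, f in zip(arrays, detect_flags)]
    else:
        arrays = [a[f] for a, f in zip(arrays, detect_flags)]
    if any(a.size == 0 for a in arrays):
        raise ValueError("a group is empty after filtering non-detects")
    h, p = stats.kruskal(*arrays)
    return TestResult(float(h), float(p), len(arrays), include_nondetects)


@dataclass(frozen=True)
class NormalityResult:
    ks: TestResult
    shapiro: TestResult
    rejected: bool
    log_transformed: bool


def normality_checks(sample, log_transform: bool = False, alpha: float = 0.05) -> NormalityResult:
    """Kolmogorov-Smirnov (Lilliefors) and Shapiro-Wilk normality tests.

    With ``log_transform`` the tests address log-normality and require
    strictly positive values.  The distribution is declared non-normal
    when either test rejects at ``alpha``.  Degenerate (constant or
    n < 3) samples are an error.
    """
    v = np.asarray(sample, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    if log_transform:
        if np.any(v <= 0):
            raise ValueError("log transform requires positive values")
        v = np.log(v)
    if np.ptp(v) == 0:
        raise ValueError("constant sample: normality tests are degenerate")
    ks_stat, ks_p = lilliefors(v, dist="norm")
    sw_stat, sw_p = stats.shapiro(v)
    ks = TestResult(float(ks_stat), float(ks_p), 1, True)
    sw = TestResult(float(sw_stat), float(sw_p), 1, True)
    return NormalityResult(ks, sw, rejected=(ks_p < alpha or sw_p < alpha),
                           log_transformed=log_transform)


@dataclass(frozen=True)
class ProportionContrast:
    seg_a: str
    seg_b: str
    x_a: int
    n_a: int
    x_b: int
    n_b: int
    ci95: tuple[float, float]
    differs: bool


def bayes_prop_diff(
    x_a: int,
    n_a: int,
    x_b: int,
    n_b: int,
    prior: tuple[float, float] = (1.0, 1.0),
    n_mc: int = 20_000,
    seed: int = 0,
    seg_a: str = "A",
    seg_b: str = "B",
) -> ProportionContrast:
    """Bayesian contrast of two exceedance proportions.

    Independent Beta(a + x, b + n - x) posteriors are sampled; the 95%
    credible interval of p_a - p_b is the 2.5/97.5 Monte Carlo
    percentiles and the groups "differ" when 0 lies outside it.  The
    default flat Beta(1,1) prior can be swapped for Jeffreys (0.5, 0.5).
    """
    if not (0 <= x_a <= n_a and 0 <= x_b <= n_b):
        raise ValueError("need 0 <= x <= n for both groups")
    a, b = prior
    rng = np.random.default_rng(seed)
    pa = rng.beta(a + x_a, b + n_a - x_a, size=n_mc)
    pb = rng.beta(a + x_b, b + n_b - x_b, size=n_mc)
    lo, hi = np.percentile(pa - pb, [2.5, 97.5])
    return ProportionContrast(
        seg_a, seg_b, x_a, n_a, x_b, n_b, (float(lo), float(hi)),
        differs=not (lo <= 0.0 <= hi),
    )


def pairwise_prop_contrasts(
    counts: dict[str, tuple[int, int]], **kwargs
) -> list[ProportionContrast]:
    """All pairwise contrasts from a mapping ``seg -> (x, n)``."""
    segs = list(counts)
    out = []
    for i, sa in enumerate(segs):
        for sb in segs[i + 1 :]:
            out.append(
                bayes_prop_diff(*counts[sa], *counts[sb], seg_a=sa, seg_b=sb, **kwargs)
            )
    return out


@dataclass(frozen=True)
class ModelComparison:
    model: str
    minus2_loglik: float
    df: int


@dataclass(frozen=True)
class VarianceDecomposition:
    models: tuple[ModelComparison, ...]
    p_worker_vs_seg: float
    p_seg_added_to_worker: float
    within_worker_dominates: bool

    def minus2ll(self, model: str) -> float:
        return next(m.minus2_loglik for m in self.models if m.model == model)


def _fit_logistic(y: np.ndarray, x: np.ndarray, ridge: float) -> tuple[float, int]:
    """Ridge-penalised logistic fit; returns (-2 log L, rank of design)."""
    design = np.column_stack([np.ones(len(y)), x])
    df = int(np.linalg.matrix_rank(design))
    model = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=5000, tol=1e-10)
    model.fit(x, y)
    p = model.predict_proba(x)[:, 1]
    return 2.0 * float(log_loss(y, p, normalize=False)), df


def logistic_variance_decomposition(
    frame: pd.DataFrame,
    outcome: str = "above_lod",
    seg: str = "seg",
    worker: str = "person_id",
    ridge: float = 1e-3,
    alpha: float = 0.05,
) -> VarianceDecomposition:
    """Nested logistic models of the detection indicator.

    Fits worker-only, SEG-only and SEG+worker models of P(day above LOD)
    and compares them by -2 log likelihood.  A small fixed L2 (ridge)
    penalty keeps workers with all-negative (or all-positive) runs -
    complete separation - at finite coefficients; the reported -2LL is
    the unpenalised deviance of the fitted probabilities.  Since each
    worker belongs to one SEG, the SEG design is nested in the worker
    design and SEG+worker coincides with the worker model up to rank.

    "Within-worker dominates" when the worker model significantly beats
    the SEG model (chi-square on the -2LL drop) while adding SEG to the
    worker model gains nothing at ``alpha``.
    """
    y = frame[outcome].to_numpy(dtype=float)
    if frame[seg].nunique() < 2 or frame[worker].nunique() < 2:
        raise ValueError("need at least 2 SEGs and 2 workers")
    x_seg = pd.get_dummies(frame[seg], drop_first=True).to_numpy(dtype=float)
    x_worker = pd.get_dummies(frame[worker], drop_first=True).to_numpy(dtype=float)
    x_both = np.column_stack([x_seg, x_worker])

    m2_seg, df_seg = _fit_logistic(y, x_seg, ridge)
    m2_worker, df_worker = _fit_logistic(y, x_worker, ridge)
    m2_both, df_both = _fit_logistic(y, x_both, ridge)

    d_ws = max(0.0, m2_seg - m2_worker)
    df_ws = df_worker - df_seg
    p_ws = float(stats.chi2.sf(d_ws, df_ws)) if df_ws > 0 else 1.0
    d_add = max(0.0, m2_worker - m2_both)
    df_add = df_both - df_worker
    p_add = float(stats.chi2.sf(d_add, df_add)) if df_add > 0 else 1.0

    return VarianceDecomposition(
        models=(
            ModelComparison("seg", m2_seg, df_seg),
            ModelComparison("worker", m2_worker, df_worker),
            ModelComparison("seg_plus_worker", m2_both, df_both),
        ),
        p_worker_vs_seg=p_ws,
        p_seg_added_to_worker=p_add,
        within_worker_dominates=(p_ws < alpha and p_add >= alpha and m2_worker < m2_seg),
    )


def acf_lag1(grid: WorkdayGrid) -> float:
    """Lag-1 Pearson correlation over within-person consecutive grid days.

    Pairs are adjacent entries of each person's ordered grid; pairs never
    span persons.  Returns NaN (missing) for a constant series; fewer
    than 2 pairs is an error.
    """
    xs, ys = [], []
    for _, g in grid.frame.groupby("person_id", sort=True):
        v = g.sort_values("date")["value"].to_numpy(dtype=float)
        if v.size >= 2:
            xs.append(v[:-1])
            ys.append(v[1:])
    if not xs:
        raise ValueError("fewer than 2 consecutive-day pairs")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 2:
        raise ValueError("fewer than 2 consecutive-day pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
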