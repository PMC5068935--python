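"""Germination time-course analysis.

Cumulative germination curves, four-parameter Hill function (4PHF) fits,
t50 extraction, stage-schedule t-tests from summary statistics, and the
genotype x environment two-way ANOVA on replicate t50 values.

The 4PHF is ``g(t) = y0 + a * t^b / (c^b + t^b)``: baseline fraction ``y0``,
asymptote increment ``a``, shape ``b`` (steepness), and half-rise time ``c``
(hours).  For ``a, b, c > 0`` the curve is non-decreasing in t, so a
converged fit is automatically a valid cumulative curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GerminationRecord",
    "HillFit",
    "StageTiming",
    "TTestResult",
    "AnovaResult",
    "hill",
    "build_cumulative_curve",
    "fit_4phf",
    "t50_from_fit",
    "stage_ttest",
    "two_way_anova",
]


@dataclass
class GerminationRecord:
    """Cumulative germination counts for one accession/replicate/environment."""

    accession: str
    environment: str
    replicate: str | int
    times: np.ndarray  # hours, strictly increasing
    cumulative_counts: np.ndarray
    total_seeds: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_counts = np.asarray(self.cumulative_counts, dtype=float)
        if self.times.shape != self.cumulative_counts.shape:
            raise ValueError("times and counts must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.cumulative_counts) < 0):
            raise ValueError("cumulative counts must be non-decreasing")
        if self.cumulative_counts[-1] > self.total_seeds:
            raise ValueError("cumulative count exceeds total seeds")

    @property
    def fractions(self) -> np.ndarray:
        return self.cumulative_counts / self.total_seeds


@dataclass
class HillFit:
    y0: float
    a: float
    b: float
    c: float
    converged: bool
    rss: float
    degenerate: bool = False

    @property
    def t50(self) -> float:
        """Relative-mode t50 (time to half the fitted rise) — equals c."""
        return self.c


@dataclass(frozen=True)
class StageTiming:
    """Summary timing of one germination stage (testa rupture, radicle
    protrusion, cotyledon greening or cotyledon expansion)."""

    stage: str
    accession: str
    environment: str
    mean_hours: float
    sd_hours: float
    n: int

    def __post_init__(self) -> None:
        if self.sd_hours < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("need n >= 2 replicates")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    f_genotype: float
    f_environment: float
    f_interaction: float
    p_genotype: float
    p_environment: float
    p_interaction: float


def hill(t, y0: float, a: float, b: float, c: float):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tb = np.where(t > 0, t, 0.0) ** b
        out = y0 + a * tb / (c**b + tb)
    return np.where(t <= 0, y0, out)


def build_cumulative_curve(
    times,
    interval_counts,
    total_seeds: int,
    accession: str = "",
    environment: str = "",
    replicate: str | int = 0,
) -> GerminationRecord:
    """Turn per-interval germinant counts into a cumulative record.

    ``interval_counts[i]`` is the number of germinants newly scored (and
    removed) at ``times[i]``.
    """
    counts = np.asarray(interval_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("interval counts must be >= 0")
    cum = np.cumsum(counts)
    if cum[-1] > total_seeds:
        raise ValueError("cumulative count exceeds total seeds")
    return GerminationRecord(
        accession=accession,
        environment=environment,
        replicate=replicate,
        times=np.asarray(times, dtype=float),
        cumulative_counts=cum,
        total_seeds=total_seeds,
    )


_DEGENERATE_SPREAD = 1e-9


def fit_4phf(times, fractions=None, max_iter: int = 100) -> HillFit:
    """Least-squares 4PHF fit of a cumulative germination curve.

    Accepts a :class:`GerminationRecord` or ``(times, fractions)`` arrays.
    Bounded least squares (a, b, c > 0; 0 <= y0) with at most ``max_iter``
    function evaluations; hitting the cap clears ``converged`` rather than
    raising.  Initialisation: y0 from the curve minimum, a from the observed
    rise, c from the earliest half-rise crossing, b = 2.
    """
    if isinstance(times, GerminationRecord):
        rec = times
        times, fractions = rec.times, rec.fractions
    t = np.asarray(times, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    if t.size != y.size:
        raise ValueError("times and fractions must align")
    rise = float(y.max() - y.min())
    if rise < _DEGENERATE_SPREAD:
        # flat curve: nothing to fit
        return HillFit(
            y0=float(y.min()), a=0.0, b=np.nan, c=np.nan,
            converged=False, rss=0.0, degenerate=True,
        )
    y0_0 = float(y.min())
    a_0 = rise
    half = y0_0 + a_0 / 2.0
    above = np.flatnonzero(y >= half)
    c_0 = float(t[above[0]]) if above.size else float(np.median(t))
    c_0 = max(c_0, 1e-6)
    x0 = np.array([y0_0, a_0, 2.0, c_0])
    lb = np.array([0.0, 1e-9, 1e-9, 1e-9])
    ub = np.array([1.0, 1.0, np.inf, np.inf])
    x0 = np.clip(x0, lb + 1e-12, np.where(np.isfinite(ub), ub - 1e-12, x0))
    res = optimize.least_squares(
        lambda p: hill(t, *p) - y,
        x0,
        bounds=(lb, ub),
        max_nfev=max_iter,
        ftol=1e-8,
        xtol=1e-12,
        gtol=1e-12,
    )
    converged = bool(res.status > 0)
    y0f, af, bf, cf = res.x
    return HillFit(
        y0=float(y0f), a=float(af), b=float(bf), c=float(cf),
        converged=converged, rss=float(2.0 * res.cost),
    )


def t50_from_fit(fit: HillFit, mode: str = "relative") -> float | None:
    """Time to 50% germination from a converged 4PHF fit.

    ``relative``: time at half the fitted rise (g = y0 + a/2), which is c.
    ``absolute``: time at g = 0.5 of total seeds; ``None`` when the fitted
    asymptote never reaches 50%.
    """
    if fit.degenerate or not fit.converged:
        raise ValueError("t50 requires a converged, non-degenerate fit")
    if mode == "relative":
        return float(fit.c)
    if mode == "absolute":
        if fit.y0 + fit.a < 0.5:
            return None
        if fit.y0 >= 0.5:
            return 0.0
        return float(fit.c * ((0.5 - fit.y0) / (fit.y0 + fit.a - 0.5)) ** (1.0 / fit.b))
    raise ValueError(f"unknown t50 mode {mode!r}")


def stage_ttest(x: StageTiming, y: StageTiming) -> TTestResult:
    """Pooled-variance two-sided two-sample t-test from summary statistics.

    sp^2 = ((n_x-1) s_x^2 + (n_y-1) s_y^2) / (n_x + n_y - 2), df = n_x+n_y-2.
    The equal-variance form is what reproduces the published stage-schedule
    p-values from triplicate means/SDs.
    """
    if x.stage != y.stage or x.environment != y.environment:
        raise ValueError("t-test requires matching stage and environment")
    df = x.n + y.n - 2
    sp2 = ((x.n - 1) * x.sd_hours**2 + (y.n - 1) * y.sd_hours**2) / df
    if sp2 == 0.0:
        if x.mean_hours == y.mean_hours:
            return TTestResult(t=0.0, df=df, p=1.0)
        warnings.warn("zero pooled variance with unequal means")
        return TTestResult(t=np.inf, df=df, p=0.0)
    t, p = stats.ttest_ind_from_stats(
        x.mean_hours, x.sd_hours, x.n, y.mean_hours, y.sd_hours, y.n, equal_var=True
    )
    return TTestResult(t=float(t), df=df, p=float(p))


def two_way_anova(data: pd.DataFrame) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction on a balanced 2x2 design.

    ``data`` needs columns ``value``, ``genotype``, ``environment`` with two
    levels each and an equal number (>= 2) of replicates per cell.  In the
    balanced case all sum-of-squares types coincide.
    """
    for col in ("value", "genotype", "environment"):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    if data["value"].isna().any():
        raise ValueError("NaN responses not allowed in a balanced design")
    cells = data.groupby(["genotype", "environment"], sort=True).size()
    if len(cells) != 4 or cells.nunique() != 1:
        raise ValueError("design must be a balanced 2x2 layout")
    if cells.iloc[0] < 2:
        raise ValueError("need >= 2 replicates per cell")
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("value ~ C(genotype) * C(environment)", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual designs emit RuntimeWarnings
        tab = sm.stats.anova_lm(model, typ=2)

    def _fp(row: str) -> tuple[float, float]:
        f = float(tab.loc[row, "F"])
        p = float(tab.loc[row, "PR(>F)"])
        ss = float(tab.loc[row, "sum_sq"])
        resid = float(tab.loc["Residual", "sum_sq"])
        if resid <= 1e-12 * max(1.0, abs(float(data["value"].mean()))):
            # degenerate: no within-cell variance
            if ss <= 1e-12:
                return 0.0, 1.0
            return np.inf, 0.0
        return f, p

    fg, pg = _fp("C(genotype)")
    fe, pe = _fp("C(environment)")
    fi, pi = _fp("C(genotype):C(environment)")
    return AnovaResult(
        f_genotype=fg, f_environment=fe, f_interaction=fi,
        p_genotype=pg, p_environment=pe, p_interaction=pi,
    )
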