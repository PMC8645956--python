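"""Nonparametric statistics reproducing SPSS reporting conventions.

The study's statistical layer: median (IQR) summaries, the paired Wilcoxon
signed-rank test with *asymptotic* two-sided significance, and Spearman rank
correlation with the t-approximation p-value.  Conventions follow the named
software exactly:

* Wilcoxon — zero differences dropped, midranks for tied |d|, tie-corrected
  normal variance n(n+1)(2n+1)/24 − Σ(t³−t)/48, no continuity correction,
  p = 2·(1 − Φ(|Z|)).
* Spearman — rho is the Pearson correlation of midranks (equal to the
  6Σd² formula when untied); p from t = rho·sqrt((n−2)/(1−rho²)) on n−2 df.
* Percentiles — weighted-average (HAVERAGE) convention, position (n+1)·p.

These are implemented explicitly (the convention itself is what downstream
results depend on); scipy's equivalents serve only as cross-checks in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, t as t_dist

__all__ = [
    "PairedSample",
    "WilcoxonResult",
    "SpearmanResult",
    "median_iqr",
    "wilcoxon_asymptotic",
    "spearman",
    "correlation_panel",
]


@dataclass
class PairedSample:
    """Matched observations at two conditions, paired by subject id."""

    ids: list
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.ids) == self.a.size == self.b.size):
            raise ValueError("ids, a, b must have equal length")
        if self.a.size < 2:
            raise ValueError("need n >= 2 pairs")


@dataclass
class WilcoxonResult:
    n: int          # pairs used after dropping zero differences
    W_plus: float   # sum of positive-difference ranks
    W_minus: float
    Z: float
    p: float        # asymptotic two-sided


@dataclass
class SpearmanResult:
    rho: float
    n: int
    t: float
    p: float
    flags: tuple = ()


def median_iqr(values, method: str = "weighted_average") -> tuple[float, float]:
    """Median and IQR (Q3 − Q1).

    ``weighted_average`` uses the (n+1)·p percentile position (the HAVERAGE
    convention of the reporting software); ``linear`` uses the common
    sample-quantile interpolation.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    np_method = {"weighted_average": "weibull", "linear": "linear"}[method]
    q1, q3 = np.quantile(x, [0.25, 0.75], method=np_method)
    return float(np.median(x)), float(q3 - q1)


def wilcoxon_asymptotic(sample: PairedSample) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test, asymptotic two-sided p.

    Differences b − a; zeros dropped; midranks on |d| with the tie-corrected
    normal approximation and no continuity correction.
    """
    d = sample.b - sample.a
    d = d[d != 0]
    n = d.size
    if n < 1:
        raise ValueError("all differences are zero; test unavailable")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= float(((counts**3 - counts) / 48.0).sum())
    if var <= 0:
        raise ValueError("zero variance (all |differences| tied at one value)")
    z = (w_plus - mean) / math.sqrt(var)
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return WilcoxonResult(n=n, W_plus=w_plus, W_minus=w_minus, Z=z,
                          p=min(max(p, np.finfo(float).tiny), 1.0))


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    n = x.size
    flags = []
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rho undefined")
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        flags.append("perfect_monotone:p_below_machine_floor")
        tstat = math.inf if rho > 0 else -math.inf
        p = np.finfo(float).tiny
    else:
        tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * t_dist.sf(abs(tstat), df=n - 2)
    return SpearmanResult(rho=rho, n=n, t=tstat, p=float(p), flags=tuple(flags))


def correlation_panel(
    cohort: pd.DataFrame,
    outcome: str = "delta_KiS",
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each respiratory variable with the outcome.

    ``cohort`` is one row per animal with an outcome column (e.g. ΔKiS) and
    per-animal median variables.  Missing columns are listed in the
    ``skipped`` attribute of the returned frame; significance flagged at
    p < ``alpha``.
    """
    if variables is None:
        variables = [c for c in cohort.columns if c != outcome]
    rows, skipped = [], []
    for var in variables:
        if var not in cohort.columns:
            skipped.append(var)
            continue
        res = spearman(cohort[var].to_numpy(), cohort[outcome].to_numpy())
        rows.append({"variable": var, "rho": res.rho, "p": res.p,
                     "n": res.n, "significant": res.p < alpha})
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out
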