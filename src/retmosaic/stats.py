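"""Paired t-test and one-way ANOVA.

These are the two inference procedures applied to the morphometric
readouts: two-tailed paired t-tests for contralateral-eye designs (treated
vs control eye of the same animal) and one-way ANOVA for surface-area
fractions across groups.  Tail probabilities are evaluated through the
regularized incomplete beta function:

    P(|T_df| >= t)  = I_{df/(df+t^2)}(df/2, 1/2)
    P(F_{d1,d2} >= f) = I_{d2/(d2+d1*f)}(d2/2, d1/2)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betainc

from .errors import ValidationError

__all__ = ["PairedTResult", "AnovaResult", "paired_t", "one_way_anova", "t_sf_two_tailed", "f_sf"]


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    n: int
    mean_diff: float
    degenerate: bool = False  # zero-variance differences with nonzero mean

    def summary(self) -> str:
        return (
            f"paired t-test: t({self.df}) = {self.t:.4f}, two-tailed p = {self.p:.4g}, "
            f"n = {self.n} pairs, mean difference = {self.mean_diff:.4g}"
            + (" [degenerate: zero-variance differences]" if self.degenerate else "")
        )


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float
    degenerate: bool = False  # zero within-group variance with group differences

    def summary(self) -> str:
        return (
            f"one-way ANOVA: F({self.df_between}, {self.df_within}) = {self.F:.4f}, "
            f"p = {self.p:.4g}"
            + (" [degenerate: zero within-group variance]" if self.degenerate else "")
        )


def t_sf_two_tailed(t: float, df: float) -> float:
    """P(|T_df| >= |t|) via the regularized incomplete beta function."""
    if df <= 0:
        raise ValidationError("df must be positive")
    t = float(t)
    if not np.isfinite(t):
        return 0.0
    if t == 0.0:
        return 1.0
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def f_sf(f: float, d1: float, d2: float) -> float:
    """P(F_{d1,d2} >= f) via the regularized incomplete beta function."""
    if d1 <= 0 or d2 <= 0:
        raise ValidationError("degrees of freedom must be positive")
    f = float(f)
    if f <= 0:
        return 1.0
    if not np.isfinite(f):
        return 0.0
    x = d2 / (d2 + d1 * f)
    return float(betainc(d2 / 2.0, d1 / 2.0, x))


def _as_diffs(x, y=None) -> np.ndarray:
    if y is not None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValidationError("x and y must be 1-D arrays of equal length")
        return x - y
    pairs = np.asarray(x, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValidationError("pairs must be an (n, 2) array or give x and y separately")
    return pairs[:, 0] - pairs[:, 1]


def paired_t(x, y=None) -> PairedTResult:
    """Two-tailed paired t-test.

    Accepts either an (n, 2) array of pairs or two matched 1-D samples.
    t = mean(d) / (sd(d) / sqrt(n)) with the n-1 sample standard deviation;
    df = n - 1.  All-zero differences give t = 0, p = 1; zero-variance
    differences about a nonzero mean are flagged degenerate with p = 0.
    """
    d = _as_diffs(x, y)
    n = len(d)
    if n < 2:
        raise ValidationError(f"need at least 2 pairs, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, df=df, p=1.0, n=n, mean_diff=0.0)
        return PairedTResult(
            t=float(np.inf) if mean > 0 else float(-np.inf),
            df=df,
            p=0.0,
            n=n,
            mean_diff=mean,
            degenerate=True,
        )
    t = mean / (sd / np.sqrt(n))
    return PairedTResult(t=float(t), df=df, p=t_sf_two_tailed(t, df), n=n, mean_diff=mean)


def one_way_anova(groups: Sequence[Sequence[float]], min_group_size: int = 2) -> AnovaResult:
    """One-way fixed-effects ANOVA across >= 2 groups.

    Standard between/within sum-of-squares decomposition; p from the F
    distribution on (k-1, N-k) degrees of freedom.  Identical groups give
    F = 0, p = 1; zero within-group variance with real group differences is
    flagged degenerate with p = 0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValidationError("need at least 2 groups")
    for g in gs:
        if g.ndim != 1 or len(g) < min_group_size:
            raise ValidationError(f"every group needs at least {min_group_size} observations")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ssb = float(sum(len(g) * (g.mean() - grand) ** 2 for g in gs))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    dfb = len(gs) - 1
    dfw = len(all_vals) - len(gs)
    if ssw == 0.0:
        if ssb > 0.0:
            return AnovaResult(float(np.inf), dfb, dfw, 0.0, ssb, ssw, degenerate=True)
        return AnovaResult(0.0, dfb, dfw, 1.0, 0.0, 0.0)
    F = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(F), dfb, dfw, f_sf(F, dfb, dfw), ssb, ssw)
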