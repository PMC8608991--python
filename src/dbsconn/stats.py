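"""Outcome statistics: within-subject ANOVA, Tukey-Kramer post hocs, and
Pearson linear regression.

The repeated-measures ANOVA is the classical one-way within-subject
decomposition ``SS_total = SS_subject + SS_time + SS_error`` with
``F = MS_time / MS_error`` on ``(t - 1, (t - 1)(n - 1))`` degrees of freedom.
Sphericity is assumed (no Greenhouse-Geisser correction).  Post hoc pairwise
comparisons use the studentized-range criterion with the ANOVA's error mean
square and degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RMAnovaResult",
    "RegressionResult",
    "rm_anova",
    "tukey_kramer",
    "pearson_regression",
]


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df_time: int
    df_error: int
    p: float
    ms_error: float
    ss_time: float
    ss_subject: float
    ss_error: float
    flagged: bool = False  # True when SS_error = 0 and F is undefined


def _as_matrix(Y) -> np.ndarray:
    if isinstance(Y, pd.DataFrame):
        Y = Y.to_numpy()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("outcome table must be patients x timepoints")
    if np.isnan(Y).any():
        raise ValueError("rm-ANOVA requires a complete table (no missing cells)")
    return Y


def rm_anova(Y) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a complete patients x timepoints table."""
    Y = _as_matrix(Y)
    n, t = Y.shape
    if n < 2 or t < 2:
        raise ValueError("need >= 2 patients and >= 2 timepoints")
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())
    ss_subject = float(t * ((Y.mean(axis=1) - grand) ** 2).sum())
    ss_time = float(n * ((Y.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_time
    df_time = t - 1
    df_error = (t - 1) * (n - 1)
    ms_time = ss_time / df_time
    ms_error = ss_error / df_error
    if ms_error <= 1e-12 * max(1.0, abs(ss_total)):
        return RMAnovaResult(
            F=float("nan"),
            df_time=df_time,
            df_error=df_error,
            p=float("nan"),
            ms_error=0.0,
            ss_time=ss_time,
            ss_subject=ss_subject,
            ss_error=0.0,
            flagged=True,
        )
    F = ms_time / ms_error
    p = float(sps.f.sf(F, df_time, df_error))
    return RMAnovaResult(
        F=float(F),
        df_time=df_time,
        df_error=df_error,
        p=p,
        ms_error=float(ms_error),
        ss_time=ss_time,
        ss_subject=ss_subject,
        ss_error=float(ss_error),
    )


def tukey_kramer(Y, labels=None) -> pd.DataFrame:
    """Studentized-range pairwise comparisons of timepoint means.

    Uses the rm-ANOVA error mean square and error df:
    ``q = |m_i - m_j| / sqrt(MS_error / n)`` with adjusted p from the
    studentized range distribution over ``t`` means.  Rows list unordered
    pairs (i < j) with ``mean_diff = m_j - m_i``.
    """
    Y = _as_matrix(Y)
    n, t = Y.shape
    res = rm_anova(Y)
    if labels is None:
        labels = [f"t{k}" for k in range(t)]
    if len(labels) != t:
        raise ValueError("one label per timepoint required")
    means = Y.mean(axis=0)
    rows = []
    for i in range(t):
        for j in range(i + 1, t):
            diff = means[j] - means[i]
            if res.flagged:
                q = float("nan")
                p = float("nan")
            else:
                q = abs(diff) / np.sqrt(res.ms_error / n)
                p = float(sps.studentized_range.sf(q, t, res.df_error))
            rows.append(
                {
                    "a": labels[i],
                    "b": labels[j],
                    "mean_diff": float(diff),
                    "q": q,
                    "p_adj": min(p, 1.0) if np.isfinite(p) else p,
                    "flagged": res.flagged,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def pearson_regression(x, y) -> RegressionResult:
    """Pearson correlation with two-sided t-based p and the least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return RegressionResult(
        r=float(res.rvalue),
        p=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(x),
    )
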