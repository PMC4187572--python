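"""Cohort screening, physiological aggregation and visit-comparison statistics.

Operates on tidy per-subject metric tables with columns
``subject, visit, workload, muscle, metric, value`` (one value per cell).
Visits 1 and 2 are identical control conditions; visit 3 follows dietary
nitrate. No multiple-testing correction is applied (alpha = 0.05 per test).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "screen_subject",
    "bp_characteristic",
    "ks_normality",
    "paired_comparison",
    "rm_anova",
    "pearson_with_p",
    "pearson_p_from_r",
    "correlate_changes",
    "visit_summary",
]

MVC_RANGE = (200.0, 700.0)   # Newtons, inclusive
IPAQ_MAX = 10000.0           # MET-minutes


def screen_subject(mvc: float, ipaq: float) -> bool:
    """Eligibility: MVC within 200-700 N (inclusive) and IPAQ <= 10,000 MET-min."""
    if mvc < 0 or ipaq < 0:
        raise ValueError("mvc and ipaq must be non-negative")
    return MVC_RANGE[0] <= mvc <= MVC_RANGE[1] and ipaq <= IPAQ_MAX


def bp_characteristic(readings: Sequence[float]) -> float:
    """Characteristic blood pressure: mean of the second and third readings."""
    if len(readings) != 3:
        raise ValueError(f"expected 3 BP readings, got {len(readings)}")
    return float((readings[1] + readings[2]) / 2.0)


def ks_normality(sample: Sequence[float], method: str = "ks") -> tuple[float, float]:
    """One-sample normality test against N(sample mean, sample SD).

    ``method="ks"`` is the classical Kolmogorov-Smirnov test with estimated
    parameters (as commonly reported from SPSS output); note its p-values
    are conservative when parameters are estimated. ``method="lilliefors"``
    applies the corresponding correction.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError(f"need n >= 3, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    if method == "ks":
        res = sps.kstest(x, "norm", args=(x.mean(), sd))
        return float(res.statistic), float(res.pvalue)
    if method == "lilliefors":
        stat, p = lilliefors(x, dist="norm")
        return float(stat), float(p)
    raise ValueError(f"unknown method {method!r}")


def paired_comparison(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Classical paired t test on matched samples; returns ``(t, df, p)``.

    Identical samples give ``t=0, p=1``; zero-variance differences with a
    nonzero mean are an error (t undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need matched samples of equal length n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def rm_anova(values: np.ndarray) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA on a complete subject x visit matrix.

    Returns ``(F, df1, df2, p)`` with ``df1 = k-1`` and ``df2 = (k-1)(n-1)``
    for n subjects and k visits.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 subjects and >= 2 visits")
    if not np.isfinite(m).all():
        raise ValueError("incomplete matrix (non-finite entries)")
    n, k = m.shape
    # identical visit means: F = 0 exactly (AnovaRM would return 0/0)
    if np.allclose(m.mean(axis=0), m.mean(), rtol=0, atol=1e-12 * max(1.0, np.abs(m).max())):
        return 0.0, k - 1, (k - 1) * (n - 1), 1.0
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "visit": np.tile(np.arange(k), n),
        "value": m.ravel(),
    })
    res = AnovaRM(long, depvar="value", subject="subject", within=["visit"]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), int(row["Num DF"]), int(row["Den DF"]), float(row["Pr > F"])


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-tailed p; requires n >= 3 and variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r at sample size n via the t transform.

    ``t = r * sqrt(n-2) / sqrt(1-r^2)`` with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1 < r < 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


_REQUIRED_METRIC_COLS = {"subject", "visit", "workload", "muscle", "metric", "value"}


def _pivot_metric(metrics: pd.DataFrame, workload, muscle, metric) -> pd.DataFrame:
    sel = metrics[
        (metrics["workload"] == workload)
        & (metrics["muscle"] == muscle)
        & (metrics["metric"] == metric)
    ]
    return sel.pivot(index="subject", columns="visit", values="value")


def correlate_changes(
    metrics: pd.DataFrame,
    bp: pd.DataFrame,
    visit_pairs: Iterable[tuple[int, int]] = ((1, 2), (2, 3), (3, 1)),
) -> pd.DataFrame:
    """Correlate between-visit changes in each metric with changes in BP.

    ``metrics`` is the tidy metric table; ``bp`` has columns
    ``subject, visit, systolic, diastolic``. For every
    (workload, metric, muscle, visit pair, BP component) cell, subjects
    present at both visits are paired, differenced (later minus earlier in
    the stated pair order) and correlated. Cells with fewer than 3 complete
    pairs are skipped. Returns a tidy frame mirroring a correlation-table
    grid: one row per cell with r, p and n.
    """
    missing = _REQUIRED_METRIC_COLS - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns {sorted(missing)}")
    bp_wide = {
        comp: bp.pivot(index="subject", columns="visit", values=comp)
        for comp in ("systolic", "diastolic")
    }
    rows = []
    for (workload, metric, muscle), _ in metrics.groupby(["workload", "metric", "muscle"]):
        piv = _pivot_metric(metrics, workload, muscle, metric)
        for a, b in visit_pairs:
            if a not in piv.columns or b not in piv.columns:
                continue
            d_metric = (piv[b] - piv[a]).dropna()
            for comp, wide in bp_wide.items():
                if a not in wide.columns or b not in wide.columns:
                    continue
                d_bp = (wide[b] - wide[a]).dropna()
                common = d_metric.index.intersection(d_bp.index)
                if len(common) < 3:
                    continue
                r, p = pearson_with_p(d_metric.loc[common], d_bp.loc[common])
                rows.append({
                    "workload": workload, "metric": metric, "muscle": muscle,
                    "visit_pair": f"{a}-{b}", "bp_component": comp,
                    "r": r, "p": p, "n": len(common),
                })
    return pd.DataFrame(rows)


def visit_summary(
    metrics: pd.DataFrame,
    visit_pairs: Iterable[tuple[int, int]] = ((1, 2), (2, 3), (3, 1)),
) -> pd.DataFrame:
    """Group summary per (workload, metric, muscle): mean +- SD per visit,
    paired-t p-values between visits and the repeated-measures ANOVA p.

    Complete cases only: subjects missing any visit are dropped from the
    paired tests and ANOVA of that cell.
    """
    rows = []
    for (workload, metric, muscle), _ in metrics.groupby(["workload", "metric", "muscle"]):
        piv = _pivot_metric(metrics, workload, muscle, metric)
        row: dict = {"workload": workload, "metric": metric, "muscle": muscle}
        for v in sorted(piv.columns):
            row[f"mean_v{v}"] = piv[v].mean()
            row[f"sd_v{v}"] = piv[v].std(ddof=1)
        for a, b in visit_pairs:
            if a in piv.columns and b in piv.columns:
                pair = piv[[a, b]].dropna()
                if len(pair) >= 2:
                    _, _, p = paired_comparison(pair[a], pair[b])
                    row[f"p_{a}v{b}"] = p
        complete = piv.dropna()
        if complete.shape[0] >= 2 and complete.shape[1] >= 2:
            f, df1, df2, p = rm_anova(complete.to_numpy())
            row.update({"anova_F": f, "anova_df1": df1, "anova_df2": df2, "anova_p": p})
        rows.append(row)
    return pd.DataFrame(rows)
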