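"""Cohort reference statistics: stratified sampling, normality, group
comparison, mean ± SD summaries and the mean + 2SD upper reference limit,
plus inter-observer agreement (Bland–Altman and correlation).

The upper reference limit is ``mean + 2*SD`` exactly (not 1.96·SD): for a
Tpe/QT ratio of 0.21 ± 0.02 this gives the 0.25 cutoff used for follow-up
flagging.  Group comparison is the unpaired (equal-variance) Student t-test;
Welch's variant is available behind a flag.  Non-normal strata are still
summarized as mean ± SD, with the Shapiro–Wilk p recorded alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SamplingError

__all__ = [
    "ReferenceSummary",
    "GroupComparison",
    "AgreementReport",
    "upper_reference_limit",
    "stratified_sample",
    "summarize",
    "test_normality",
    "compare_groups",
    "observer_agreement",
    "summarize_markers",
]


@dataclass(frozen=True)
class ReferenceSummary:
    """Mean ± SD reference summary of one marker in one stratum."""

    marker: str
    stratum: str
    n: int
    mean: float
    sd: float
    upper_limit: float
    normality_p: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison result (unpaired t-test)."""

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    test: str = "unpaired t"
    significant: bool = False


@dataclass(frozen=True)
class AgreementReport:
    """Inter-observer agreement: Bland–Altman bias/limits plus correlation."""

    n: int
    bias: float
    loa_lower: float
    loa_upper: float
    pearson_r: float


def upper_reference_limit(mean: float, sd: float) -> float:
    """Upper reference limit: mean + 2·SD."""
    return mean + 2.0 * sd


def stratified_sample(
    population: pd.DataFrame,
    strata_columns: Sequence[str],
    n: int | dict,
    seed: int,
    exclusion_flag: str | None = None,
) -> pd.DataFrame:
    """Seeded stratified random sample preserving stratum proportions.

    Rows with a truthy ``exclusion_flag`` column (e.g. referred to secondary
    screening) are removed before sampling.  ``n`` is either a total count
    (allocated across strata by largest remainder on the population
    proportions) or a per-stratum dict.
    """
    pop = population
    if exclusion_flag is not None:
        pop = pop[~pop[exclusion_flag].astype(bool)]
    groups = pop.groupby(list(strata_columns), sort=True)
    sizes = groups.size()
    if isinstance(n, dict):
        alloc = dict(n)
    else:
        if n > len(pop):
            raise SamplingError(f"requested {n} from population of {len(pop)}")
        raw = sizes / sizes.sum() * n
        alloc = {k: int(np.floor(v)) for k, v in raw.items()}
        short = n - sum(alloc.values())
        for k in (raw - pd.Series(alloc)).sort_values(ascending=False).index[:short]:
            alloc[k] += 1
    rng = np.random.default_rng(seed)
    parts = []
    for key, grp in groups:
        if isinstance(key, tuple) and len(key) == 1:
            key = key[0]
        want = alloc.get(key, 0)
        if want > len(grp):
            raise SamplingError(f"stratum {key!r}: requested {want} of {len(grp)}")
        if want:
            idx = rng.choice(len(grp), size=want, replace=False)
            parts.append(grp.iloc[np.sort(idx)])
    return pd.concat(parts) if parts else pop.iloc[:0]


def test_normality(values: Sequence[float]) -> float:
    """Shapiro–Wilk p-value; requires 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError(f"Shapiro–Wilk needs 3 <= n <= 5000, got {len(x)}")
    return float(stats.shapiro(x).pvalue)


def summarize(values: Sequence[float], stratum: str = "", marker: str = "") -> ReferenceSummary:
    """Mean, sample SD (n−1), mean + 2SD upper limit and normality p."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError(f"summary needs n >= 2, got {len(x)}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    p = test_normality(x) if 3 <= len(x) <= 5000 else float("nan")
    return ReferenceSummary(
        marker=marker,
        stratum=stratum,
        n=len(x),
        mean=mean,
        sd=sd,
        upper_limit=upper_reference_limit(mean, sd),
        normality_p=p,
    )


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    welch: bool = False,
    alpha: float = 0.05,
) -> GroupComparison:
    """Unpaired Student's t-test (two-sided); Welch variant behind a flag.

    Degenerate case: both groups constant with equal means gives p = 1 by
    convention; constant with different means gives p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.std(a) == 0 and np.std(b) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        stat = 0.0 if p == 1.0 else float("inf")
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        statistic=stat,
        p_value=p,
        test="Welch t" if welch else "unpaired t",
        significant=p < alpha,
    )


def observer_agreement(measurements_a: Sequence[float], measurements_b: Sequence[float]) -> AgreementReport:
    """Bland–Altman bias and 95% limits of agreement, plus Pearson r.

    The limits are bias ± 1.96·SD of the paired differences.  The
    correlation is NaN when either series is constant.
    """
    a = np.asarray(measurements_a, dtype=float)
    b = np.asarray(measurements_b, dtype=float)
    if len(a) != len(b):
        raise ValueError(f"paired series must have equal length ({len(a)} vs {len(b)})")
    if len(a) < 2:
        raise ValueError("agreement needs n >= 2")
    diff = b - a
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if np.std(a) > 0 and np.std(b) > 0:
        r = float(stats.pearsonr(a, b).statistic)
    else:
        r = float("nan")
    return AgreementReport(
        n=len(a), bias=bias, loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd, pearson_r=r
    )


def summarize_markers(
    markers: pd.DataFrame,
    marker_columns: Sequence[str] = ("tpe_v5", "qt_v5", "qtc", "tpe_qt"),
    stratum_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Reference summaries for each marker, overall and per stratum."""
    rows = []

    def _emit(df: pd.DataFrame, label: str) -> None:
        for col in marker_columns:
            vals = df.loc[df.get("evaluable", True).astype(bool), col].dropna()
            if len(vals) >= 3:
                s = summarize(vals, stratum=label, marker=col)
                rows.append(s.__dict__)

    _emit(markers, "all")
    for col in stratum_columns:
        for val, grp in markers.groupby(col):
            _emit(grp, f"{col}={val}")
    return pd.DataFrame(rows)
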