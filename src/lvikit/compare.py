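"""Pairwise inter-unit significance tests and correlations.

Proportions are compared with the pooled two-sample z-test, means with
Welch's t-test; no multiple-testing correction is applied by default
(Bonferroni / Holm are available behind a flag).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import SurveyDataset

__all__ = [
    "PairResult",
    "ComparisonMatrix",
    "two_proportion_test",
    "two_sample_mean_test",
    "pairwise_proportion_tests",
    "pairwise_mean_tests",
    "pairwise_significance",
    "correlation",
]


class PairResult(NamedTuple):
    statistic: float
    p_two_tailed: float
    significant: bool


@dataclass
class ComparisonMatrix:
    """All-pairs test results for one indicator across units."""

    indicator: str
    units: list[str]
    results: dict[frozenset, PairResult]
    alpha: float = 0.05

    def pair(self, a: str, b: str) -> PairResult:
        return self.results[frozenset((a, b))]

    @property
    def different_from(self) -> dict[str, list[str]]:
        """Per unit, the sorted list of units it differs from at alpha."""
        out: dict[str, list[str]] = {u: [] for u in self.units}
        for key, res in self.results.items():
            if res.significant:
                a, b = sorted(key)
                out[a].append(b)
                out[b].append(a)
        return {u: sorted(v) for u, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.results, key=sorted):
            a, b = sorted(key)
            res = self.results[key]
            rows.append(
                {
                    "indicator": self.indicator,
                    "unit_a": a,
                    "unit_b": b,
                    "statistic": res.statistic,
                    "p_two_tailed": res.p_two_tailed,
                    "significant": res.significant,
                }
            )
        return pd.DataFrame(rows)


def two_proportion_test(
    p1: float, n1: int, p2: float, n2: int
) -> tuple[float, float]:
    """Pooled two-sample z-test on percentages; returns ``(z, p_two_tailed)``.

    ``p1``/``p2`` are percentages in [0, 100].  Degenerate pooled proportions
    (all successes or all failures) give p = 1 when the inputs agree and are
    an error otherwise.
    """
    for p in (p1, p2):
        if not 0 <= p <= 100:
            raise ValueError("proportions must be percentages in [0, 100]")
    if min(n1, n2) < 1:
        raise ValueError("sample sizes must be >= 1")
    f1, f2 = p1 / 100.0, p2 / 100.0
    pooled = (f1 * n1 + f2 * n2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        if f1 == f2:
            return 0.0, 1.0
        raise ValueError("pooled proportion is degenerate but inputs differ")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (f1 - f2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def two_sample_mean_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t-test from summary statistics; returns ``(t, df, p_two_tailed)``.

    df follows Welch-Satterthwaite; with equal n and sd it reduces to the
    pooled ``2n - 2``.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if min(n1, n2) < 2:
        raise ValueError("sample sizes must be >= 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        df = float(n1 + n2 - 2)
        if mean1 == mean2:
            return 0.0, df, 1.0
        return float("inf") if mean1 > mean2 else float("-inf"), df, 0.0
    se = np.sqrt(v1 + v2)
    t = (mean1 - mean2) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df), float(2 * stats.t.sf(abs(t), df))


def _adjust(pvals: list[float], method: str | None) -> list[float]:
    if method is None:
        return pvals
    m = len(pvals)
    if method == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    if method == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        return list(adj)
    raise ValueError(f"unknown correction '{method}'")


def _pairwise(
    units: Sequence[str],
    tester,
    indicator: str,
    alpha: float,
    correction: str | None,
) -> ComparisonMatrix:
    pairs = list(itertools.combinations(units, 2))
    stats_p = [tester(a, b) for a, b in pairs]
    adj = _adjust([p for _, p in stats_p], correction)
    results = {
        frozenset((a, b)): PairResult(stat, p_adj, p_adj < alpha)
        for (a, b), (stat, _), p_adj in zip(pairs, stats_p, adj)
    }
    return ComparisonMatrix(indicator, list(units), results, alpha)


def pairwise_proportion_tests(
    props: Mapping[str, float],
    ns: Mapping[str, int],
    indicator: str = "",
    alpha: float = 0.05,
    correction: str | None = None,
) -> ComparisonMatrix:
    """All-pairs pooled z-tests from per-unit percentages and sample sizes."""
    units = list(props)

    def tester(a: str, b: str) -> tuple[float, float]:
        return two_proportion_test(props[a], ns[a], props[b], ns[b])

    return _pairwise(units, tester, indicator, alpha, correction)


def pairwise_mean_tests(
    means: Mapping[str, float],
    sds: Mapping[str, float],
    ns: Mapping[str, int],
    indicator: str = "",
    alpha: float = 0.05,
    correction: str | None = None,
) -> ComparisonMatrix:
    """All-pairs Welch t-tests from per-unit summary statistics."""
    units = list(means)

    def tester(a: str, b: str) -> tuple[float, float]:
        t, _, p = two_sample_mean_test(
            means[a], sds[a], ns[a], means[b], sds[b], ns[b]
        )
        return t, p

    return _pairwise(units, tester, indicator, alpha, correction)


def pairwise_significance(
    ds: SurveyDataset,
    field_name: str,
    target_category: str | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> ComparisonMatrix:
    """All-pairs tests on a raw survey field.

    With ``target_category`` the field is treated as categorical and compared
    by pooled z-tests on the share matching the category; otherwise the field
    is numeric and compared by Welch t-tests on the raw responses.
    """
    if len(ds.units) < 2:
        raise ValueError("need at least two units to compare")
    if target_category is not None:
        props: dict[str, float] = {}
        ns: dict[str, int] = {}
        for unit in ds.units:
            obs = [r.categorical(field_name) for r in ds.records_in(unit)]
            obs = [o for o in obs if o is not None]
            if not obs:
                raise ValueError(f"unit '{unit}' has no responses for '{field_name}'")
            props[unit] = 100.0 * sum(o == target_category for o in obs) / len(obs)
            ns[unit] = len(obs)
        return pairwise_proportion_tests(props, ns, field_name, alpha, correction)

    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    ns = {}
    for unit in ds.units:
        nums = [r.numeric(field_name) for r in ds.records_in(unit)]
        nums = [x for x in nums if x is not None]
        if len(nums) < 2:
            raise ValueError(f"unit '{unit}' has < 2 responses for '{field_name}'")
        arr = np.asarray(nums, dtype=float)
        means[unit] = float(arr.mean())
        sds[unit] = float(arr.std(ddof=1))
        ns[unit] = len(nums)
    return pairwise_mean_tests(means, sds, ns, field_name, alpha, correction)


def correlation(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Pearson correlation with two-tailed p from the t distribution (df = n-2)."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError("inputs must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant input")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)
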