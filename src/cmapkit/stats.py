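"""Group summaries and hypothesis tests for CMAP parameters.

The workflow this module supports is the usual one for small-animal
electrophysiology cohorts: summarize each group as n / mean / sd, compare
two independent groups with a two-tailed unpaired t-test (pooled-variance
Student by default, Welch available) or the Mann-Whitney U test, and compare
three or more groups with one-way ANOVA plus Tukey HSD, or Kruskal-Wallis
plus Holm-adjusted pairwise Mann-Whitney tests.

``summary_t_test`` computes the t-test from (n, mean, sd) alone, so printed
summary tables can be re-checked without raw data; it agrees with
``two_sample_test`` to machine precision on any raw sample having exactly
those moments.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError
from .io import TwoGroupTable

__all__ = [
    "GroupSummary",
    "TestResult",
    "two_sample_test",
    "summary_t_test",
    "one_way_anova",
    "summarize_groups",
    "format_report",
    "results_to_json",
]


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and sample SD (divisor n - 1) of one group."""

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DegenerateDataError(f"group {self.group!r}: n must be >= 2")
        if self.sd < 0:
            raise DegenerateDataError(f"group {self.group!r}: sd must be >= 0")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-tailed hypothesis test.

    ``extras`` carries method-specific detail: the post-hoc table for
    multi-group tests (list of dicts with the pair and adjusted p), or a
    ``degenerate`` note when the zero-variance convention was applied.
    """

    method: str
    statistic: float
    df: float
    p_value: float
    tails: int = 2
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "tails": self.tails,
            **({"extras": self.extras} if self.extras else {}),
        }


def _degenerate_two_sample(mean_a: float, mean_b: float, method: str) -> TestResult:
    if np.isclose(mean_a, mean_b):
        return TestResult(
            method=method,
            statistic=0.0,
            df=float("nan"),
            p_value=1.0,
            extras={"degenerate": "zero variance in both groups; p = 1 by convention"},
        )
    raise DegenerateDataError(
        "both groups have zero variance but different means; no test is defined"
    )


def two_sample_test(table: TwoGroupTable, method: str = "student") -> TestResult:
    """Compare two independent samples, two-tailed.

    Parameters
    ----------
    method : {"student", "welch", "mann_whitney"}
        ``student`` — pooled-variance t-test; ``welch`` — unequal-variance
        t-test with Welch-Satterthwaite df; ``mann_whitney`` — exact when the
        combined n <= 20 and there are no ties, otherwise the normal
        approximation with tie correction.
    """
    a, b = table.values
    if method in ("student", "welch"):
        if len(a) < 2 or len(b) < 2:
            raise DegenerateDataError("t-tests need n >= 2 per group")
        if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
            return _degenerate_two_sample(a.mean(), b.mean(), method)
        res = sps.ttest_ind(a, b, equal_var=(method == "student"))
        return TestResult(
            method=method,
            statistic=float(res.statistic),
            df=float(res.df),
            p_value=float(res.pvalue),
        )
    if method == "mann_whitney":
        if min(len(a), len(b)) < 2:
            warnings.warn("Mann-Whitney with n < 2 in a group is barely informative")
        n_comb = len(a) + len(b)
        ties = len(np.unique(np.concatenate([a, b]))) < n_comb
        mode = "exact" if (n_comb <= 20 and not ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=mode)
        return TestResult(
            method="mann_whitney",
            statistic=float(res.statistic),
            df=float("nan"),
            p_value=float(res.pvalue),
            extras={"mode": mode},
        )
    raise ValueError(f"unknown method {method!r}")


def summary_t_test(a: GroupSummary, b: GroupSummary, method: str = "student") -> TestResult:
    """Unpaired two-tailed t-test from summary statistics only.

    Lets a reader verify a published n / mean +- sd table without raw data.
    ``student`` pools the variances; ``welch`` uses the Welch-Satterthwaite
    degrees of freedom.
    """
    if method not in ("student", "welch"):
        raise ValueError(f"unknown method {method!r}")
    if a.sd == 0.0 and b.sd == 0.0:
        return _degenerate_two_sample(a.mean, b.mean, method)
    stat, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(method == "student")
    )
    if method == "student":
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestResult(
        method=method, statistic=float(stat), df=float(df), p_value=float(p)
    )


def one_way_anova(
    groups: Dict[str, Sequence[float]], method: str = "anova_tukey"
) -> TestResult:
    """Compare k >= 3 independent groups with post-hoc pairwise tests.

    ``anova_tukey`` — one-way ANOVA omnibus F followed by Tukey HSD;
    ``kruskal_posthoc`` — Kruskal-Wallis H followed by pairwise Mann-Whitney
    tests with Holm adjustment. The post-hoc table is in
    ``result.extras["posthoc"]`` as a list of ``{group_a, group_b, p}``
    dicts (adjusted p-values).
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError(
            "one_way_anova needs >= 3 groups; use two_sample_test for two"
        )
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    for g, s in zip(names, samples):
        if len(s) < 2:
            raise DegenerateDataError(f"group {g!r}: n must be >= 2")

    if method == "anova_tukey":
        f, p = sps.f_oneway(*samples)
        hsd = sps.tukey_hsd(*samples)
        posthoc = [
            {"group_a": names[i], "group_b": names[j], "p": float(hsd.pvalue[i, j])}
            for i, j in itertools.combinations(range(len(names)), 2)
        ]
        k, n_tot = len(samples), sum(map(len, samples))
        return TestResult(
            method="anova_tukey",
            statistic=float(f),
            df=float(k - 1),
            p_value=float(p),
            extras={"df_within": float(n_tot - k), "posthoc": posthoc},
        )
    if method == "kruskal_posthoc":
        h, p = sps.kruskal(*samples)
        pairs = list(itertools.combinations(range(len(names)), 2))
        raw = [
            float(sps.mannwhitneyu(samples[i], samples[j], alternative="two-sided").pvalue)
            for i, j in pairs
        ]
        adj = multipletests(raw, method="holm")[1]
        posthoc = [
            {"group_a": names[i], "group_b": names[j], "p": float(q)}
            for (i, j), q in zip(pairs, adj)
        ]
        return TestResult(
            method="kruskal_posthoc",
            statistic=float(h),
            df=float(len(names) - 1),
            p_value=float(p),
            extras={"posthoc": posthoc},
        )
    raise ValueError(f"unknown method {method!r}")


def summarize_groups(groups: Dict[str, Sequence[float]]) -> List[GroupSummary]:
    """n / mean / sample-SD summaries per group, unrounded.

    Rounding belongs to presentation (reports print 2 decimals); the
    returned values keep full precision.
    """
    out = []
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise DegenerateDataError(f"group {name!r}: need >= 2 values")
        out.append(
            GroupSummary(
                group=str(name), n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1))
            )
        )
    return out


def format_report(
    sections: Sequence[tuple],
    title: str = "Group comparison report",
) -> str:
    """Render a plain-text report.

    ``sections`` is a sequence of ``(label, summaries, result)`` where
    ``summaries`` is a list of :class:`GroupSummary` and ``result`` a
    :class:`TestResult`.
    """
    lines = [title, "=" * len(title), ""]
    for label, summaries, result in sections:
        lines.append(f"{label}")
        for s in summaries:
            lines.append(
                f"  {s.group}: n = {s.n}, mean = {s.mean:.2f}, sd = {s.sd:.2f}"
            )
        df_txt = "" if np.isnan(result.df) else f", df = {result.df:.4g}"
        lines.append(
            f"  {result.method} (two-tailed): statistic = "
            f"{result.statistic:.4g}{df_txt}, p = {result.p_value:.4g}"
        )
        for row in result.extras.get("posthoc", []):
            lines.append(
                f"    post-hoc {row['group_a']} vs {row['group_b']}: p = {row['p']:.4g}"
            )
        if "degenerate" in result.extras:
            lines.append(f"    note: {result.extras['degenerate']}")
        lines.append("")
    return "\n".join(lines)


def results_to_json(sections: Sequence[tuple]) -> str:
    """Machine-readable companion to :func:`format_report`."""
    payload = []
    for label, summaries, result in sections:
        payload.append(
            {
                "label": label,
                "groups": [
                    {"group": s.group, "n": s.n, "mean": s.mean, "sd": s.sd}
                    for s in summaries
                ],
                "test": result.to_dict(),
            }
        )
    return json.dumps(payload, indent=2, allow_nan=True)
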