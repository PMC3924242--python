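"""Group statistics shared by all measurement modules.

Two-sample t-tests (Student and Welch), one-way ANOVA with Tukey's HSD
post-hoc, and mean +/- SEM group summaries.  The t-tests accept either
raw per-unit values or printed summary statistics ``(mean, sem, n)`` —
the two entry points agree exactly because the t statistic depends on the
data only through those summaries.  Tukey's adjustment needs the
within-group spread and therefore requires raw values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "TestResult", "two_sample_t", "anova_tukey", "group_summary"]


@dataclass
class GroupSummary:
    """Mean +/- SEM summary of one group; SEM = sample SD / sqrt(n)."""

    label: str
    n: int
    mean: float
    sem: float
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        sem = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
        return cls(label, int(v.size), float(v.mean()), sem, v)

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)


@dataclass
class TestResult:
    """A hypothesis-test result; ``pairwise`` is present only for
    ANOVA/Tukey and holds the adjusted all-pairs p-values."""

    test: str
    statistic: float
    df: float | tuple[float, float]
    p_two_sided: float
    pairwise: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0) and not math.isnan(self.p_two_sided):
            raise ValueError("p-value outside [0, 1]")


def _coerce(group) -> tuple[float, float, int]:
    """Accept raw values, GroupSummary, or a (mean, sem, n) tuple; return
    (mean, sd, n)."""
    if isinstance(group, GroupSummary):
        return group.mean, group.sd, group.n
    if isinstance(group, tuple) and len(group) == 3 and np.isscalar(group[0]):
        mean, sem, n = group
        return float(mean), float(sem) * math.sqrt(int(n)), int(n)
    v = np.asarray(group, dtype=float)
    return float(v.mean()), float(np.std(v, ddof=1)), int(v.size)


def two_sample_t(group_a, group_b, variant: str = "welch") -> TestResult:
    """Two-sided two-sample t-test from raw values or summaries.

    ``variant="welch"`` (default) uses the unequal-variance statistic
    with Satterthwaite degrees of freedom; ``"student"`` pools the
    variances.  Two groups with zero variance and equal means give p = 1
    by convention; zero variance with unequal means is an error.
    """
    ma, sa, na = _coerce(group_a)
    mb, sb, nb = _coerce(group_b)
    if na < 2 or nb < 2:
        raise ValueError("need n >= 2 per group")
    va, vb = sa**2, sb**2

    if variant == "student":
        df: float = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    elif variant == "welch":
        se2 = va / na + vb / nb
        if se2 > 0:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            df = na + nb - 2
    else:
        raise ValueError(f"unknown variant {variant!r}")

    if se2 == 0:
        if ma == mb:
            return TestResult(f"{variant}_t", 0.0, df, 1.0)
        raise ValueError("zero variance with unequal means: t undefined")
    t = (ma - mb) / math.sqrt(se2)
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(f"{variant}_t", float(t), float(df), p)


def anova_tukey(
    groups: Mapping[str, Sequence[float]] | Sequence[GroupSummary],
    reference: str | None = None,
) -> TestResult:
    """One-way ANOVA with Tukey's HSD post-hoc over raw values.

    Returns the omnibus F and p plus an all-pairs table of Tukey-adjusted
    p-values; ``reference`` filters the pairwise table to comparisons
    against one designated group (the table still uses the all-group
    studentized-range adjustment).
    """
    if isinstance(groups, Mapping):
        named = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    else:
        named = {}
        for g in groups:
            if not isinstance(g, GroupSummary) or g.values is None:
                raise ValueError("Tukey's post-hoc requires raw values per group")
            named[g.label] = np.asarray(g.values, dtype=float)
    if len(named) < 2:
        raise ValueError("need >= 2 groups")
    for label, v in named.items():
        if v.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")

    labels = list(named)
    values = [named[k] for k in labels]
    f_stat, p_omnibus = sps.f_oneway(*values)
    n_total = sum(v.size for v in values)
    df = (len(values) - 1, n_total - len(values))

    hsd = sps.tukey_hsd(*values)
    rows = []
    for i, j in combinations(range(len(values)), 2):
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(values[i].mean() - values[j].mean()),
                "p_adj": float(hsd.pvalue[i, j]),
            }
        )
    pairwise = pd.DataFrame(rows)
    if reference is not None:
        if reference not in labels:
            raise ValueError(f"reference group {reference!r} not among groups")
        keep = (pairwise["group_a"] == reference) | (pairwise["group_b"] == reference)
        pairwise = pairwise[keep].reset_index(drop=True)

    return TestResult("anova_tukey", float(f_stat), df, float(p_omnibus), pairwise)


def group_summary(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean +/- SEM table, one row per group."""
    rows = []
    for label, values in values_by_group.items():
        s = GroupSummary.from_values(str(label), values)
        rows.append({"group": s.label, "n": s.n, "mean": s.mean, "sem": s.sem})
    return pd.DataFrame(rows)
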