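"""Nonparametric cohort comparisons and group summaries.

The comparison structure mirrors the analysis the scores feed: unpaired
two-group rank tests (Mann-Whitney U / Wilcoxon rank-sum) between bins,
a Kruskal-Wallis omnibus test across three or more bins, and
Benjamini-Hochberg FDR adjustment over all pairwise bin tests. All
alternatives are two-sided.

The rank-sum test has an exact mode that enumerates every assignment of
the pooled (midranked) observations to the two groups and counts
assignments whose U deviates from its null mean by at least the
observed deviation — the standard two-sided permutation p-value, valid
with ties. ``auto`` uses it for combined n <= 12 without ties and falls
back to the tie-corrected, continuity-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyInputError, ValidationError

#: Combined-size ceiling for the exact rank-sum mode in ``auto``.
EXACT_N_LIMIT = 12


@dataclass
class TestResult:
    """One comparison: statistic, p-value, and bookkeeping."""

    method: str  # "rank_sum" | "kruskal_wallis"
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    p_adjusted: float | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float | None  # absent for a single-member bin
    median: float
    q1: float
    q3: float
    n_excluded: int = 0


def _midrank_u(x: Sequence[float], y: Sequence[float]) -> float:
    """U statistic of x computed from midranks of the pooled data."""
    n1 = len(x)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)


def _exact_rank_sum_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided p by enumeration of all C(n, n1) group labelings."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2
    mu = n1 * (n - n1) / 2
    u_obs = float(ranks[: n1].sum() - offset)
    dev_obs = abs(u_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - mu) >= dev_obs - 1e-9:
            hits += 1
    return u_obs, hits / total


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    groups: tuple[str, str] = ("x", "y"),
) -> TestResult:
    """Unpaired two-sided Mann-Whitney U test with midranks for ties.

    ``mode`` is ``exact`` (full enumeration, valid with ties),
    ``normal_approx`` (tie correction and continuity correction), or
    ``auto`` (exact when combined n <= 12 and the pooled data are
    tie-free, approximation otherwise).
    """
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValidationError(f"unknown rank-sum mode {mode!r}")
    if len(x) == 0 or len(y) == 0:
        raise EmptyInputError("rank-sum test needs two non-empty groups")
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    pooled = x + y
    if mode == "auto":
        tie_free = len(set(pooled)) == len(pooled)
        mode = "exact" if len(pooled) <= EXACT_N_LIMIT and tie_free else "normal_approx"

    if mode == "exact":
        u, p = _exact_rank_sum_p(x, y)
    else:
        u, p = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        u, p = float(u), float(min(p, 1.0))
    return TestResult(
        method="rank_sum",
        groups=groups,
        statistic=u,
        p_value=p,
        n_per_group=(len(x), len(y)),
        details={"mode": mode, "continuity_correction": mode == "normal_approx"},
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> TestResult:
    """Kruskal-Wallis H (midranks, tie-corrected) with a chi-square p.

    The all-tied degenerate case (every pooled observation equal) is
    reported as H = 0, p = 1 rather than an error.
    """
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise EmptyInputError("Kruskal-Wallis groups must be non-empty")
    total_n = sum(len(g) for g in groups)
    if total_n < 3:
        raise ValidationError("Kruskal-Wallis needs total n >= 3")
    labels = tuple(labels) if labels else tuple(f"group{i}" for i in range(len(groups)))
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
        h, p = float(h), float(p)
    return TestResult(
        method="kruskal_wallis",
        groups=labels,
        statistic=h,
        p_value=p,
        n_per_group=tuple(len(g) for g in groups),
        details={"df": df},
    )


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted.tolist()


def _usable_bins(
    table: pd.DataFrame, bin_field: str, value_field: str, min_size: int = 2
) -> tuple[dict[str, np.ndarray], int]:
    """Bin -> values after exclusions; also the excluded-sample count."""
    if bin_field not in table.columns or value_field not in table.columns:
        raise ValidationError(
            f"score table lacks column {bin_field!r} or {value_field!r}"
        )
    work = table[[bin_field, value_field]].copy()
    n0 = len(work)
    work = work.dropna()
    work = work[~work[bin_field].astype(str).isin({"unknown", ""})]
    excluded = n0 - len(work)
    bins = {
        str(label): np.asarray(sub[value_field], dtype=float)
        for label, sub in work.groupby(bin_field, sort=True, observed=True)
    }
    small = [b for b, v in bins.items() if len(v) < min_size]
    for b in small:
        del bins[b]
    return bins, excluded


def compare_by_bins(
    score_table: pd.DataFrame,
    bin_field: str,
    scheme: str = "omnibus",
    value_field: str = "mapi",
) -> list[TestResult]:
    """Compare a score across bins of a categorical field.

    ``omnibus`` runs one Kruskal-Wallis test across all usable bins;
    ``pairwise_fdr`` runs the rank-sum test on every bin pair and
    BH-adjusts the p-values. Samples with unknown bin or missing score
    are excluded; bins with fewer than 2 samples are dropped.
    """
    if scheme not in ("omnibus", "pairwise_fdr"):
        raise ValidationError(f"unknown comparison scheme {scheme!r}")
    bins, _ = _usable_bins(score_table, bin_field, value_field)
    if len(bins) < 2:
        raise ValidationError(
            f"need >= 2 usable bins for {bin_field!r}; usable: {sorted(bins)}"
        )
    labels = sorted(bins)
    if scheme == "omnibus":
        return [kruskal_wallis([bins[b] for b in labels], labels=labels)]
    results = [
        rank_sum_test(bins[a], bins[b], mode="auto", groups=(a, b))
        for a, b in itertools.combinations(labels, 2)
    ]
    for res, adj in zip(results, bh_fdr([r.p_value for r in results])):
        res.p_adjusted = adj
    return results


def group_summary(
    score_table: pd.DataFrame, bin_field: str, value_field: str = "mapi"
) -> list[GroupSummary]:
    """Per-bin n, mean, sample SD, median, and quartiles.

    Samples with a missing score are ignored but counted per bin; a
    single-member bin has no SD.
    """
    if len(score_table) == 0:
        raise EmptyInputError("empty score table")
    if bin_field not in score_table.columns or value_field not in score_table.columns:
        raise ValidationError(
            f"score table lacks column {bin_field!r} or {value_field!r}"
        )
    out = []
    for label, sub in score_table.groupby(bin_field, sort=True, observed=True, dropna=False):
        values = np.asarray(sub[value_field], dtype=float)
        kept = values[np.isfinite(values)]
        if kept.size == 0:
            continue
        out.append(
            GroupSummary(
                group=str(label),
                n=int(kept.size),
                mean=float(kept.mean()),
                sd=float(kept.std(ddof=1)) if kept.size > 1 else None,
                median=float(np.median(kept)),
                q1=float(np.percentile(kept, 25)),
                q3=float(np.percentile(kept, 75)),
                n_excluded=int(values.size - kept.size),
            )
        )
    return out
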