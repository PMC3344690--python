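"""Plug-in estimation of diversities from category counts, and the
two-sample Z comparison of Gini-Simpson diversities.

Estimation is plug-in throughout: probabilities are estimated by the
empirical frequencies among *recorded* reports (missing observations are
excluded first), and a diversity is estimated by evaluating its formula at
those frequencies.  No finite-sample bias correction is applied.  Shannon-type
diversities are deliberately excluded from estimation and testing: no
uniformly unbiased estimator of Shannon diversity exists, so the inferential
pipeline is restricted to the Gini-Simpson type.

The variance of the plug-in Gini-Simpson estimate uses the standard
large-sample (delta-method) formula for Simpson-type indices,

    Var(H_hat) = (4/n) * (sum p_i^3 - (sum p_i^2)^2),

and two collections are compared with ``Z = (H_a - H_b) / sqrt(V_a + V_b)``
against the standard normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import ProbabilityDistribution
from .diversity import (
    gini_simpson_diversity,
    relative_marginal_diversity,
    self_f_diversity,
)
from .generators import gini_simpson_generator
from ._util import format_p_value, round_half_up

__all__ = [
    "CategoryCounts",
    "DiversityEstimate",
    "TwoSampleComparison",
    "DegenerateComparisonError",
    "plug_in_distribution",
    "estimate_gini_simpson",
    "gini_simpson_variance",
    "compare_gini_simpson",
    "recording_rate",
    "summarize_tables",
    "read_counts_csv",
    "write_counts_csv",
    "MISSING_ROW_LABEL",
]

#: Reserved category label marking the missing-report row in counts CSVs.
MISSING_ROW_LABEL = "__missing__"


class DegenerateComparisonError(ValueError):
    """Raised when a two-sample comparison has zero total variance."""


@dataclass(frozen=True)
class CategoryCounts:
    """Observed category counts for one attribute in one report collection.

    ``counts`` are per-category counts among recorded reports; ``n_missing``
    is the number of reports where the attribute was not recorded (or could
    not be mapped to a canonical category).  Together they account for every
    report: ``sum(counts) + n_missing == n_total_reports``.
    """

    attribute_name: str
    labels: tuple[str, ...]
    counts: tuple[int, ...]
    n_missing: int = 0
    n_unmapped: int = 0  # informational subset of n_missing

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("category labels must be unique")
        if any(c < 0 for c in self.counts) or self.n_missing < 0:
            raise ValueError("counts must be nonnegative")
        if not 0 <= self.n_unmapped <= self.n_missing:
            raise ValueError("n_unmapped must not exceed n_missing")

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def n_recorded(self) -> int:
        return int(sum(self.counts))

    @property
    def n_total_reports(self) -> int:
        return self.n_recorded + self.n_missing


def plug_in_distribution(c: CategoryCounts) -> ProbabilityDistribution:
    """Empirical category frequencies over recorded reports only.

    Zero-count categories are preserved in the label set (they still define
    the attribute's ``k`` and its uniform reference).
    """
    if c.n_recorded < 1:
        raise ValueError(f"attribute {c.attribute_name!r} has no recorded reports")
    return ProbabilityDistribution.from_counts(c.labels, c.counts)


@dataclass(frozen=True)
class DiversityEstimate:
    """A plug-in diversity estimate with its normalized value and variance."""

    estimate: float
    relative_estimate: float
    variance: float
    n: int
    k: int

    def standard_error(self) -> float:
        return math.sqrt(self.variance)


def gini_simpson_variance(p: np.ndarray, n: int) -> float:
    """Delta-method variance of the plug-in Gini-Simpson estimate."""
    p = np.asarray(p, dtype=float)
    s2 = float(np.sum(p ** 2))
    s3 = float(np.sum(p ** 3))
    return max(0.0, (4.0 / n) * (s3 - s2 * s2))


def estimate_gini_simpson(c: CategoryCounts) -> DiversityEstimate:
    """Plug-in Gini-Simpson diversity, its relative value and its variance.

    The relative estimate divides by the maximum ``(k-1)/k`` attained at the
    uniform distribution over the attribute's ``k`` categories.  A
    single-category attribute has zero diversity by definition.
    """
    if c.k == 1:
        return DiversityEstimate(0.0, 0.0, 0.0, n=c.n_recorded, k=1)
    if c.n_recorded < 2:
        raise ValueError("need at least two recorded reports to estimate diversity")
    p = plug_in_distribution(c)
    h = gini_simpson_diversity(p)
    rel = h * c.k / (c.k - 1)
    var = gini_simpson_variance(p.probs, c.n_recorded)
    return DiversityEstimate(h, rel, var, n=c.n_recorded, k=c.k)


@dataclass(frozen=True)
class TwoSampleComparison:
    """Z comparison of Gini-Simpson diversity between two collections."""

    attribute_name: str
    estimate_a: DiversityEstimate
    estimate_b: DiversityEstimate
    z: float
    p_value: float
    level: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.level

    @property
    def p_value_text(self) -> str:
        """p-value with values below 1e-5 reported as ``< 0.00001``."""
        return format_p_value(self.p_value)


def compare_gini_simpson(a: CategoryCounts, b: CategoryCounts,
                         level: float = 0.05,
                         alternative: str = "two-sided") -> TwoSampleComparison:
    """Z test for equality of Gini-Simpson diversity in two collections.

    The statistic is formed on the absolute diversity scale; with a shared
    label set the ``k/(k-1)`` normalization cancels, so the test is identical
    on the relative scale.  ``alternative`` is ``"two-sided"`` (default),
    ``"greater"`` (a more diverse than b) or ``"less"``.
    """
    if a.labels != b.labels:
        raise ValueError(
            f"attribute {a.attribute_name!r}: label sets differ between samples "
            f"({a.labels} vs {b.labels})")
    if not 0.0 < level < 1.0:
        raise ValueError("significance level must be in (0, 1)")
    ea = estimate_gini_simpson(a)
    eb = estimate_gini_simpson(b)
    v = ea.variance + eb.variance
    if v == 0.0:
        raise DegenerateComparisonError(
            f"attribute {a.attribute_name!r}: both variance estimates are zero")
    z = (ea.estimate - eb.estimate) / math.sqrt(v)
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    else:
        raise ValueError("alternative must be two-sided, greater or less")
    return TwoSampleComparison(a.attribute_name, ea, eb, z, min(p, 1.0), level)


def recording_rate(c: CategoryCounts) -> float:
    """Percentage of reports in which the attribute was recorded (1 decimal)."""
    if c.n_total_reports < 1:
        raise ValueError("empty collection")
    return round_half_up(100.0 * c.n_recorded / c.n_total_reports, 1)


# ---------------------------------------------------------------------------
# Summary tables


def summarize_tables(pairs: Sequence[tuple[CategoryCounts, CategoryCounts]],
                     level: float = 0.05,
                     digits: int = 4) -> dict[str, pd.DataFrame]:
    """Per-attribute summary of two report collections (a vs b).

    Returns three DataFrames:

    ``counts``
        Recorded / missing report counts and number-of-categories diversity
        per collection.  The NoC diversity of collection ``a`` may be supplied
        by distinct surface-term bookkeeping upstream; here it is ``k - 1``
        of the label set carried by each ``CategoryCounts``.
    ``relative``
        Relative Gini-Simpson diversities per collection plus the two-sample
        Z test p-value.
    ``per_category``
        Gini-Simpson self diversity and relative marginal diversity for every
        category in both collections.

    All diversity values are rounded half-up to ``digits`` decimals.
    """
    f = gini_simpson_generator()
    counts_rows, rel_rows, cat_rows = [], [], []
    for a, b in pairs:
        if a.labels != b.labels:
            raise ValueError(
                f"attribute {a.attribute_name!r}: label sets differ between "
                "the two collections")
        counts_rows.append({
            "attribute": a.attribute_name,
            "recorded_a": a.n_recorded,
            "missing_a": a.n_missing,
            "noc_diversity_a": a.k - 1,
            "recorded_b": b.n_recorded,
            "missing_b": b.n_missing,
            "noc_diversity_b": b.k - 1,
        })
        cmp_res = compare_gini_simpson(a, b, level=level)
        rel_rows.append({
            "attribute": a.attribute_name,
            "k": a.k,
            "n_a": a.n_recorded,
            "relative_gs_a": round_half_up(cmp_res.estimate_a.relative_estimate, digits),
            "n_b": b.n_recorded,
            "relative_gs_b": round_half_up(cmp_res.estimate_b.relative_estimate, digits),
            "z": round_half_up(cmp_res.z, digits),
            "p_value": cmp_res.p_value_text,
            "significant": cmp_res.significant,
        })
        pa = plug_in_distribution(a)
        pb = plug_in_distribution(b)
        for i, label in enumerate(a.labels):
            cat_rows.append({
                "attribute": a.attribute_name,
                "category": label,
                "count_a": a.counts[i],
                "self_diversity_a": round_half_up(self_f_diversity(f, pa, i), digits),
                "relative_marginal_a": round_half_up(
                    relative_marginal_diversity(f, pa, i), digits),
                "count_b": b.counts[i],
                "self_diversity_b": round_half_up(self_f_diversity(f, pb, i), digits),
                "relative_marginal_b": round_half_up(
                    relative_marginal_diversity(f, pb, i), digits),
            })
    return {
        "counts": pd.DataFrame(counts_rows),
        "relative": pd.DataFrame(rel_rows),
        "per_category": pd.DataFrame(cat_rows),
    }


# ---------------------------------------------------------------------------
# Counts CSV round-trip

_COUNT_COLS = ["attribute", "category", "count_collection_a", "count_collection_b"]


def read_counts_csv(path) -> list[tuple[CategoryCounts, CategoryCounts]]:
    """Read per-attribute counts for two collections from CSV.

    Expected columns: ``attribute, category, count_collection_a,
    count_collection_b`` with one optional ``__missing__`` row per attribute
    carrying the missing-report counts.  Attribute and category order follow
    first appearance in the file.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing_cols = [c for c in _COUNT_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"counts CSV {path} lacks required columns {missing_cols}")
    pairs = []
    for attr in df["attribute"].drop_duplicates():
        sub = df[df["attribute"] == attr]
        miss = sub[sub["category"] == MISSING_ROW_LABEL]
        body = sub[sub["category"] != MISSING_ROW_LABEL]
        labels = tuple(body["category"].astype(str))
        miss_a = int(miss["count_collection_a"].sum())
        miss_b = int(miss["count_collection_b"].sum())
        a = CategoryCounts(str(attr), labels,
                           tuple(int(x) for x in body["count_collection_a"]),
                           n_missing=miss_a)
        b = CategoryCounts(str(attr), labels,
                           tuple(int(x) for x in body["count_collection_b"]),
                           n_missing=miss_b)
        pairs.append((a, b))
    return pairs


def write_counts_csv(pairs: Sequence[tuple[CategoryCounts, CategoryCounts]],
                     path) -> None:
    """Inverse of :func:`read_counts_csv` (byte-stable modulo line endings)."""
    rows = []
    for a, b in pairs:
        for label, ca, cb in zip(a.labels, a.counts, b.counts):
            rows.append((a.attribute_name, label, ca, cb))
        rows.append((a.attribute_name, MISSING_ROW_LABEL, a.n_missing, b.n_missing))
    pd.DataFrame(rows, columns=_COUNT_COLS).to_csv(path, index=False,
                                                   encoding="utf-8",
                                                   lineterminator="\n")
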