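"""Labeled probability distributions over attribute categories.

A categorized attribute takes one of ``k`` labeled values (its categories).
Diversity measures are functions of the probability vector ``p = (p_1, ..., p_k)``
over those categories.  The label set — not the support — defines ``k``:
a category that was never observed still counts toward the number of
categories and toward the uniform reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ProbabilityDistribution", "JointDistribution"]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class ProbabilityDistribution:
    """A probability vector over an ordered set of unique category labels.

    Parameters
    ----------
    labels:
        Ordered category identifiers ``A_1, ..., A_k``.  Must be unique.
    probs:
        Nonnegative probabilities summing to 1 (within ``1e-12``).  Zero
        entries are allowed and retained: they contribute to ``k``.
    """

    labels: tuple[str, ...]
    probs: np.ndarray = field(repr=False)

    def __init__(self, labels: Sequence[str], probs: Sequence[float]):
        labels = tuple(str(x) for x in labels)
        p = np.asarray(probs, dtype=float)
        if p.ndim != 1 or p.size != len(labels):
            raise ValueError("labels and probs must have equal length")
        if len(labels) < 1:
            raise ValueError("need at least one category")
        if len(set(labels)) != len(labels):
            raise ValueError("category labels must be unique")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "probs", p)

    @property
    def k(self) -> int:
        """Number of categories (length of the label set, zeros included)."""
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    @classmethod
    def uniform(cls, labels: Sequence[str]) -> "ProbabilityDistribution":
        """The uniform reference distribution ``u = (1/k, ..., 1/k)``."""
        k = len(labels)
        return cls(labels, np.full(k, 1.0 / k))

    @classmethod
    def dichotomy(cls, p: float) -> "ProbabilityDistribution":
        """The two-point distribution ``(p, 1-p)`` used by marginal diversity."""
        return cls(("in", "out"), np.array([p, 1.0 - p]))

    @classmethod
    def from_counts(cls, labels: Sequence[str], counts: Sequence[float]
                    ) -> "ProbabilityDistribution":
        c = np.asarray(counts, dtype=float)
        total = c.sum()
        if total <= 0:
            raise ValueError("counts sum to zero; no distribution defined")
        return cls(labels, c / total)


@dataclass(frozen=True)
class JointDistribution:
    """A joint probability table ``p(x, y)`` over two labeled attributes."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    joint_probs: np.ndarray = field(repr=False)

    def __init__(self, row_labels: Sequence[str], col_labels: Sequence[str],
                 joint_probs) -> None:
        rows = tuple(str(x) for x in row_labels)
        cols = tuple(str(x) for x in col_labels)
        m = np.asarray(joint_probs, dtype=float)
        if m.shape != (len(rows), len(cols)):
            raise ValueError("joint_probs shape does not match labels")
        if np.any(m < 0):
            raise ValueError("joint probabilities must be nonnegative")
        if abs(m.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"joint probabilities sum to {m.sum()!r}, not 1")
        m = m.copy()
        m.setflags(write=False)
        object.__setattr__(self, "row_labels", rows)
        object.__setattr__(self, "col_labels", cols)
        object.__setattr__(self, "joint_probs", m)

    def row_marginal(self) -> ProbabilityDistribution:
        return ProbabilityDistribution(self.row_labels, self.joint_probs.sum(axis=1))

    def col_marginal(self) -> ProbabilityDistribution:
        return ProbabilityDistribution(self.col_labels, self.joint_probs.sum(axis=0))

    @classmethod
    def independent(cls, px: ProbabilityDistribution, py: ProbabilityDistribution
                    ) -> "JointDistribution":
        return cls(px.labels, py.labels, np.outer(px.probs, py.probs))
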