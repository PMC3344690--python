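"""f-diversity measures of categorized attributes.

All functions are pure: they take a :class:`ProbabilityDistribution` (or a
:class:`JointDistribution` for f-information) and return a float.  Zero
probabilities follow the usual entropy conventions: ``0 log 0 = 0`` and a
zero-probability category contributes nothing to the quadratic term of the
f-entropy.  Per-category measures at ``p_i = 0`` return the continuity limit
where it is finite (Gini-Simpson self diversity -> 1, marginal diversity -> 0)
and ``inf`` where it diverges (Shannon self diversity).

The central quantity is the f-entropy

    H_f(p) = sum_i p_i^2 f(1/p_i) + f(0) sum_i p_i (1 - p_i),

the p-weighted average of the per-category self f-diversities

    R_{f,i}(p) = p_i f(1/p_i) + f(0) (1 - p_i).

Relative versions divide by the value at the uniform distribution, making
attributes with different numbers of categories comparable on [0, 1].
"""

from __future__ import annotations

import math

import numpy as np

from .distributions import JointDistribution, ProbabilityDistribution
from .generators import ConvexGenerator

__all__ = [
    "gini_simpson_diversity",
    "shannon_diversity",
    "number_of_categories_diversity",
    "f_entropy",
    "relative_f_diversity",
    "rarity_order_beta",
    "diversity_from_rarity",
    "self_f_diversity",
    "marginal_f_diversity",
    "relative_self_diversity",
    "relative_marginal_diversity",
    "f_information",
]


def gini_simpson_diversity(p: ProbabilityDistribution) -> float:
    """Gini-Simpson index ``1 - sum p_i^2``.

    The probability that two independently drawn reports fall in different
    categories; ranges over ``[0, (k-1)/k]`` with the maximum at uniform.
    """
    return float(1.0 - np.sum(p.probs ** 2))


def shannon_diversity(p: ProbabilityDistribution, log_base: float = math.e) -> float:
    """Shannon entropy ``-sum p_i log p_i`` in the given base (default natural)."""
    q = p.probs[p.probs > 0]
    return float(-np.sum(q * np.log(q)) / math.log(log_base))


def number_of_categories_diversity(p: ProbabilityDistribution) -> float:
    """``k - 1`` where ``k`` is the size of the label set (zeros included)."""
    return float(p.k - 1)


def f_entropy(f: ConvexGenerator, p: ProbabilityDistribution) -> float:
    """f-entropy ``sum p_i^2 f(1/p_i) + f(0) sum p_i (1 - p_i)``."""
    total = 0.0
    for pi in p.probs:
        if pi > 0:
            total += pi * pi * f(1.0 / pi)
    gs = 1.0 - float(np.sum(p.probs ** 2))
    return total + f.at_zero * gs


def relative_f_diversity(f: ConvexGenerator, p: ProbabilityDistribution) -> float:
    """``H_f(p) / H_f(u)`` with ``u`` uniform over the same label set.

    For a single-category attribute both numerator and denominator are 0;
    the ratio is resolved to 0, the diversity floor.
    """
    if p.k == 1:
        return 0.0
    u = ProbabilityDistribution.uniform(p.labels)
    denom = f_entropy(f, u)
    if denom <= 0:
        raise ValueError(f"H_f at uniform is {denom!r}; relative diversity undefined")
    return f_entropy(f, p) / denom


def rarity_order_beta(p_i: float, beta: float) -> float:
    """Rarity of order ``beta``: ``(1 - p_i**beta)/beta``, or ``-log p_i`` at 0.

    ``beta = 1`` gives the Gini-Simpson rarity ``1 - p_i``, ``beta = 0`` the
    Shannon rarity ``-log p_i`` and ``beta = -1`` the number-of-categories
    rarity ``(1 - p_i)/p_i``.  For ``p_i = 0`` with ``beta <= 0`` the rarity
    diverges and ``inf`` is returned.
    """
    if beta < -1:
        raise ValueError("order-beta rarity requires beta >= -1")
    if not 0.0 <= p_i <= 1.0:
        raise ValueError("p_i must lie in [0, 1]")
    if p_i == 0.0:
        if beta <= 0:
            return math.inf
        return 1.0 / beta
    if beta == 0:
        return -math.log(p_i)
    return (1.0 - p_i ** beta) / beta


def diversity_from_rarity(p: ProbabilityDistribution, rarity) -> float:
    """Average rarity ``sum_i p_i R_i(p)`` for a per-category rarity vector.

    Categories with ``p_i = 0`` contribute nothing, even for infinite rarity
    (the ``0 * inf`` convention that keeps the number-of-categories diversity
    finite on distributions with empty categories).
    """
    r = np.asarray(rarity, dtype=float)
    if r.shape != p.probs.shape:
        raise ValueError("rarity vector length must equal the number of categories")
    mask = p.probs > 0
    return float(np.sum(p.probs[mask] * r[mask]))


def self_f_diversity(f: ConvexGenerator, p: ProbabilityDistribution, i: int) -> float:
    """Self f-diversity ``R_{f,i}(p) = p_i f(1/p_i) + f(0)(1 - p_i)``.

    The rarity of category ``i``: under the Gini-Simpson generator it equals
    ``1 - p_i``, under Shannon ``-log p_i`` (``inf`` at ``p_i = 0``).
    """
    pi = float(p.probs[i])
    if pi == 0.0:
        # lim p->0 of p f(1/p): equals lim t->inf f(t)/t (may be infinite)
        lim = _slope_at_infinity(f)
        return lim + f.at_zero
    return pi * f(1.0 / pi) + f.at_zero * (1.0 - pi)


def _slope_at_infinity(f: ConvexGenerator, t: float = 1e12) -> float:
    """Numerical ``lim_{t->inf} f(t)/t``; ``inf`` when the ratio still grows."""
    r1, r2 = f(t) / t, f(10 * t) / (10 * t)
    if r2 > r1 + 1e-9:
        return math.inf
    return r2


def marginal_f_diversity(f: ConvexGenerator, p: ProbabilityDistribution,
                         i: int) -> float:
    """f-diversity of the dichotomy ``(p_i, 1 - p_i)``.

    Collapses all other categories into one, measuring how much category ``i``
    alone contributes to unpredictability.  For the Gini-Simpson generator it
    equals ``2 p_i (1 - p_i)``; it is 0 at ``p_i`` in ``{0, 1}`` by continuity.
    """
    pi = float(p.probs[i])
    if pi in (0.0, 1.0):
        return 0.0
    d = ProbabilityDistribution.dichotomy(pi)
    return f_entropy(f, d)


def relative_self_diversity(f: ConvexGenerator, p: ProbabilityDistribution,
                            i: int) -> float:
    """``R_{f,i}(p) / H_f(p)`` — the share of total diversity carried by ``i``."""
    h = f_entropy(f, p)
    if h <= 0:
        raise ValueError("H_f(p) = 0; relative self diversity undefined")
    return self_f_diversity(f, p, i) / h


def relative_marginal_diversity(f: ConvexGenerator, p: ProbabilityDistribution,
                                i: int) -> float:
    """Marginal f-diversity normalized by its value at the even dichotomy.

    ``H_{f,i}(p) / H_f((1/2, 1/2))``; for the Gini-Simpson generator this is
    ``4 p_i (1 - p_i)``, maximal (1) at ``p_i = 1/2`` and 0 at the ends.  For
    a binary attribute both categories share the same value.
    """
    ref = f_entropy(f, ProbabilityDistribution.dichotomy(0.5))
    if ref <= 0:
        raise ValueError("H_f at the even dichotomy is 0; cannot normalize")
    return marginal_f_diversity(f, p, i) / ref


def f_information(f: ConvexGenerator, j: JointDistribution) -> float:
    """f-information ``sum_{x,y} p(x)p(y) f(p(x,y) / (p(x)p(y)))``.

    Nonnegative, and 0 exactly when the two attributes are independent
    (``f(1) = 0``).  With the Shannon generator this is mutual information.
    Cells with a zero marginal are skipped; a zero joint cell with positive
    marginals contributes ``p(x)p(y) f(0)``.
    """
    px = j.joint_probs.sum(axis=1)
    py = j.joint_probs.sum(axis=0)
    total = 0.0
    for a, pa in enumerate(px):
        if pa == 0:
            continue
        for b, pb in enumerate(py):
            if pb == 0:
                continue
            pab = j.joint_probs[a, b]
            total += pa * pb * f(pab / (pa * pb))
    return total
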