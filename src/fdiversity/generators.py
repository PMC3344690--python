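"""Convex generators defining f-diversities.

An f-diversity is built from a convex function ``f`` on ``[0, inf)`` with
``f(1) = 0``.  The f-entropy of a distribution ``p`` is

    H_f(p) = sum_i p_i^2 f(1/p_i) + f(0) sum_i p_i (1 - p_i)

and it is an f-diversity (nonnegative, minimal at a degenerate distribution,
maximal at uniform, symmetric, concave) when additionally
``g(t) = (f(t) - f(0)) / t`` is concave.

Built-in generators
-------------------
``gini_simpson``
    ``f(t) = t - 1`` for ``t > 1``, else ``0`` (so ``f(0) = 0``);
    yields the Gini-Simpson index ``1 - sum p_i^2``.
``shannon``
    ``f(t) = t log t`` (``f(0) = 0``); yields Shannon entropy.
``number_of_categories``
    ``f(t) = (t - 1)^2`` (``f(0) = 1``); yields ``k - 1`` for any ``p``
    with full support over ``k`` labels, with per-category rarity
    ``(1 - p_i) / p_i``.
``order_beta(beta)``
    ``f(t) = (t - t^(1-beta)) / beta`` for ``beta in [-1, 1), beta != 0``;
    interpolates the family of order-``beta`` rarities
    ``(1 - p^beta)/beta``.  ``beta = 0`` is Shannon, ``beta = 1`` the
    Gini-Simpson hinge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "ConvexGenerator",
    "gini_simpson_generator",
    "shannon_generator",
    "number_of_categories_generator",
    "order_beta_generator",
    "get_generator",
    "BUILTIN_GENERATORS",
]


@dataclass(frozen=True)
class ConvexGenerator:
    """A convex function ``f`` with ``f(1) = 0`` plus its limit value at 0.

    ``evaluate`` need only be defined for ``t > 0``; ``at_zero`` supplies the
    (possibly limiting) value ``f(0)`` used by the f-entropy formula.
    """

    name: str
    evaluate: Callable[[float], float]
    at_zero: float

    def __call__(self, t: float) -> float:
        if t < 0:
            raise ValueError("generator defined on [0, inf) only")
        if t == 0:
            return self.at_zero
        return self.evaluate(t)

    # -- numerical admissibility checks -------------------------------------

    def check_root_at_one(self, tol: float = 1e-12) -> bool:
        """``f(1) = 0`` is required of every generator."""
        return abs(self(1.0)) <= tol

    def check_convexity(self, grid: np.ndarray | None = None,
                        tol: float = 1e-9) -> bool:
        """Midpoint convexity of ``f`` sampled on a log-spaced grid.

        Checks ``f(l*t1 + (1-l)*t2) <= l*f(t1) + (1-l)*f(t2) + tol`` for all
        grid pairs at several mixing weights.  A numerical surrogate for the
        analytic property; no symbolic analysis is attempted.
        """
        if grid is None:
            grid = np.logspace(-3, 3, 25)
        vals = np.array([self(t) for t in grid])
        for lam in (0.25, 0.5, 0.75):
            for i in range(len(grid)):
                for j in range(i + 1, len(grid)):
                    mid = lam * grid[i] + (1 - lam) * grid[j]
                    if self(mid) > lam * vals[i] + (1 - lam) * vals[j] + tol:
                        return False
        return True

    def check_admissibility(self, grid: np.ndarray | None = None,
                            tol: float = 1e-9) -> bool:
        """Concavity of ``g(t) = (f(t) - f(0))/t`` on a sampled grid.

        Concave ``g`` guarantees the f-entropy is maximal at the uniform
        distribution, i.e. that it is a genuine f-diversity.  The default
        grid covers ``t >= 1`` only: the f-entropy evaluates ``f`` at the
        reciprocals ``1/p_i``, never strictly between 0 and 1, so concavity
        is required on that range (the Gini-Simpson hinge, for instance, is
        admissible there but has a convex kink at ``t = 1``).
        """
        if grid is None:
            grid = np.logspace(0, 3, 25)

        def g(t: float) -> float:
            return (self(t) - self.at_zero) / t

        gvals = np.array([g(t) for t in grid])
        for lam in (0.25, 0.5, 0.75):
            for i in range(len(grid)):
                for j in range(i + 1, len(grid)):
                    mid = lam * grid[i] + (1 - lam) * grid[j]
                    if g(mid) < lam * gvals[i] + (1 - lam) * gvals[j] - tol:
                        return False
        return True


def gini_simpson_generator() -> ConvexGenerator:
    """Hinge generator of the Gini-Simpson index."""
    return ConvexGenerator(
        name="gini_simpson",
        evaluate=lambda t: t - 1.0 if t > 1.0 else 0.0,
        at_zero=0.0,
    )


def shannon_generator(log_base: float = math.e) -> ConvexGenerator:
    """``t log t`` generator of Shannon entropy, in the given log base."""
    if log_base <= 0 or log_base == 1:
        raise ValueError("log_base must be positive and != 1")
    lb = math.log(log_base)
    return ConvexGenerator(
        name="shannon",
        evaluate=lambda t: t * math.log(t) / lb,
        at_zero=0.0,  # lim t->0+ of t log t
    )


def number_of_categories_generator() -> ConvexGenerator:
    """Generator whose f-entropy is k - 1, the number-of-categories diversity."""
    return ConvexGenerator(
        name="number_of_categories",
        evaluate=lambda t: (t - 1.0) ** 2,
        at_zero=1.0,
    )


def order_beta_generator(beta: float, log_base: float = math.e) -> ConvexGenerator:
    """Generator of the order-``beta`` rarity family.

    ``beta = 1`` returns the Gini-Simpson hinge, ``beta = 0`` the Shannon
    generator, ``beta = -1`` reproduces the number-of-categories rarity
    ``(1 - p)/p`` (via ``f(t) = t^2 - t``).  Requires ``beta >= -1``.
    """
    if beta < -1:
        raise ValueError("order-beta family requires beta >= -1")
    if beta == 0:
        return shannon_generator(log_base)
    if beta == 1:
        return gini_simpson_generator()
    if beta > 1:
        raise ValueError("generator form requires beta <= 1 (f(0) diverges above)")
    b = float(beta)
    at_zero = 0.0  # t^(1-beta) -> 0 as t -> 0+ for every beta < 1
    return ConvexGenerator(
        name=f"order_beta({b:g})",
        evaluate=lambda t: (t - t ** (1.0 - b)) / b,
        at_zero=at_zero,
    )


BUILTIN_GENERATORS = ("gini_simpson", "shannon", "number_of_categories", "order_beta")


def get_generator(name: str, *, beta: float | None = None,
                  log_base: float = math.e) -> ConvexGenerator:
    """Look up a built-in generator by name (the CLI's selection hook)."""
    if name == "gini_simpson":
        return gini_simpson_generator()
    if name == "shannon":
        return shannon_generator(log_base)
    if name == "number_of_categories":
        return number_of_categories_generator()
    if name == "order_beta":
        if beta is None:
            raise ValueError("order_beta generator requires beta")
        return order_beta_generator(beta, log_base)
    raise KeyError(f"unknown generator {name!r}; choose from {BUILTIN_GENERATORS}")
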