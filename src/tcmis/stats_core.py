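"""Exact statistics shared across the pipeline.

Hypergeometric tail probabilities (computed via log-space stable survival
functions, which survive population sizes in the tens of millions),
Benjamini-Hochberg step-up adjustment, and a one-sided set-overlap
enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DomainError",
    "TailProblem",
    "hypergeom_tail",
    "bh_adjust",
    "set_overlap_test",
]


class DomainError(ValueError):
    """Raised when counts or probabilities violate their domain constraints."""


@dataclass(frozen=True)
class TailProblem:
    """An upper-tail hypergeometric question.

    ``pop_size`` items, ``successes_in_pop`` of which are marked; ``draws``
    items are taken without replacement and ``observed`` marked items are
    seen.
    """

    pop_size: int
    successes_in_pop: int
    draws: int
    observed: int

    def __post_init__(self) -> None:
        if not 0 <= self.successes_in_pop <= self.pop_size:
            raise DomainError(
                f"successes_in_pop={self.successes_in_pop} outside [0, {self.pop_size}]"
            )
        if not 0 <= self.draws <= self.pop_size:
            raise DomainError(f"draws={self.draws} outside [0, {self.pop_size}]")
        if not 0 <= self.observed <= min(self.draws, self.successes_in_pop):
            raise DomainError(
                f"observed={self.observed} outside "
                f"[0, min({self.draws}, {self.successes_in_pop})]"
            )


def hypergeom_tail(problem: TailProblem, strict: bool = False) -> float:
    """Upper-tail probability of a hypergeometric count.

    Returns ``P(X >= observed)`` by default, or ``P(X > observed)`` when
    ``strict`` is true.
    """
    threshold = problem.observed if not strict else problem.observed + 1
    # sf(k) = P(X > k); scipy evaluates the pmf in log space.
    p = float(
        stats.hypergeom.sf(
            threshold - 1,
            problem.pop_size,
            problem.successes_in_pop,
            problem.draws,
        )
    )
    return min(max(p, 0.0), 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        return []
    if np.any(np.isnan(ps)) or np.any(ps < 0.0) or np.any(ps > 1.0):
        raise DomainError("p-values must lie in [0, 1]")
    q = multipletests(ps, method="fdr_bh")[1]
    return [float(v) for v in q]


def set_overlap_test(
    set_a: Collection, set_b: Collection, universe_size: int
) -> float:
    """One-sided enrichment p-value for the overlap of two sets.

    The overlap of ``set_b`` with ``set_a`` is compared against drawing
    ``|set_b|`` items uniformly from a universe of ``universe_size``
    containing ``|set_a|`` marked items.
    """
    a = set(set_a)
    b = set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise DomainError("universe smaller than one of the sets")
    problem = TailProblem(
        pop_size=universe_size,
        successes_in_pop=len(a),
        draws=len(b),
        observed=len(a & b),
    )
    return hypergeom_tail(problem, strict=False)
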