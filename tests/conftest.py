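"""Shared fixtures and independent oracles.

The enumeration oracle walks every possible draw explicitly and is kept
independent of the library code paths it validates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest


def enum_hypergeom_tail(
    pop: int, successes: int, draws: int, observed: int, strict: bool = False
) -> float:
    """Tail probability by explicit enumeration of all C(pop, draws) draws.

    Items 0..successes-1 are the marked ones. Only viable for pop <= ~12.
    """
    total = 0
    hits = 0
    marked = set(range(successes))
    for combo in itertools.combinations(range(pop), draws):
        total += 1
        count = sum(1 for item in combo if item in marked)
        if (count > observed) if strict else (count >= observed):
            hits += 1
    return hits / total


def bh_by_hand(pvalues: list[float]) -> list[float]:
    """Step-up BH applied literally: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvalues[idx] * m / rank)
        q[idx] = running
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_network():
    """Hand-built 2-herb / 3-compound / 4-target fixture."""
    from tcmis.hct_network import assemble, classify_direct

    hc = [("hA", "c1"), ("hA", "c2"), ("hB", "c2"), ("hB", "c3")]
    ct = [
        classify_direct("c1", "101", 500.0, "nM", "Ki"),
        classify_direct("c1", "102"),
        classify_direct("c2", "102", 2.0, "uM", "IC50"),
        classify_direct("c3", "103"),
        classify_direct("c3", "104", 50.0, "uM", "Kd"),
    ]
    network, rejects = assemble(hc, ct)
    assert rejects == []
    return network


def assert_close(actual, expected, tol=1e-9):
    assert math.isclose(actual, expected, rel_tol=0, abs_tol=tol), (
        f"{actual} != {expected} (tol {tol})"
    )
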