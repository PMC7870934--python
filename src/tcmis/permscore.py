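"""Permutation-based target-set scoring of compounds.

Null hypothesis: a compound's targets fall on a gene set's members no more
often than random draws from the protein-coding universe. For each gene
set a shared bank of random gene-set draws is generated once; every
compound's observed member-target count ``Sm`` is compared against its
null counts, yielding a strict-tail permutation p-value, a z-score, and
BH-adjusted calls. Five per-gene-set models are combined into a consensus
ranking by averaging normalized z-scores.

The analytic fast path replaces Monte Carlo with the exact hypergeometric
strict tail and closed-form null moments; it is bit-stable and used for
validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genesets import DEFAULT_UNIVERSE_SIZE, GeneSet
from .stats_core import DomainError, TailProblem, bh_adjust, hypergeom_tail

__all__ = [
    "CompoundTargetProfile",
    "PermutationResult",
    "ModelPrediction",
    "ConsensusRanking",
    "ScoreSettings",
    "NullSampler",
    "eligible_profiles",
    "sample_null",
    "permutation_pvalue",
    "permutation_zscore",
    "analytic_pvalue",
    "score_model",
    "combine_models",
    "profiles_from_ct_edges",
]


@dataclass(frozen=True)
class CompoundTargetProfile:
    compound_id: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.targets) < 1:
            raise DomainError(f"{self.compound_id}: empty target profile")

    @property
    def m(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class PermutationResult:
    compound_id: str
    geneset_name: str
    observed_overlap: int
    null_mean: float
    null_sd: float
    pvalue: float
    zscore: float
    n_permutations: int
    seed: Optional[int]
    analytic_p: float
    qvalue: Optional[float] = None


@dataclass
class ModelPrediction:
    geneset_name: str
    results: list[PermutationResult]
    positives: set[str]
    q_threshold: float = 0.01


@dataclass
class ConsensusRanking:
    union_positives: set[str]
    all_model_positives: set[str]
    combined_z: dict[str, float]
    normalization: str = "zstandardize"

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.combined_z.items(), key=lambda kv: (-kv[1], kv[0]))


class NullSampler:
    """Shared bank of random gene-set draws for one scoring model.

    Each of ``n_permutations`` draws takes ``geneset_size`` distinct gene
    indices uniformly from ``range(universe_size)``. The same draws are
    reused for every compound in the model.
    """

    def __init__(
        self,
        geneset_size: int,
        universe_size: int = DEFAULT_UNIVERSE_SIZE,
        n_permutations: int = 100_000,
        seed: int = 0,
    ) -> None:
        if geneset_size > universe_size:
            raise DomainError("gene set larger than universe")
        if n_permutations < 1:
            raise DomainError("need at least one permutation")
        self.geneset_size = geneset_size
        self.universe_size = universe_size
        self.n_permutations = n_permutations
        self.seed = seed
        rng = np.random.default_rng(seed)
        if geneset_size == 0:
            self._draws = np.empty((n_permutations, 0), dtype=np.int32)
        elif n_permutations * universe_size <= 20_000_000:
            # vectorized path for small universes
            keys = rng.random((n_permutations, universe_size))
            self._draws = np.argsort(keys, axis=1)[:, :geneset_size].astype(np.int32)
        else:
            draws = np.empty((n_permutations, geneset_size), dtype=np.int32)
            for i in range(n_permutations):
                draws[i] = rng.choice(universe_size, size=geneset_size, replace=False)
            self._draws = draws

    def overlaps(self, target_indices: Sequence[int]) -> np.ndarray:
        """Null overlap count for a compound, per permutation draw."""
        member = np.zeros(self.universe_size, dtype=bool)
        member[np.asarray(list(target_indices), dtype=np.int64)] = True
        if self._draws.shape[1] == 0:
            return np.zeros(self.n_permutations, dtype=np.int64)
        return member[self._draws].sum(axis=1)


def sample_null(
    geneset_size: int,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    n_permutations: int = 100_000,
    seed: int = 0,
) -> NullSampler:
    return NullSampler(geneset_size, universe_size, n_permutations, seed)


def eligible_profiles(
    profiles: Iterable[CompoundTargetProfile],
    genes: GeneSet,
    blocklist: Iterable[str] = (),
) -> list[CompoundTargetProfile]:
    """Drop blocklisted compounds and compounds with no member targets."""
    blocked = set(blocklist)
    return [
        p
        for p in profiles
        if p.compound_id not in blocked and p.targets & genes.genes
    ]


def permutation_pvalue(observed: int, null_samples: np.ndarray) -> float:
    """Share of null draws strictly exceeding the observed count."""
    null_samples = np.asarray(null_samples)
    if null_samples.size < 1:
        raise DomainError("empty null sample")
    return float((null_samples > observed).sum() / null_samples.size)


def permutation_zscore(observed: int, null_samples: np.ndarray) -> float:
    """(observed - null mean) / null SD."""
    null_samples = np.asarray(null_samples, dtype=float)
    mu = float(null_samples.mean())
    sd = float(null_samples.std())
    if sd == 0.0:
        raise DomainError("degenerate null: SD is zero, z-score undefined")
    return (observed - mu) / sd


def analytic_pvalue(
    observed: int, m: int, geneset_size: int, universe_size: int
) -> float:
    """Exact strict-tail probability of the permutation null."""
    problem = TailProblem(
        pop_size=universe_size,
        successes_in_pop=geneset_size,
        draws=m,
        observed=observed,
    )
    return hypergeom_tail(problem, strict=True)


def _analytic_moments(m: int, x: int, universe: int) -> tuple[float, float]:
    mean = m * x / universe
    var = m * (x / universe) * (1 - x / universe) * (universe - m) / (universe - 1)
    return mean, math.sqrt(var)


@dataclass(frozen=True)
class ScoreSettings:
    universe_size: int = DEFAULT_UNIVERSE_SIZE
    n_permutations: int = 100_000
    seed: int = 0
    q_threshold: float = 0.01
    method: str = "permutation"  # "permutation" | "analytic"
    blocklist: frozenset[str] = field(default_factory=frozenset)


def _index_universe(
    profiles: Sequence[CompoundTargetProfile], genes: GeneSet, universe_size: int
) -> dict[str, int]:
    """Assign stable indices within [0, universe_size) to every known gene.

    Known genes (targets and gene-set members) occupy the low indices in
    sorted order; the remainder of the universe is anonymous padding.
    """
    known = set(genes.genes)
    for p in profiles:
        known |= p.targets
    if len(known) > universe_size:
        raise DomainError(
            f"{len(known)} distinct genes exceed universe size {universe_size}"
        )
    return {g: i for i, g in enumerate(sorted(known))}


def score_model(
    profiles: Sequence[CompoundTargetProfile],
    genes: GeneSet,
    settings: ScoreSettings = ScoreSettings(),
) -> ModelPrediction:
    """Score eligible compounds against one gene set.

    p-values are BH-adjusted across all compounds scored in this model;
    positives are those with q below the threshold.
    """
    kept = eligible_profiles(profiles, genes, settings.blocklist)
    x = len(genes)
    results: list[PermutationResult] = []

    if settings.method == "analytic":
        for p in sorted(kept, key=lambda p: p.compound_id):
            sm = len(p.targets & genes.genes)
            mu, sd = _analytic_moments(p.m, x, settings.universe_size)
            if sd == 0.0:
                raise DomainError("degenerate null: SD is zero")
            pv = analytic_pvalue(sm, p.m, x, settings.universe_size)
            results.append(
                PermutationResult(
                    compound_id=p.compound_id,
                    geneset_name=genes.name,
                    observed_overlap=sm,
                    null_mean=mu,
                    null_sd=sd,
                    pvalue=pv,
                    zscore=(sm - mu) / sd,
                    n_permutations=0,
                    seed=None,
                    analytic_p=pv,
                )
            )
    elif settings.method == "permutation":
        index = _index_universe(kept, genes, settings.universe_size)
        sampler = NullSampler(
            geneset_size=x,
            universe_size=settings.universe_size,
            n_permutations=settings.n_permutations,
            seed=settings.seed,
        )
        for p in sorted(kept, key=lambda p: p.compound_id):
            sm = len(p.targets & genes.genes)
            nulls = sampler.overlaps([index[t] for t in p.targets])
            results.append(
                PermutationResult(
                    compound_id=p.compound_id,
                    geneset_name=genes.name,
                    observed_overlap=sm,
                    null_mean=float(nulls.mean()),
                    null_sd=float(nulls.std()),
                    pvalue=permutation_pvalue(sm, nulls),
                    zscore=permutation_zscore(sm, nulls),
                    n_permutations=settings.n_permutations,
                    seed=settings.seed,
                    analytic_p=analytic_pvalue(sm, p.m, x, settings.universe_size),
                )
            )
    else:
        raise DomainError(f"unknown scoring method {settings.method!r}")

    qvalues = bh_adjust([r.pvalue for r in results])
    results = [
        PermutationResult(**{**r.__dict__, "qvalue": q})
        for r, q in zip(results, qvalues)
    ]
    positives = {
        r.compound_id for r in results if r.qvalue < settings.q_threshold
    }
    return ModelPrediction(
        geneset_name=genes.name,
        results=results,
        positives=positives,
        q_threshold=settings.q_threshold,
    )


def combine_models(
    models: Sequence[ModelPrediction], normalization: str = "zstandardize"
) -> ConsensusRanking:
    """Cross-model consensus: union/intersection of positives and the mean
    per-model normalized z-score for every scored compound.

    Normalization happens across compounds within each model; the
    intersection is taken over the models in which a compound was scored.
    """
    if not models:
        raise DomainError("no models to combine")
    per_model_norm: list[dict[str, float]] = []
    for model in models:
        zs = np.array([r.zscore for r in model.results], dtype=float)
        ids = [r.compound_id for r in model.results]
        if zs.size == 0:
            per_model_norm.append({})
            continue
        if normalization == "zstandardize":
            sd = zs.std()
            norm = (zs - zs.mean()) / sd if sd > 0 else np.zeros_like(zs)
        elif normalization == "minmax":
            span = zs.max() - zs.min()
            norm = (zs - zs.min()) / span if span > 0 else np.zeros_like(zs)
        else:
            raise DomainError(f"unknown normalization {normalization!r}")
        per_model_norm.append(dict(zip(ids, (float(v) for v in norm))))

    union_positives: set[str] = set()
    for model in models:
        union_positives |= model.positives

    scored_in: dict[str, list[float]] = {}
    positive_in: dict[str, int] = {}
    n_scored: dict[str, int] = {}
    for model, norm in zip(models, per_model_norm):
        for cid, z in norm.items():
            scored_in.setdefault(cid, []).append(z)
            n_scored[cid] = n_scored.get(cid, 0) + 1
            if cid in model.positives:
                positive_in[cid] = positive_in.get(cid, 0) + 1
    combined = {cid: float(np.mean(zs)) for cid, zs in scored_in.items()}
    all_model_positives = {
        cid
        for cid, n in n_scored.items()
        if positive_in.get(cid, 0) == n and cid in union_positives
    }
    return ConsensusRanking(
        union_positives=union_positives,
        all_model_positives=all_model_positives,
        combined_z=combined,
        normalization=normalization,
    )


def profiles_from_ct_edges(ct_edges) -> list[CompoundTargetProfile]:
    """Collapse compound-target edges into per-compound target profiles."""
    targets: dict[str, set[str]] = {}
    for e in ct_edges:
        targets.setdefault(e.compound_id, set()).add(e.target)
    return [
        CompoundTargetProfile(compound_id=c, targets=frozenset(t))
        for c, t in sorted(targets.items())
    ]


def model_table(model: ModelPrediction) -> pd.DataFrame:
    """Flat per-compound table of one model's results."""
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "geneset": r.geneset_name,
                "observed_overlap": r.observed_overlap,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "pvalue": r.pvalue,
                "analytic_p": r.analytic_p,
                "qvalue": r.qvalue,
                "zscore": r.zscore,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
                "positive": r.compound_id in model.positives,
            }
            for r in model.results
        ]
    )
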