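"""Seeded generators for every input table, with planted ground truth.

Emulates the four pipeline inputs — herb literature counts, herb-compound
pairs, compound-target interactions, and gene sets — plus fingerprints and
SMILES, so every stage is testable offline. Planted structure (enriched
herbs, member-biased compounds, fingerprint prototypes) is returned
alongside the data and written to a sidecar JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .chemclust import Fingerprint
from .genesets import GeneSet, GeneSetCollection, write_gmt
from .litmine import HerbLiteratureRecord
from .stats_core import DomainError

__all__ = [
    "SyntheticConfig",
    "HCTData",
    "make_literature_table",
    "make_cir_sets",
    "make_hct",
    "make_fingerprints",
    "write_all",
    "SMILES_VOCABULARY",
]

#: Small vocabulary of real structures cycled through for SMILES output.
SMILES_VOCABULARY = [
    "c1ccccc1",  # benzene
    "CC(=O)Oc1ccccc1C(=O)O",  # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",  # ibuprofen
    "Oc1ccc(cc1)/C=C/c1cc(O)cc(O)c1",  # resveratrol
    "O=c1cc(oc2cc(O)cc(O)c12)-c1ccc(O)c(O)c1",  # luteolin
    "O=c1c(O)c(oc2cc(O)cc(O)c12)-c1ccc(O)c(O)c1",  # quercetin
    "O=c1cc(oc2cc(O)cc(O)c12)-c1ccccc1",  # chrysin
    "COc1cc2oc(-c3ccccc3)cc(=O)c2c(O)c1O",  # oroxylin A-like flavone
    "CCCCCCCCCCCCCCO",  # 1-tetradecanol
    "CCCCCCCCCCCCCCCC(=O)O",  # palmitic acid
    "Cc1cc2c(cc1O)C(=O)c1cc(O)ccc1C2=O",  # chrysophanol-like
    "OC[C@H]1O[C@@H](Oc2ccccc2)[C@H](O)[C@@H](O)[C@@H]1O",  # phenyl glucoside
    "CC(C)=CCc1c(O)cc(O)c2c1oc(-c1ccc(O)cc1)cc2=O",  # prenyl flavone
    "COc1ccc(C=CC(=O)CC(=O)C=Cc2ccc(O)c(OC)c2)cc1O",  # curcumin-like
    "CN1CCC[C@H]1c1cccnc1",  # nicotine
    "O=C(O)c1ccccc1O",  # salicylic acid
    "NCCc1ccc(O)c(O)c1",  # dopamine
    "CC(=O)NC1=CC=C(O)C=C1",  # paracetamol
    "C1CCC2(CC1)CCCCC2",  # spiro hydrocarbon
]


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    # literature screen
    n_herbs: int = 525
    n_enriched_herbs: int = 66
    corpus_N: int = 29_000_000
    corpus_K: int = 3_874_763
    herb_paper_range: tuple[int, int] = (200, 2000)
    enrichment_multiplier: float = 10.0
    # gene sets
    universe_size: int = 20462
    cir_sizes: tuple[int, int, int] = (138, 78, 226)
    cir_overlap: float = 0.10  # pairwise Jaccard
    # compound-target network
    n_compounds: int = 200
    targets_per_compound: tuple[int, int] = (4, 12)
    planted_positive_fraction: float = 0.20
    planted_cir_bias: float = 5.0  # lambda >= 1; 1 means no planted signal
    compounds_per_herb: tuple[int, int] = (3, 15)
    affinity_fraction: float = 0.5  # CT rows carrying an affinity value
    # fingerprints
    fp_prototypes: int = 3
    fp_flip_prob: float = 0.02
    fp_length: int = 512
    fp_density: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_herbs", "n_enriched_herbs", "universe_size", "n_compounds"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        for name in ("planted_positive_fraction", "cir_overlap", "fp_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name}={v} outside [0, 1]")
        if self.planted_cir_bias < 1.0:
            raise DomainError("planted_cir_bias must be >= 1")
        if self.n_enriched_herbs > self.n_herbs:
            raise DomainError("more enriched herbs than herbs")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _gene_id(i: int) -> str:
    return str(i + 1)  # Entrez-style integer strings 1..universe_size


def make_literature_table(
    config: SyntheticConfig,
) -> tuple[list[HerbLiteratureRecord], set[str]]:
    """Herb paper counts with a planted set of disease-enriched herbs.

    Background herbs draw k ~ Binomial(n, K/N); enriched herbs use the
    multiplied rate min(1, multiplier*K/N).
    """
    rng = _rng(config, 1)
    base_rate = config.corpus_K / config.corpus_N
    enriched_rate = min(1.0, config.enrichment_multiplier * base_rate)
    herb_ids = [f"herb{i:04d}" for i in range(config.n_herbs)]
    enriched = set(
        rng.choice(config.n_herbs, size=config.n_enriched_herbs, replace=False)
    )
    lo, hi = config.herb_paper_range
    records = []
    enriched_ids = set()
    for i, herb in enumerate(herb_ids):
        n = int(rng.integers(lo, hi + 1))
        rate = enriched_rate if i in enriched else base_rate
        k = int(rng.binomial(n, rate))
        if i in enriched:
            enriched_ids.add(herb)
        records.append(
            HerbLiteratureRecord(herb_id=herb, herb_papers=n, cooccurrence_papers=k)
        )
    return records, enriched_ids


def make_cir_sets(config: SyntheticConfig) -> GeneSetCollection:
    """Three gene sets with controlled pairwise Jaccard overlap.

    Built from disjoint blocks: a shared triple core, pair-exclusive
    overlap blocks, and per-set unique genes; realized pairwise Jaccard is
    within rounding (±0.02) of the request.
    """
    s1, s2, s3 = config.cir_sizes
    j = config.cir_overlap

    def pair_overlap(sa: int, sb: int) -> int:
        return int(round(j * (sa + sb) / (1.0 + j)))

    o12, o13, o23 = pair_overlap(s1, s2), pair_overlap(s1, s3), pair_overlap(s2, s3)
    t = max(0, o12 + o13 - s1, o12 + o23 - s2, o13 + o23 - s3)
    e12, e13, e23 = o12 - t, o13 - t, o23 - t
    if min(e12, e13, e23) < 0:
        raise DomainError("requested overlap structure infeasible")
    u1 = s1 - e12 - e13 - t
    u2 = s2 - e12 - e23 - t
    u3 = s3 - e13 - e23 - t
    if min(u1, u2, u3) < 0:
        raise DomainError("requested overlap exceeds set sizes")
    total = t + e12 + e13 + e23 + u1 + u2 + u3
    if total > config.universe_size:
        raise DomainError("universe too small for requested sets")

    rng = _rng(config, 2)
    pool = rng.choice(config.universe_size, size=total, replace=False)
    genes = [_gene_id(i) for i in pool]
    cursor = 0

    def take(n: int) -> set[str]:
        nonlocal cursor
        block = set(genes[cursor : cursor + n])
        cursor += n
        return block

    core = take(t)
    b12, b13, b23 = take(e12), take(e13), take(e23)
    q1, q2, q3 = take(u1), take(u2), take(u3)
    io = GeneSet("IO", frozenset(core | b12 | b13 | q1))
    im = GeneSet("IM", frozenset(core | b12 | b23 | q2))
    innate = GeneSet("IN", frozenset(core | b13 | b23 | q3))
    return GeneSetCollection(sets=[io, im, innate], universe_size=config.universe_size)


@dataclass
class HCTData:
    hc_pairs: list[tuple[str, str]]
    ct_rows: list[dict]
    planted_positives: set[str]
    herbs: list[str] = field(default_factory=list)


def make_hct(
    config: SyntheticConfig,
    cir: GeneSetCollection,
    herbs: Optional[list[str]] = None,
) -> HCTData:
    """Herb-compound pairs and compound-target rows with planted positives.

    A ``planted_positive_fraction`` of compounds draw each target from the
    CIR union with probability (lambda-1)/lambda, and uniformly from the
    universe otherwise; lambda=1 therefore yields a pure null. A fraction
    of rows carry Ki/Kd/IC50/EC50 affinities straddling the 10 uM direct
    threshold, in mixed nM/uM units.
    """
    rng = _rng(config, 3)
    cir_union = sorted(set().union(*(s.genes for s in cir.sets)))
    universe = [_gene_id(i) for i in range(config.universe_size)]
    compound_ids = [f"cmpd{i:04d}" for i in range(config.n_compounds)]

    n_planted = int(round(config.planted_positive_fraction * config.n_compounds))
    planted = set(
        rng.choice(config.n_compounds, size=n_planted, replace=False)
    )
    p_cir = (config.planted_cir_bias - 1.0) / config.planted_cir_bias

    lo, hi = config.targets_per_compound
    kinds = ("Ki", "Kd", "IC50", "EC50")
    ct_rows: list[dict] = []
    planted_ids = set()
    for i, cid in enumerate(compound_ids):
        m = int(rng.integers(lo, hi + 1))
        chosen: set[str] = set()
        is_planted = i in planted
        if is_planted:
            planted_ids.add(cid)
        while len(chosen) < m:
            if is_planted and rng.random() < p_cir:
                g = cir_union[int(rng.integers(len(cir_union)))]
            else:
                g = universe[int(rng.integers(len(universe)))]
            chosen.add(g)
        for g in sorted(chosen):
            row = {
                "compound_id": cid,
                "entrez_id": g,
                "affinity_value": "",
                "affinity_unit": "",
                "affinity_kind": "",
            }
            if rng.random() < config.affinity_fraction:
                um = float(10.0 ** rng.uniform(-2.0, 2.0))  # straddles 10 uM
                if rng.random() < 0.5:
                    row["affinity_value"] = f"{um * 1000.0:.4f}"
                    row["affinity_unit"] = "nM"
                else:
                    row["affinity_value"] = f"{um:.6f}"
                    row["affinity_unit"] = "uM"
                row["affinity_kind"] = kinds[int(rng.integers(len(kinds)))]
            ct_rows.append(row)

    if herbs is None:
        herbs = [f"herb{i:04d}" for i in range(config.n_enriched_herbs)]
    lo_h, hi_h = config.compounds_per_herb
    hc_pairs: set[tuple[str, str]] = set()
    for herb in herbs:
        size = int(rng.integers(lo_h, min(hi_h, config.n_compounds) + 1))
        for idx in rng.choice(config.n_compounds, size=size, replace=False):
            hc_pairs.add((herb, compound_ids[int(idx)]))
    # every compound attached to at least one herb
    attached = {c for _, c in hc_pairs}
    for cid in compound_ids:
        if cid not in attached:
            herb = herbs[int(rng.integers(len(herbs)))]
            hc_pairs.add((herb, cid))
    return HCTData(
        hc_pairs=sorted(hc_pairs),
        ct_rows=ct_rows,
        planted_positives=planted_ids,
        herbs=list(herbs),
    )


def make_fingerprints(
    config: SyntheticConfig,
) -> tuple[list[Fingerprint], np.ndarray]:
    """Prototype bit patterns plus Bernoulli flip noise, with true labels."""
    if config.fp_prototypes < 1:
        raise DomainError("need at least one prototype")
    rng = _rng(config, 4)
    protos = rng.random((config.fp_prototypes, config.fp_length)) < config.fp_density
    labels = rng.integers(config.fp_prototypes, size=config.n_compounds)
    fps = []
    for i in range(config.n_compounds):
        bits = protos[labels[i]].copy()
        flips = rng.random(config.fp_length) < config.fp_flip_prob
        bits ^= flips
        if not bits.any():
            bits[int(rng.integers(config.fp_length))] = True
        fps.append(Fingerprint(compound_id=f"cmpd{i:04d}", bits=bits))
    return fps, labels


def write_all(config: SyntheticConfig, out_dir: str | Path) -> dict:
    """Generate every table and write the pipeline's input dialects.

    Produces literature.tsv, herb_compound.tsv, compound_target.tsv,
    genesets.gmt, smiles.tsv, blocklist.txt and ground_truth.json; returns
    the ground-truth dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, enriched = make_literature_table(config)
    with open(out / "literature.tsv", "w") as fh:
        fh.write("herb_id\therb_papers\tcooccurrence_papers\n")
        for r in records:
            fh.write(f"{r.herb_id}\t{r.herb_papers}\t{r.cooccurrence_papers}\n")

    cir = make_cir_sets(config)
    write_gmt(cir.sets, out / "genesets.gmt")

    hct = make_hct(config, cir, herbs=sorted(enriched))
    with open(out / "herb_compound.tsv", "w") as fh:
        fh.write("herb_id\tcompound_id\n")
        for h, c in hct.hc_pairs:
            fh.write(f"{h}\t{c}\n")
    with open(out / "compound_target.tsv", "w") as fh:
        fh.write("compound_id\tentrez_id\taffinity_value\taffinity_unit\taffinity_kind\n")
        for row in hct.ct_rows:
            fh.write(
                f"{row['compound_id']}\t{row['entrez_id']}\t{row['affinity_value']}\t"
                f"{row['affinity_unit']}\t{row['affinity_kind']}\n"
            )

    with open(out / "smiles.tsv", "w") as fh:
        fh.write("compound_id\tsmiles\n")
        for i in range(config.n_compounds):
            fh.write(
                f"cmpd{i:04d}\t{SMILES_VOCABULARY[i % len(SMILES_VOCABULARY)]}\n"
            )
    (out / "blocklist.txt").write_text("")

    truth = {
        "config": asdict(config),
        "enriched_herbs": sorted(enriched),
        "planted_positives": sorted(hct.planted_positives),
        "cir_set_sizes": {s.name: len(s) for s in cir.sets},
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
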