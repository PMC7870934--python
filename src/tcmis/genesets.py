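"""Gene-set curation and integration.

Gene identity is the Entrez ID as a trimmed string; no symbol mapping is
bundled. Sets can be filtered by supporting-agent count, integrated by
minimum membership across base sets, unioned, and tested pairwise for
overlap enrichment. GMT and one-ID-per-line formats are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .stats_core import DomainError, set_overlap_test

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "DEFAULT_UNIVERSE_SIZE",
    "filter_by_agent_count",
    "integrate_min_membership",
    "union_sets",
    "pairwise_overlap_report",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
]

#: Human protein-coding gene universe used throughout unless overridden.
DEFAULT_UNIVERSE_SIZE = 20462


def _clean_ids(genes: Iterable[str]) -> frozenset[str]:
    cleaned = set()
    for g in genes:
        gid = str(g).strip()
        if not gid:
            raise DomainError("empty gene ID")
        cleaned.add(gid)
    return frozenset(cleaned)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", _clean_ids(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)
    universe_size: int = DEFAULT_UNIVERSE_SIZE

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise DomainError("gene-set names must be unique")
        for s in self.sets:
            if len(s) > self.universe_size:
                raise DomainError(
                    f"set {s.name} larger than universe ({len(s)} > {self.universe_size})"
                )

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def filter_by_agent_count(
    target_agents: Mapping[str, int], min_agents: int = 3, name: str = "IO"
) -> GeneSet:
    """Keep targets supported by at least ``min_agents`` agents."""
    for target, count in target_agents.items():
        if count < 0:
            raise DomainError(f"negative agent count for {target}")
    kept = {t for t, c in target_agents.items() if c >= min_agents}
    return GeneSet(name=name, genes=frozenset(kept))


def integrate_min_membership(
    collection: GeneSetCollection, min_sets: int = 2, name: str = "IG-1"
) -> GeneSet:
    """Genes belonging to at least ``min_sets`` of the collection's sets."""
    if min_sets > len(collection.sets):
        raise DomainError(
            f"min_sets={min_sets} exceeds number of sets ({len(collection.sets)})"
        )
    counts: dict[str, int] = {}
    for s in collection.sets:
        for g in s.genes:
            counts[g] = counts.get(g, 0) + 1
    return GeneSet(name=name, genes=frozenset(g for g, c in counts.items() if c >= min_sets))


def union_sets(collection: GeneSetCollection, name: str = "IG-2") -> GeneSet:
    """Union of all sets in the collection."""
    if not collection.sets:
        raise DomainError("collection is empty")
    union: set[str] = set()
    for s in collection.sets:
        union |= s.genes
    return GeneSet(name=name, genes=frozenset(union))


def pairwise_overlap_report(collection: GeneSetCollection) -> pd.DataFrame:
    """Overlap size and enrichment p-value for every unordered pair."""
    rows = []
    sets = collection.sets
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            rows.append(
                {
                    "set_i": a.name,
                    "set_j": b.name,
                    "size_i": len(a),
                    "size_j": len(b),
                    "overlap": len(a.genes & b.genes),
                    "pvalue": set_overlap_test(
                        a.genes, b.genes, collection.universe_size
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["set_i", "set_j", "size_i", "size_j", "overlap", "pvalue"]
    )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DomainError(f"{path}: malformed GMT line: {line[:60]!r}")
            sets.append(GeneSet(name=fields[0], genes=frozenset(fields[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path, description: str = "-") -> None:
    with open(path, "w") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{description}\t{genes}\n")


def read_gene_list(path: str | Path, name: str = "custom") -> GeneSet:
    """Read a one-Entrez-ID-per-line gene list."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    return GeneSet(name=name, genes=frozenset(genes))
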