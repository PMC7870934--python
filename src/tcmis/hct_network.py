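"""Tripartite herb-compound-target network assembly and analysis.

Compound-target interactions are classified *direct* when a binding
affinity (Ki, Kd, IC50 or EC50) below 10 uM supports them, otherwise
*indirect* (functional/literature evidence). Duplicate edges collapse
direct-over-indirect; duplicate direct rows keep the lowest affinity.
Degrees K (per compound) and D (per target) are counted over
compound-target edges only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .genesets import GeneSet
from .stats_core import DomainError

__all__ = [
    "CTInteraction",
    "HCTNetwork",
    "DegreeReport",
    "DIRECT_AFFINITY_THRESHOLD_UM",
    "classify_direct",
    "dedupe_ct",
    "assemble",
    "restrict_to_geneset",
    "degree_report",
    "select_high_degree_genes",
    "herb_subnetwork",
    "shared_targets",
    "positive_proportion_by_herb",
    "read_herb_compound_table",
    "read_compound_target_table",
    "write_edge_lists",
    "to_graphml",
]

DIRECT_AFFINITY_THRESHOLD_UM = 10.0

_UNIT_TO_UM = {"nM": 1e-3, "uM": 1.0, "μM": 1.0, "µM": 1.0}
_KINDS = ("Ki", "Kd", "IC50", "EC50")
# Preference order among tied direct duplicates.
_KIND_RANK = {k: i for i, k in enumerate(_KINDS)}


class AffinityParseError(ValueError):
    """Raised for unknown affinity units or kinds."""


@dataclass(frozen=True)
class CTInteraction:
    compound_id: str
    target: str
    evidence: str  # "direct" | "indirect"
    affinity_value: Optional[float] = None
    affinity_unit: Optional[str] = None
    affinity_kind: Optional[str] = None

    def __post_init__(self) -> None:
        if self.evidence not in ("direct", "indirect"):
            raise DomainError(f"bad evidence class {self.evidence!r}")
        if self.evidence == "direct" and self.affinity_um is None:
            raise DomainError(
                f"direct edge {self.compound_id}-{self.target} lacks affinity data"
            )

    @property
    def affinity_um(self) -> Optional[float]:
        if self.affinity_value is None:
            return None
        if self.affinity_unit not in _UNIT_TO_UM:
            raise AffinityParseError(f"unknown affinity unit {self.affinity_unit!r}")
        return float(self.affinity_value) * _UNIT_TO_UM[self.affinity_unit]

    @property
    def pair(self) -> tuple[str, str]:
        return (self.compound_id, self.target)


def classify_direct(
    compound_id: str,
    target: str,
    affinity_value: Optional[float] = None,
    affinity_unit: Optional[str] = None,
    affinity_kind: Optional[str] = None,
    threshold_um: float = DIRECT_AFFINITY_THRESHOLD_UM,
) -> CTInteraction:
    """Build a CTInteraction, deciding direct/indirect from the affinity.

    Direct requires an affinity strictly below ``threshold_um`` after unit
    conversion; everything else (including edges with no affinity at all)
    is indirect.
    """
    if affinity_kind is not None and affinity_kind not in _KINDS:
        raise AffinityParseError(f"unknown affinity kind {affinity_kind!r}")
    um = None
    if affinity_value is not None:
        if affinity_unit not in _UNIT_TO_UM:
            raise AffinityParseError(f"unknown affinity unit {affinity_unit!r}")
        um = float(affinity_value) * _UNIT_TO_UM[affinity_unit]
    evidence = "direct" if um is not None and um < threshold_um else "indirect"
    return CTInteraction(
        compound_id=str(compound_id).strip(),
        target=str(target).strip(),
        evidence=evidence,
        affinity_value=affinity_value,
        affinity_unit=affinity_unit,
        affinity_kind=affinity_kind,
    )


def _dedupe_key(edge: CTInteraction) -> tuple:
    # direct first, then lowest uM affinity, then kind preference.
    um = edge.affinity_um
    return (
        0 if edge.evidence == "direct" else 1,
        um if um is not None else float("inf"),
        _KIND_RANK.get(edge.affinity_kind, len(_KINDS)),
    )


def dedupe_ct(edges: Iterable[CTInteraction]) -> list[CTInteraction]:
    """One edge per (compound, target): direct outranks indirect, lowest
    affinity wins among direct duplicates, earlier rows break remaining ties.
    Output ordered by (compound, target)."""
    best: dict[tuple[str, str], CTInteraction] = {}
    for edge in edges:
        prev = best.get(edge.pair)
        if prev is None or _dedupe_key(edge) < _dedupe_key(prev):
            best[edge.pair] = edge
    return [best[k] for k in sorted(best)]


@dataclass
class HCTNetwork:
    herbs: set[str] = field(default_factory=set)
    compounds: set[str] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)
    hc_edges: set[tuple[str, str]] = field(default_factory=set)
    ct_edges: list[CTInteraction] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.hc_edges) + len(self.ct_edges)

    @property
    def n_nodes(self) -> int:
        return len(self.herbs) + len(self.compounds) + len(self.targets)

    def ct_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.ct_edges}

    def compounds_of(self, herb_id: str) -> set[str]:
        return {c for h, c in self.hc_edges if h == herb_id}

    def targets_of(self, compound_id: str) -> set[str]:
        return {e.target for e in self.ct_edges if e.compound_id == compound_id}

    def direct_count(self) -> int:
        return sum(1 for e in self.ct_edges if e.evidence == "direct")


@dataclass
class DegreeReport:
    compound_degree: dict[str, int]
    target_degree: dict[str, int]
    mean_compound_degree: float
    mean_target_degree: float

    def display_means(self) -> tuple[float, float]:
        """Means rounded to one decimal for reporting."""
        return (round(self.mean_compound_degree, 1), round(self.mean_target_degree, 1))


def assemble(
    hc_pairs: Iterable[tuple[str, str]],
    ct_edges: Iterable[CTInteraction],
    herb_filter: Optional[set[str]] = None,
) -> tuple[HCTNetwork, list[str]]:
    """Assemble the tripartite network.

    Restricts to herbs in ``herb_filter`` (when given), keeps compounds
    linked to at least one retained herb, dedupes compound-target edges and
    prunes orphan nodes. Dangling references are returned as a rejects
    report rather than raising.
    """
    rejects: list[str] = []
    hc = set()
    for herb, compound in hc_pairs:
        herb, compound = str(herb).strip(), str(compound).strip()
        if herb_filter is not None and herb not in herb_filter:
            continue
        hc.add((herb, compound))
    herbs = {h for h, _ in hc}
    compounds = {c for _, c in hc}

    deduped = dedupe_ct(ct_edges)
    kept_ct = []
    for edge in deduped:
        if edge.compound_id not in compounds:
            rejects.append(
                f"ct edge {edge.compound_id}->{edge.target}: compound not attached "
                "to any retained herb"
            )
            continue
        kept_ct.append(edge)
    targets = {e.target for e in kept_ct}
    # no herb/compound orphan pruning beyond the herb filter: herbs with no
    # compounds cannot occur (hc defines them) and compounds keep their herb
    # membership even when target-less at this stage.
    return (
        HCTNetwork(
            herbs=herbs,
            compounds=compounds,
            targets=targets,
            hc_edges=hc,
            ct_edges=kept_ct,
        ),
        rejects,
    )


def restrict_to_geneset(network: HCTNetwork, genes: GeneSet) -> HCTNetwork:
    """Keep CT edges whose target is in ``genes``; prune compounds with no
    remaining targets and herbs with no remaining compounds."""
    kept_ct = [e for e in network.ct_edges if e.target in genes.genes]
    compounds = {e.compound_id for e in kept_ct}
    hc = {(h, c) for h, c in network.hc_edges if c in compounds}
    herbs = {h for h, _ in hc}
    targets = {e.target for e in kept_ct}
    return HCTNetwork(
        herbs=herbs, compounds=compounds, targets=targets, hc_edges=hc, ct_edges=kept_ct
    )


def degree_report(network: HCTNetwork) -> DegreeReport:
    """Degrees K (compound) and D (target), counted over CT edges only."""
    if not network.compounds or not network.targets:
        raise DomainError("degree report on an empty network")
    k: dict[str, int] = {c: 0 for c in network.compounds}
    d: dict[str, int] = {t: 0 for t in network.targets}
    for e in network.ct_edges:
        k[e.compound_id] = k.get(e.compound_id, 0) + 1
        d[e.target] = d.get(e.target, 0) + 1
    return DegreeReport(
        compound_degree=k,
        target_degree=d,
        mean_compound_degree=sum(k.values()) / len(k),
        mean_target_degree=sum(d.values()) / len(d),
    )


def select_high_degree_genes(
    report: DegreeReport, min_degree: int = 10, name: str = "high-degree"
) -> GeneSet:
    """Targets with D >= min_degree (inclusive boundary)."""
    return GeneSet(
        name=name,
        genes=frozenset(t for t, d in report.target_degree.items() if d >= min_degree),
    )


def herb_subnetwork(
    network: HCTNetwork,
    herb_id: str,
    compounds_filter: Optional[set[str]] = None,
) -> HCTNetwork:
    """Single-herb compound-target subnetwork, optionally limited to a
    compound subset."""
    if herb_id not in network.herbs:
        raise DomainError(f"herb {herb_id!r} not in network")
    compounds = network.compounds_of(herb_id)
    if compounds_filter is not None:
        compounds &= set(compounds_filter)
    kept_ct = [e for e in network.ct_edges if e.compound_id in compounds]
    compounds = {e.compound_id for e in kept_ct} | compounds
    return HCTNetwork(
        herbs={herb_id},
        compounds=compounds,
        targets={e.target for e in kept_ct},
        hc_edges={(herb_id, c) for c in compounds},
        ct_edges=kept_ct,
    )


def shared_targets(
    network: HCTNetwork, compounds: set[str], name: str = "shared"
) -> GeneSet:
    """Targets adjacent to every listed compound."""
    compounds = set(compounds)
    if len(compounds) < 2:
        raise DomainError("need at least two compounds")
    shared: Optional[set[str]] = None
    for c in sorted(compounds):
        targets = network.targets_of(c)
        shared = targets if shared is None else shared & targets
    return GeneSet(name=name, genes=frozenset(shared or set()))


def positive_proportion_by_herb(
    network: HCTNetwork,
    positives: set[str],
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-herb share of network compounds that are predicted positive.

    Flagged iff the proportion strictly exceeds ``threshold``. The
    denominator is the herb's compounds present in the current network.
    """
    positives = set(positives)
    rows = []
    for herb in sorted(network.herbs):
        compounds = network.compounds_of(herb)
        n_pos = len(compounds & positives)
        prop = n_pos / len(compounds) if compounds else 0.0
        rows.append(
            {
                "herb_id": herb,
                "n_compounds": len(compounds),
                "n_positive": n_pos,
                "proportion": prop,
                "flagged": prop > threshold,
            }
        )
    return pd.DataFrame(
        rows, columns=["herb_id", "n_compounds", "n_positive", "proportion", "flagged"]
    )


# ---------------------------------------------------------------------------
# I/O


def read_herb_compound_table(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"herb_id", "compound_id"} - set(df.columns)
    if missing:
        raise DomainError(f"{path}: missing columns {sorted(missing)}")
    return [(r.herb_id, r.compound_id) for r in df.itertuples(index=False)]


def read_compound_target_table(
    path: str | Path, threshold_um: float = DIRECT_AFFINITY_THRESHOLD_UM
) -> list[CTInteraction]:
    """Read compound_id/entrez_id rows with optional affinity columns and
    classify each as direct or indirect."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"compound_id", "entrez_id"} - set(df.columns)
    if missing:
        raise DomainError(f"{path}: missing columns {sorted(missing)}")
    edges = []
    for row in df.itertuples(index=False):
        value = getattr(row, "affinity_value", None)
        value = float(value) if value not in (None, "", "nan") and pd.notna(value) else None
        unit = getattr(row, "affinity_unit", None)
        unit = unit if value is not None and pd.notna(unit) and unit != "" else None
        kind = getattr(row, "affinity_kind", None)
        kind = kind if pd.notna(kind) and kind not in ("", None) else None
        edges.append(
            classify_direct(
                compound_id=row.compound_id,
                target=row.entrez_id,
                affinity_value=value,
                affinity_unit=unit,
                affinity_kind=kind,
                threshold_um=threshold_um,
            )
        )
    return edges


def read_workbook_sheet(
    path: str | Path, sheet: str, column_map: Mapping[str, str]
) -> pd.DataFrame:
    """Read one sheet of an XLSX workbook, renaming columns per
    ``column_map`` (source column -> pipeline column). Requires openpyxl."""
    df = pd.read_excel(path, sheet_name=sheet, dtype=str, engine="openpyxl")
    missing = set(column_map) - set(df.columns)
    if missing:
        raise DomainError(f"{path}[{sheet}]: missing columns {sorted(missing)}")
    return df.rename(columns=dict(column_map))[list(column_map.values())]


def write_edge_lists(
    network: HCTNetwork, out_dir: str | Path, header_comment: str | None = None
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = f"# {header_comment}\n" if header_comment else ""
    with open(out / "herb_compound_edges.tsv", "w") as fh:
        fh.write(prefix)
        fh.write("herb_id\tcompound_id\n")
        for h, c in sorted(network.hc_edges):
            fh.write(f"{h}\t{c}\n")
    with open(out / "compound_target_edges.tsv", "w") as fh:
        fh.write(prefix)
        fh.write("compound_id\tentrez_id\tevidence\taffinity_value\taffinity_unit\taffinity_kind\n")
        for e in sorted(network.ct_edges, key=lambda e: e.pair):
            fh.write(
                f"{e.compound_id}\t{e.target}\t{e.evidence}\t"
                f"{'' if e.affinity_value is None else e.affinity_value}\t"
                f"{e.affinity_unit or ''}\t{e.affinity_kind or ''}\n"
            )


def to_graphml(network: HCTNetwork, path: str | Path) -> None:
    g = nx.Graph()
    for h in network.herbs:
        g.add_node(f"herb:{h}", kind="herb", label=h)
    for c in network.compounds:
        g.add_node(f"compound:{c}", kind="compound", label=c)
    for t in network.targets:
        g.add_node(f"target:{t}", kind="target", label=t)
    for h, c in network.hc_edges:
        g.add_edge(f"herb:{h}", f"compound:{c}", kind="herb-compound")
    for e in network.ct_edges:
        g.add_edge(
            f"compound:{e.compound_id}",
            f"target:{e.target}",
            kind="compound-target",
            evidence=e.evidence,
        )
    nx.write_graphml(g, path)
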