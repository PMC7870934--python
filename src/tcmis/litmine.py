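"""Literature co-occurrence screening of herbs against a disease.

Each herb contributes two counts: ``n`` papers mentioning the herb and
``k`` papers mentioning both the herb and the disease. Against corpus
constants (total papers ``N``, disease papers ``K``) the chance of seeing
at least ``k`` co-occurrences is a hypergeometric upper tail; herbs are
called significant when the BH-adjusted q-value falls below ``q_threshold``
and the co-occurrence ratio k/n exceeds ``r_threshold``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .stats_core import DomainError, TailProblem, bh_adjust, hypergeom_tail

__all__ = [
    "CorpusStats",
    "HerbLiteratureRecord",
    "herb_pvalue",
    "neg_log_q",
    "screen_herbs",
    "read_literature_table",
    "write_screen_table",
]


@dataclass(frozen=True)
class CorpusStats:
    total_papers: int
    disease_papers: int

    def __post_init__(self) -> None:
        if not 0 < self.disease_papers <= self.total_papers:
            raise DomainError(
                "need 0 < disease_papers <= total_papers, got "
                f"{self.disease_papers} / {self.total_papers}"
            )


@dataclass(frozen=True)
class HerbLiteratureRecord:
    herb_id: str
    herb_papers: int
    cooccurrence_papers: int
    ratio: Optional[float] = field(default=None)
    pvalue: Optional[float] = field(default=None)
    qvalue: Optional[float] = field(default=None)
    significant: Optional[bool] = field(default=None)

    def __post_init__(self) -> None:
        if self.herb_papers < 0 or self.cooccurrence_papers < 0:
            raise DomainError("counts must be non-negative")
        if self.cooccurrence_papers > self.herb_papers:
            raise DomainError(
                f"{self.herb_id}: co-occurrence count {self.cooccurrence_papers} "
                f"exceeds herb paper count {self.herb_papers}"
            )


def herb_pvalue(record: HerbLiteratureRecord, corpus: CorpusStats) -> float:
    """Chance probability of co-occurrence in at least ``k`` papers."""
    if record.herb_papers > corpus.total_papers:
        raise DomainError(
            f"{record.herb_id}: herb paper count exceeds corpus size"
        )
    if record.herb_papers == 0:
        return 1.0
    problem = TailProblem(
        pop_size=corpus.total_papers,
        successes_in_pop=corpus.disease_papers,
        draws=record.herb_papers,
        observed=min(record.cooccurrence_papers, corpus.disease_papers),
    )
    return hypergeom_tail(problem, strict=False)


def neg_log_q(qvalue: float, floor: float = 1e-200) -> float:
    """-log10 of a q-value, with zeros floored (default cap 200.00)."""
    if not 0.0 <= qvalue <= 1.0:
        raise DomainError(f"q-value {qvalue} outside [0, 1]")
    return -math.log10(max(qvalue, floor))


def screen_herbs(
    records: Iterable[HerbLiteratureRecord],
    corpus: CorpusStats,
    q_threshold: float = 0.01,
    r_threshold: float = 0.05,
) -> list[HerbLiteratureRecord]:
    """Score every herb, BH-adjust across the whole list, and flag hits.

    Output is sorted by descending -lg(q), ties broken by descending ratio
    then by herb id. Significance requires q < q_threshold (strict) and
    ratio > r_threshold (strict).
    """
    records = list(records)
    if not records:
        raise DomainError("no herb records supplied")
    pvalues = [herb_pvalue(r, corpus) for r in records]
    qvalues = bh_adjust(pvalues)
    scored = []
    for rec, p, q in zip(records, pvalues, qvalues):
        ratio = (
            rec.cooccurrence_papers / rec.herb_papers if rec.herb_papers > 0 else 0.0
        )
        scored.append(
            replace(
                rec,
                ratio=ratio,
                pvalue=p,
                qvalue=q,
                significant=(q < q_threshold and ratio > r_threshold),
            )
        )
    scored.sort(key=lambda r: (r.qvalue, -r.ratio, r.herb_id))
    return scored


def read_literature_table(path: str | Path) -> list[HerbLiteratureRecord]:
    """Read a TSV with columns herb_id, herb_papers, cooccurrence_papers."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"herb_id": str})
    required = {"herb_id", "herb_papers", "cooccurrence_papers"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"{path}: missing columns {sorted(missing)}")
    return [
        HerbLiteratureRecord(
            herb_id=row.herb_id,
            herb_papers=int(row.herb_papers),
            cooccurrence_papers=int(row.cooccurrence_papers),
        )
        for row in df.itertuples(index=False)
    ]


def write_screen_table(
    records: Iterable[HerbLiteratureRecord],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "herb_id": [r.herb_id for r in records],
            "herb_papers": [r.herb_papers for r in records],
            "cooccurrence_papers": [r.cooccurrence_papers for r in records],
            "ratio": [r.ratio for r in records],
            "pvalue": [r.pvalue for r in records],
            "qvalue": [r.qvalue for r in records],
            "neg_log_q": [neg_log_q(r.qvalue) for r in records],
            "significant": [bool(r.significant) for r in records],
        }
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
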