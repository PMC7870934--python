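"""Scaffold clustering of compounds by circular feature-class fingerprints.

Fingerprints are feature-class circular fingerprints of radius 3 (diameter
6) folded to a fixed bit length. Distances are Tanimoto; clustering is
PAM-style k-medoids where each center is the member minimizing the
root-mean-square Tanimoto distance to its cluster. Identical canonical
structures yield identical fingerprints; tautomer-insensitive
canonicalization is NOT promised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats_core import DomainError

__all__ = [
    "Fingerprint",
    "ClusterResult",
    "SmilesParseError",
    "fingerprint_from_smiles",
    "tanimoto_distance",
    "distance_matrix",
    "cluster",
    "read_smiles_file",
    "write_clusters",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass(frozen=True)
class Fingerprint:
    compound_id: str
    bits: np.ndarray  # fixed-length boolean vector

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    def __len__(self) -> int:
        return int(self.bits.size)


def fingerprint_from_smiles(
    smiles: str,
    radius: int = 3,
    n_bits: int = 2048,
    compound_id: Optional[str] = None,
) -> Fingerprint:
    """Folded feature-class circular fingerprint of a SMILES string."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius,
        fpSize=n_bits,
        atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
    )
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(fp.GetOnBits())] = True
    return Fingerprint(compound_id=compound_id or smiles, bits=bits)


def _as_bits(fp) -> np.ndarray:
    return fp.bits if isinstance(fp, Fingerprint) else np.asarray(fp, dtype=bool)


def tanimoto_distance(a, b) -> float:
    """1 - |a AND b| / |a OR b|; two all-zero vectors have distance 0."""
    av, bv = _as_bits(a), _as_bits(b)
    if av.size != bv.size:
        raise DomainError(f"fingerprint length mismatch ({av.size} vs {bv.size})")
    union = int(np.logical_or(av, bv).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(av, bv).sum())
    return 1.0 - inter / union


def distance_matrix(fingerprints: Sequence) -> np.ndarray:
    """Pairwise Tanimoto distances as a dense symmetric matrix."""
    bits = np.stack([_as_bits(f) for f in fingerprints]).astype(np.float64)
    inter = bits @ bits.T
    counts = bits.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist


@dataclass
class ClusterResult:
    labels: np.ndarray  # cluster index per compound
    medoids: list[int]  # member index of each cluster center
    objective: float  # overall RMS distance of members to their medoid
    within_rms: list[float]  # per-cluster RMS distance to the medoid

    @property
    def k(self) -> int:
        return len(self.medoids)


def _objective(dist2: np.ndarray, medoids: np.ndarray, labels: np.ndarray) -> float:
    total = sum(dist2[i, medoids[labels[i]]] for i in range(dist2.shape[0]))
    return float(np.sqrt(total / dist2.shape[0]))


def cluster(
    fingerprints: Sequence,
    k: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    n_restarts: int = 10,
) -> ClusterResult:
    """Partition compounds into k groups under Tanimoto distance.

    Alternating k-medoids: points join their nearest medoid, each medoid
    moves to the member minimizing the within-cluster RMS distance. The
    RMS objective never increases across iterations. Several seeded
    restarts guard against poor initializations; the best objective wins,
    and the result is deterministic given the seed.
    """
    n = len(fingerprints)
    if k < 1 or k > n:
        raise DomainError(f"k={k} outside [1, {n}]")
    dist = distance_matrix(fingerprints)
    dist2 = dist**2
    best: Optional[ClusterResult] = None
    for restart in range(max(1, n_restarts)):
        result = _cluster_once(dist, dist2, k, [seed, restart], max_iter)
        if best is None or result.objective < best.objective - 1e-15:
            best = result
    return best


def _cluster_once(
    dist: np.ndarray, dist2: np.ndarray, k: int, seed, max_iter: int
) -> ClusterResult:
    n = dist.shape[0]
    rng = np.random.default_rng(seed)

    # k-medoids++ style seeding on squared distances
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        d2 = dist2[:, medoids].min(axis=1)
        total = d2.sum()
        if total <= 0:  # duplicate points: fall back to unchosen indices
            remaining = [i for i in range(n) if i not in medoids]
            medoids.append(remaining[0])
            continue
        medoids.append(int(rng.choice(n, p=d2 / total)))
    medoids = np.array(sorted(set(medoids)), dtype=int)
    while medoids.size < k:  # degenerate duplicates in seeding
        extra = [i for i in range(n) if i not in medoids][0]
        medoids = np.append(medoids, extra)

    labels = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                # revive with the point farthest from its current medoid
                far = int(np.argmax(dist2[np.arange(n), medoids[labels]]))
                new_medoids[c] = far
                continue
            within = dist2[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = int(members[np.argmin(within)])
        new_labels = np.argmin(dist[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels

    within_rms = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            within_rms.append(0.0)
        else:
            within_rms.append(float(np.sqrt(dist2[members, medoids[c]].mean())))
    return ClusterResult(
        labels=labels.astype(int),
        medoids=[int(m) for m in medoids],
        objective=_objective(dist2, medoids, labels),
        within_rms=within_rms,
    )


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read compound_id<TAB>SMILES rows (header optional)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "compound_id":
                continue
            if len(fields) < 2:
                raise DomainError(f"{path}: malformed SMILES line: {line[:60]!r}")
            rows.append((fields[0], fields[1]))
    return rows


def write_clusters(
    fingerprints: Sequence[Fingerprint],
    result: ClusterResult,
    out_dir: str | Path,
    header_comment: str | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [f.compound_id for f in fingerprints]
    df = pd.DataFrame(
        {
            "compound_id": ids,
            "cluster": result.labels,
            "is_center": [i in result.medoids for i in range(len(ids))],
        }
    )
    prefix = f"# {header_comment}\n" if header_comment else ""
    with open(out / "clusters.tsv", "w") as fh:
        fh.write(prefix)
        df.to_csv(fh, sep="\t", index=False)
    with open(out / "cluster_centers.tsv", "w") as fh:
        fh.write(prefix)
        fh.write("cluster\tcenter_compound_id\twithin_rms\n")
        for c, m in enumerate(result.medoids):
            fh.write(f"{c}\t{ids[m]}\t{result.within_rms[c]:.6f}\n")
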