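"""Protein family construction: genome filters, Markov clustering of the
similarity graph, family-level filters, single-copy core-marker selection and
BLOSUM62 medoid computation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence
import warnings

import networkx as nx
import numpy as np
import pandas as pd


class FamilyError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    gene_id: str
    genome_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self):
        if self.length < 1:
            raise FamilyError(f"{self.gene_id}: length must be >= 1")


@dataclass
class Family:
    family_id: str
    members: tuple[str, ...]
    copy_counts: dict[str, int] = field(default_factory=dict)
    is_core: bool = False
    medoid: str | None = None

    def __post_init__(self):
        if not self.members:
            raise FamilyError(f"{self.family_id}: family has no members")

    @property
    def size(self) -> int:
        return len(self.members)

    def genomes(self) -> set[str]:
        return set(self.copy_counts)


# ---------------------------------------------------------------------------
# genome filter

def filter_genomes(metadata: pd.DataFrame, min_completeness: float = 45.0,
                   max_contamination: float = 10.0) -> set[str]:
    """Genomes with completeness strictly above ``min_completeness`` and
    contamination strictly below ``max_contamination``.

    Thresholds are interpreted on the same scale as the table columns.
    """
    for col in ("genome_id", "completeness", "contamination"):
        if col not in metadata.columns:
            raise FamilyError(f"metadata is missing column '{col}'")
    bad = metadata[metadata[["completeness", "contamination"]].isna().any(axis=1)]
    if len(bad):
        names = ", ".join(bad["genome_id"].astype(str))
        raise FamilyError(f"missing completeness/contamination for: {names}")
    keep = metadata[(metadata["completeness"] > min_completeness)
                    & (metadata["contamination"] < max_contamination)]
    return set(keep["genome_id"])


# ---------------------------------------------------------------------------
# Markov clustering

def _mcl(matrix: np.ndarray, inflation: float, expansion: int = 2,
         max_iter: int = 200, tol: float = 1e-8,
         prune: float = 1e-12) -> np.ndarray:
    """Run Markov clustering on a column-stochastic transition matrix."""
    M = matrix / matrix.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        M = M / M.sum(axis=0, keepdims=True)
        if np.abs(M - prev).max() < tol:
            break
    return M


def cluster_families(proteins: Sequence[ProteinRecord], hits: pd.DataFrame,
                     min_pct_id: float = 35.0,
                     inflation: float = 1.5) -> list[Family]:
    """Cluster proteins into families by MCL on the thresholded hit graph.

    Edges below ``min_pct_id`` percent identity are discarded; the remaining
    bitscore-weighted graph is symmetrized (max of the two directions),
    self-loop augmented, and clustered with expansion 2 and the given
    inflation. Every protein ends up in exactly one family; proteins with no
    qualifying edges become singletons.
    """
    ids = sorted({p.gene_id for p in proteins})
    if len(ids) != len(proteins):
        raise FamilyError("duplicate gene_id among proteins")
    genome_of = {p.gene_id: p.genome_id for p in proteins}
    idx = {g: i for i, g in enumerate(ids)}
    n = len(ids)

    if len(hits) == 0:
        warnings.warn("empty hit table: every protein becomes its own family")
        strong = hits
    else:
        unknown = set(hits["qseqid"]) | set(hits["sseqid"])
        unknown -= set(ids)
        if unknown:
            raise FamilyError(
                f"hits reference unknown proteins: {sorted(unknown)[:5]}")
        strong = hits[hits["pident"] >= min_pct_id]

    A = np.zeros((n, n))
    for q, s, b in zip(strong["qseqid"], strong["sseqid"], strong["bitscore"]):
        if q == s:
            continue
        i, j = idx[q], idx[s]
        w = float(b)
        if w > A[i, j]:
            A[i, j] = w
    A = np.maximum(A, A.T)
    loops = A.max(axis=1)
    loops[loops == 0] = 1.0
    np.fill_diagonal(A, loops)

    M = _mcl(A, inflation=inflation)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    src, dst = np.nonzero(M > 1e-6)
    G.add_edges_from(zip(src.tolist(), dst.tolist()))
    comps = sorted((sorted(ids[i] for i in comp)
                    for comp in nx.connected_components(G)),
                   key=lambda c: c[0])
    out = []
    for k, members in enumerate(comps):
        counts: dict[str, int] = {}
        for g in members:
            counts[genome_of[g]] = counts.get(genome_of[g], 0) + 1
        out.append(Family(family_id=f"FAM{k + 1:05d}", members=tuple(members),
                          copy_counts=counts))
    return out


# ---------------------------------------------------------------------------
# family filters

def filter_families(families: Iterable[Family],
                    proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
                    min_len: int = 30, min_members: int = 4) -> list[Family]:
    """Drop members shorter than ``min_len`` residues, then drop families left
    with fewer than ``min_members`` members (in that order)."""
    if not isinstance(proteins, Mapping):
        proteins = {p.gene_id: p for p in proteins}
    out = []
    for fam in families:
        keep = tuple(g for g in fam.members if proteins[g].length >= min_len)
        if len(keep) < min_members:
            continue
        counts: dict[str, int] = {}
        for g in keep:
            gm = proteins[g].genome_id
            counts[gm] = counts.get(gm, 0) + 1
        out.append(replace(fam, members=keep, copy_counts=counts))
    return out


def select_core_markers(families: Iterable[Family], kept_genomes: set[str],
                        completeness: Mapping[str, float],
                        near_complete_cutoff: float = 90.0,
                        presence_fraction: float = 0.85) -> list[Family]:
    """Flag single-copy families present in enough near-complete genomes.

    A family is core iff every genome carrying it carries exactly one copy,
    and it occurs in at least ``presence_fraction`` of the kept genomes whose
    completeness is >= ``near_complete_cutoff``.
    """
    near = sorted(g for g in kept_genomes
                  if completeness[g] >= near_complete_cutoff)
    if not near:
        raise FamilyError(
            f"no genome has completeness >= {near_complete_cutoff}; "
            "lower --near-complete")
    out = []
    for fam in families:
        single = all(c == 1 for c in fam.copy_counts.values())
        present = sum(1 for g in near if fam.copy_counts.get(g, 0) > 0)
        core = single and present / len(near) >= presence_fraction
        out.append(replace(fam, is_core=core))
    return out


# ---------------------------------------------------------------------------
# medoid

_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def _pair_distance(a: str, b: str, mat) -> float:
    """1 - S(a,b)/max(S(a,a), S(b,b)) over columns where neither has a gap."""
    sab = saa = sbb = 0.0
    shared = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        shared += 1
        sab += mat[x, y]
        saa += mat[x, x]
        sbb += mat[y, y]
    if shared == 0:
        return 1.0
    return 1.0 - sab / max(saa, sbb)


def compute_medoid(alignment: Mapping[str, str]) -> str:
    """Member minimizing summed BLOSUM62 distance to all other members.

    Ties are broken by lexicographically smallest gene id; a singleton family
    returns its only member.
    """
    if not alignment:
        raise FamilyError("cannot compute a medoid of an empty family")
    ids = sorted(alignment)
    lengths = {len(alignment[g]) for g in ids}
    if len(lengths) != 1:
        raise FamilyError("aligned sequences must all have equal length")
    if len(ids) == 1:
        return ids[0]
    mat = _blosum62()
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _pair_distance(alignment[ids[i]], alignment[ids[j]], mat)
            D[i, j] = D[j, i] = d
    sums = D.sum(axis=1)
    best = int(np.argmin(sums))  # argmin returns first index: lexicographic tie-break
    return ids[best]
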