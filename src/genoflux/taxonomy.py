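"""Average amino acid identity, rank assignment and group divergence.

Genus/species ranks come from single-linkage clustering of the AAI matrix at
strict thresholds; class/order/family ranks come from single-linkage
clustering of Pearson distances between patristic-distance profiles of the
species tree. Both schemes nest by construction.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .io import node_label


class TaxonomyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# AAI

def compute_aai(hits: pd.DataFrame,
                gene_to_genome: Mapping[str, str]) -> pd.DataFrame:
    """AAI matrix from a hit table: mean percent identity over reciprocal
    best hits (by bitscore) for each genome pair, symmetrized by averaging
    the two directions. Pairs with no RBH are left as NaN.
    """
    df = hits.copy()
    missing = [g for g in pd.unique(pd.concat([df["qseqid"], df["sseqid"]]))
               if g not in gene_to_genome]
    if missing:
        raise TaxonomyError(f"genes without genome mapping: {missing[:5]}")
    df["qgenome"] = df["qseqid"].map(gene_to_genome)
    df["sgenome"] = df["sseqid"].map(gene_to_genome)
    df = df[df["qgenome"] != df["sgenome"]]
    genomes = sorted(set(gene_to_genome.values()))

    # best subject per (query gene, subject genome): bitscore desc,
    # evalue asc, subject id asc
    df = df.sort_values(["qseqid", "sgenome", "bitscore", "evalue", "sseqid"],
                        ascending=[True, True, False, True, True])
    best = df.drop_duplicates(["qseqid", "sgenome"], keep="first")
    best_map = {(q, sg): (s, p) for q, sg, s, p in zip(
        best["qseqid"], best["sgenome"], best["sseqid"], best["pident"])}

    aai = pd.DataFrame(np.nan, index=genomes, columns=genomes, dtype=float)
    np.fill_diagonal(aai.values, 100.0)
    for i, g1 in enumerate(genomes):
        for g2 in genomes[i + 1:]:
            pids = []
            for (q, sg), (s, p) in best_map.items():
                if gene_to_genome[q] != g1 or sg != g2:
                    continue
                back = best_map.get((s, g1))
                if back is not None and back[0] == q:
                    pids.append(0.5 * (p + back[1]))
            if pids:
                val = float(np.mean(pids))
                aai.loc[g1, g2] = aai.loc[g2, g1] = val
    return aai


def missing_pairs(aai: pd.DataFrame) -> list[tuple[str, str]]:
    out = []
    for i, g1 in enumerate(aai.index):
        for g2 in aai.index[i + 1:]:
            if np.isnan(aai.loc[g1, g2]):
                out.append((g1, g2))
    return out


# ---------------------------------------------------------------------------
# single-linkage clustering at strict thresholds

def _components(genomes: list[str], connect) -> dict[str, int]:
    G = nx.Graph()
    G.add_nodes_from(genomes)
    for i, g1 in enumerate(genomes):
        for g2 in genomes[i + 1:]:
            if connect(g1, g2):
                G.add_edge(g1, g2)
    comps = sorted((sorted(c) for c in nx.connected_components(G)),
                   key=lambda c: c[0])
    return {g: k + 1 for k, comp in enumerate(comps) for g in comp}


def assign_species_genus(aai: pd.DataFrame, genus_cut: float = 70.0,
                         species_cut: float = 95.0) -> pd.DataFrame:
    """Single-linkage genus/species clusters at strict AAI thresholds.

    Two genomes share a species iff connected by a chain of pairs with
    AAI strictly above ``species_cut``; genus likewise at ``genus_cut``.
    """
    miss = missing_pairs(aai)
    if miss:
        raise TaxonomyError(f"AAI missing for pairs: {miss[:10]}")
    genomes = sorted(aai.index)
    genus = _components(genomes, lambda a, b: aai.loc[a, b] > genus_cut)
    species = _components(genomes, lambda a, b: aai.loc[a, b] > species_cut)
    return pd.DataFrame({
        "genome": genomes,
        "genus": [f"G{genus[g]}" for g in genomes],
        "species": [f"S{species[g]}" for g in genomes],
    }).set_index("genome")


def patristic_matrix(species_tree: dendropy.Tree) -> pd.DataFrame:
    pdm = species_tree.phylogenetic_distance_matrix()
    taxa = sorted(species_tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            d = pdm.patristic_distance(t1, t2)
            mat.loc[t1.label, t2.label] = mat.loc[t2.label, t1.label] = d
    return mat


def pearson_profile_distance(dist: pd.DataFrame, g1: str, g2: str) -> float:
    """1 - Pearson r between two genomes' patristic-distance profiles,
    excluding the two self entries."""
    others = [g for g in dist.index if g not in (g1, g2)]
    x = dist.loc[g1, others].to_numpy(dtype=float)
    y = dist.loc[g2, others].to_numpy(dtype=float)
    if len(others) < 2 or x.std() == 0 or y.std() == 0:
        return 0.0 if np.allclose(x, y) else 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def assign_upper_ranks(species_tree: dendropy.Tree,
                       class_cut: float = 0.34, order_cut: float = 0.13,
                       family_cut: float = 0.015,
                       genomes: Iterable[str] | None = None) -> pd.DataFrame:
    """Class/order/family clusters from single-linkage Pearson-distance
    clustering of patristic-distance profiles at strict cuts."""
    dist = patristic_matrix(species_tree)
    want = sorted(genomes) if genomes is not None else sorted(dist.index)
    absent = [g for g in want if g not in dist.index]
    if absent:
        raise TaxonomyError(f"tree is missing genomes: {absent}")
    dist = dist.loc[want, want]
    pd_cache: dict[tuple[str, str], float] = {}
    for i, g1 in enumerate(want):
        for g2 in want[i + 1:]:
            pd_cache[(g1, g2)] = pearson_profile_distance(dist, g1, g2)

    def connect_at(cut):
        return lambda a, b: pd_cache[(a, b) if a < b else (b, a)] < cut

    cls = _components(want, connect_at(class_cut))
    order = _components(want, connect_at(order_cut))
    fam = _components(want, connect_at(family_cut))
    return pd.DataFrame({
        "genome": want,
        "class": [f"C{cls[g]}" for g in want],
        "order": [f"O{order[g]}" for g in want],
        "family": [f"F{fam[g]}" for g in want],
    }).set_index("genome")


def assign_ranks(species_tree: dendropy.Tree, aai: pd.DataFrame,
                 **kwargs) -> pd.DataFrame:
    """Full rank table: class/order/family from the tree, genus/species from
    AAI. Cross-system conflicts are reported, not resolved."""
    upper = assign_upper_ranks(species_tree,
                               genomes=aai.index, **{
                                   k: v for k, v in kwargs.items()
                                   if k.endswith("_cut")})
    lower = assign_species_genus(aai, **{
        k: v for k, v in kwargs.items() if k.endswith("aai")})
    return upper.join(lower)


# ---------------------------------------------------------------------------
# divergence

def max_divergence(aai: pd.DataFrame, group: Iterable[str]) -> float:
    """100 minus the lowest pairwise AAI within the group (0 for singletons)."""
    members = sorted(set(group))
    if not members:
        raise TaxonomyError("empty group")
    absent = [g for g in members if g not in aai.index]
    if absent:
        raise TaxonomyError(f"genomes not in AAI matrix: {absent}")
    if len(members) == 1:
        return 0.0
    lo = min(aai.loc[g1, g2] for i, g1 in enumerate(members)
             for g2 in members[i + 1:])
    return 100.0 - float(lo)
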