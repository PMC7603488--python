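"""Branch-level aggregation of reconciliation events, ancestral proteome
content, expansion/contraction detection, completeness-corrected fate
analysis of originating families, and clade rate comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reconcile import _as_species_tree


class FluxError(ValueError):
    pass


# ---------------------------------------------------------------------------
# aggregation

def aggregate_events(reconciliations, species_tree) -> pd.DataFrame:
    """Sum per-branch duplication / loss / intra-LGT / origination counts over
    families and attach each node's ancestral proteome size."""
    sp = _as_species_tree(species_tree)
    table = pd.DataFrame(
        0, index=sp.postorder,
        columns=["dup", "loss", "intra_lgt", "orig", "proteome_size"])
    for rec in reconciliations:
        for b, n in rec.duplications.items():
            table.loc[b, "dup"] += n
        for b, n in rec.losses.items():
            table.loc[b, "loss"] += n
        for b, n in rec.transfers.items():
            table.loc[b, "intra_lgt"] += n
        table.loc[rec.origination, "orig"] += 1
        for b, n in rec.presence.items():
            table.loc[b, "proteome_size"] += n
    return table


def ancestral_content(reconciliations, species_tree) -> pd.DataFrame:
    """Node x family matrix of inferred copy numbers.

    The copy number of a family at a node is the number of its gene-tree
    lineages alive at that point of the species tree under the minimum-cost
    reconciliation; at the leaves (completeness 1) this equals the observed
    gene count.
    """
    sp = _as_species_tree(species_tree)
    fams = [rec.family_id for rec in reconciliations]
    mat = pd.DataFrame(0, index=sp.postorder, columns=fams)
    for rec in reconciliations:
        for node, n in rec.presence.items():
            mat.loc[node, rec.family_id] = n
    return mat


# ---------------------------------------------------------------------------
# expansions

@dataclass
class ExpansionReport:
    expanded: list[str]
    contracted: list[str]
    novel: list[str]


def detect_expansions(content: pd.DataFrame, species_tree, parent: str,
                      child: str, fold: float = 10.0) -> ExpansionReport:
    """Families whose copy number changes more than ``fold``-fold between a
    node and its immediate child (strict inequality).

    Families appearing from zero copies are reported as ``novel`` rather than
    as fold-expansions.
    """
    sp = _as_species_tree(species_tree)
    if sp.parent.get(child) != parent:
        raise FluxError(f"'{child}' is not an immediate child of '{parent}'")
    expanded, contracted, novel = [], [], []
    for fam in content.columns:
        p = int(content.loc[parent, fam])
        c = int(content.loc[child, fam])
        if p == 0 and c > 0:
            novel.append(fam)
        elif p >= 1 and c > fold * p:
            expanded.append(fam)
        elif c >= 1 and p > fold * c:
            contracted.append(fam)
    return ExpansionReport(expanded=expanded, contracted=contracted, novel=novel)


# ---------------------------------------------------------------------------
# fate of originating families

@dataclass
class FateSummary:
    origin_branch: str
    table: pd.DataFrame  # per lineage: n, raw/corrected % lost and % duplicated


def corrected_fate(copy_counts: pd.DataFrame,
                   completeness: Mapping[str, float]) -> pd.DataFrame:
    """Completeness-corrected loss/duplication fractions per genome.

    For genome ``g`` with completeness ``c`` over ``n`` origin families:
    raw lost fraction ``p_L = absent / n`` is corrected to
    ``clip((p_L - (1 - c)) / c, 0, 1)`` — a family present in an incomplete
    genome is falsely absent with probability ``1 - c`` — and raw duplicated
    fraction ``p_D = (copies >= 2) / n`` is corrected to ``clip(p_D / c, 0, 1)``.
    Values are reported as percentages.
    """
    n = copy_counts.shape[1]
    if n == 0:
        raise FluxError("no origin families: fate is undefined")
    rows = []
    for g in copy_counts.index:
        c = float(completeness.get(g, 1.0))
        if not 0 < c <= 1:
            raise FluxError(f"completeness for {g} must be in (0, 1]")
        counts = copy_counts.loc[g]
        raw_lost = float((counts == 0).sum()) / n
        raw_dup = float((counts >= 2).sum()) / n
        corr_lost = min(max((raw_lost - (1.0 - c)) / c, 0.0), 1.0)
        corr_dup = min(max(raw_dup / c, 0.0), 1.0)
        rows.append({
            "lineage": g, "n_families": n, "completeness": c,
            "pct_lost_raw": 100.0 * raw_lost, "pct_lost": 100.0 * corr_lost,
            "pct_dup_raw": 100.0 * raw_dup, "pct_dup": 100.0 * corr_dup,
        })
    return pd.DataFrame(rows).set_index("lineage")


def fate_of_families(origin_branch: str, reconciliations,
                     completeness: Mapping[str, float], species_tree,
                     groups: Mapping[str, str] | None = None) -> FateSummary:
    """Fate of the families originating on ``origin_branch`` in each extant
    descendant lineage (optionally pooled into genus-like groups).

    When pooling, a family counts as lost only if absent from every member and
    as duplicated if any member carries >= 2 copies; the pooled completeness
    is the probability that at least one member would observe the gene,
    ``1 - prod(1 - c_g)``.
    """
    sp = _as_species_tree(species_tree)
    if origin_branch not in sp.postorder:
        raise FluxError(f"unknown branch '{origin_branch}'")
    origin_recs = [r for r in reconciliations if r.origination == origin_branch]
    if not origin_recs:
        raise FluxError(f"no family originates on branch '{origin_branch}'")
    genomes = sorted(sp.leaves_under(origin_branch))
    counts = pd.DataFrame(
        {r.family_id: [r.presence.get(g, 0) for g in genomes]
         for r in origin_recs}, index=genomes)
    comp = {g: float(completeness.get(g, 1.0)) for g in genomes}
    if groups:
        pooled = {}
        pooled_comp = {}
        for grp in sorted(set(groups.get(g, g) for g in genomes)):
            members = [g for g in genomes if groups.get(g, g) == grp]
            pooled[grp] = counts.loc[members].max(axis=0)
            pooled_comp[grp] = 1.0 - float(
                np.prod([1.0 - comp[g] for g in members]))
        counts = pd.DataFrame(pooled).T
        comp = pooled_comp
    return FateSummary(origin_branch=origin_branch,
                       table=corrected_fate(counts, comp))


# ---------------------------------------------------------------------------
# clade rate comparison

_EVENT_CLASSES = ("all", "dup", "loss", "intra_lgt", "orig")


def compare_clade_rates(table: pd.DataFrame, clade_branches: Iterable[str],
                        event_class: str = "all", n_perm: int = 9999,
                        seed: int = 0) -> float:
    """Two-sided permutation p-value for a clade's mean per-branch event count
    differing from the rest of the tree.

    The clade label set is reassigned uniformly at random among branches
    ``n_perm`` times; the p-value uses the add-one correction
    ``(1 + #{|stat_perm| >= |stat_obs|}) / (1 + n_perm)``.
    """
    if event_class not in _EVENT_CLASSES:
        raise FluxError(f"event_class must be one of {_EVENT_CLASSES}")
    clade = sorted(set(clade_branches))
    branches = list(table.index)
    unknown = set(clade) - set(branches)
    if unknown:
        raise FluxError(f"unknown clade branches: {sorted(unknown)}")
    if not clade or len(clade) >= len(branches):
        raise FluxError("clade must be a non-empty proper subset of branches")
    if event_class == "all":
        counts = table[["dup", "loss", "intra_lgt", "orig"]].sum(axis=1)
    else:
        counts = table[event_class]
    values = counts.to_numpy(dtype=float)
    mask = np.array([b in set(clade) for b in branches])
    k = mask.sum()

    def stat(m):
        return values[m].mean() - values[~m].mean()

    obs = abs(stat(mask))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = np.zeros(len(branches), dtype=bool)
        perm[rng.choice(len(branches), size=k, replace=False)] = True
        if abs(stat(perm)) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# metadata arithmetic

def predicted_genome_size(measured_size: float, completeness: float) -> float:
    """Measured genome size corrected by the completeness fraction."""
    if not 0 < completeness <= 1:
        raise FluxError("completeness must be in (0, 1]")
    return measured_size / completeness


# ---------------------------------------------------------------------------
# export

def annotated_newick(species_tree, table: pd.DataFrame) -> str:
    """Newick string with per-branch event counts as bracketed comments."""
    sp = _as_species_tree(species_tree)

    def fmt(lab):
        row = table.loc[lab]
        return (f"[&dup={int(row['dup'])},loss={int(row['loss'])},"
                f"lgt={int(row['intra_lgt'])},orig={int(row['orig'])}]")

    def render(lab):
        kids = sp.children[lab]
        if not kids:
            return f"{lab}{fmt(lab)}"
        inner = ",".join(render(k) for k in kids)
        return f"({inner}){lab}{fmt(lab)}"

    return render(sp.root) + ";\n"
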