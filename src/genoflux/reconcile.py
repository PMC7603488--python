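"""Undated duplication-transfer-loss reconciliation by minimum-cost parsimony.

Each gene tree is mapped onto a rooted species tree with a dynamic program
over (gene node, species branch) pairs. Events are speciation (free),
duplication, transfer (restricted to incomparable branch pairs, credited to
the receiver) and loss; the branch where the gene-tree root maps is the
family's origination. Absence at a species leaf with completeness ``c`` is
charged ``loss_cost * c`` instead of the full loss cost, so incomplete
genomes are not over-penalized for unobserved genes.

Ties between equal-cost reconciliations are resolved by preferring fewer
transfers, then fewer duplications, then the lexicographically smallest
species branch at each choice point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import pandas as pd

from .io import label_internal_nodes, node_label

INF = float("inf")
_INFV = (INF, INF, INF)
_ZERO = (0.0, 0, 0)


class ReconciliationError(ValueError):
    pass


@dataclass(frozen=True)
class EventCosts:
    dup: float = 2.0
    transfer: float = 3.0
    loss: float = 1.0

    def __post_init__(self):
        if min(self.dup, self.transfer, self.loss) <= 0:
            raise ReconciliationError("all event costs must be > 0")


@dataclass
class Reconciliation:
    """One minimum-cost event history for a family."""

    family_id: str
    cost: float
    origination: str
    duplications: dict[str, int]
    transfers: dict[str, int]          # keyed by receiving branch
    losses: dict[str, int]
    presence: dict[str, int]           # copies alive at each species node
    events: list[tuple[str, str]] = field(default_factory=list)
    node_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def n_dup(self) -> int:
        return sum(self.duplications.values())

    @property
    def n_transfer(self) -> int:
        return sum(self.transfers.values())

    @property
    def n_loss(self) -> int:
        return sum(self.losses.values())

    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id, "cost": self.cost,
            "origination": self.origination,
            "duplications": self.duplications, "transfers": self.transfers,
            "losses": self.losses, "presence": self.presence,
            "events": [list(e) for e in self.events],
            "node_map": {k: list(v) for k, v in self.node_map.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Reconciliation":
        return cls(family_id=d["family_id"], cost=d["cost"],
                   origination=d["origination"],
                   duplications=dict(d["duplications"]),
                   transfers=dict(d["transfers"]), losses=dict(d["losses"]),
                   presence=dict(d["presence"]),
                   events=[tuple(e) for e in d["events"]],
                   node_map={k: tuple(v) for k, v in d["node_map"].items()})


# ---------------------------------------------------------------------------
# species tree indexing

class SpeciesTree:
    """Rooted species tree indexed for reconciliation.

    Every branch is named by the label of the node below it; the root label
    denotes the root stem. Internal nodes are labelled ``N1..`` in preorder
    when unlabelled.
    """

    def __init__(self, tree: dendropy.Tree):
        label_internal_nodes(tree)
        self.tree = tree
        self.postorder: list[str] = []
        self.children: dict[str, tuple[str, ...]] = {}
        self.parent: dict[str, str | None] = {}
        self.desc: dict[str, frozenset[str]] = {}
        for node in tree.postorder_node_iter():
            lab = node_label(node)
            if lab is None:
                raise ReconciliationError("species tree has an unlabelled node")
            if lab in self.children:
                raise ReconciliationError(f"duplicate species label '{lab}'")
            kids = tuple(node_label(c) for c in node.child_nodes())
            self.postorder.append(lab)
            self.children[lab] = kids
            d = {lab}
            for k in kids:
                d |= self.desc[k]
            self.desc[lab] = frozenset(d)
        for node in tree.preorder_node_iter():
            for c in node.child_nodes():
                self.parent[node_label(c)] = node_label(node)
        self.root = node_label(tree.seed_node)
        self.parent[self.root] = None
        self.leaves = {lab for lab in self.postorder if not self.children[lab]}
        self.labels_sorted = sorted(self.postorder)
        anc: dict[str, set[str]] = {}
        for lab in self.labels_sorted:
            a, p = set(), self.parent[lab]
            while p is not None:
                a.add(p)
                p = self.parent[p]
            anc[lab] = a
        self.incomparable: dict[str, tuple[str, ...]] = {}
        for lab in self.labels_sorted:
            inc = tuple(o for o in self.labels_sorted
                        if o != lab and o not in self.desc[lab]
                        and o not in anc[lab])
            self.incomparable[lab] = inc

    def sibling(self, lab: str) -> str | None:
        p = self.parent[lab]
        if p is None:
            return None
        sibs = [c for c in self.children[p] if c != lab]
        return sibs[0] if sibs else None

    def is_leaf(self, lab: str) -> bool:
        return lab in self.leaves

    def leaves_under(self, lab: str) -> set[str]:
        return {x for x in self.desc[lab] if x in self.leaves}


def _as_species_tree(tree) -> SpeciesTree:
    return tree if isinstance(tree, SpeciesTree) else SpeciesTree(tree)


# ---------------------------------------------------------------------------
# gene tree intake

class _GNode:
    __slots__ = ("gid", "genome", "children")

    def __init__(self, gid, genome=None, children=()):
        self.gid = gid
        self.genome = genome
        self.children = list(children)


def _gene_struct(tree: dendropy.Tree, species: SpeciesTree) -> _GNode:
    counter = [0]

    def build(node: dendropy.Node) -> _GNode:
        if node.is_leaf():
            label = node_label(node)
            genome = label.split("|", 1)[0]
            if genome not in species.leaves:
                raise ReconciliationError(
                    f"gene-tree leaf '{label}' maps to unknown genome '{genome}'")
            return _GNode(label, genome=genome)
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ReconciliationError(
                f"gene tree is not binary (node with {len(kids)} children)")
        counter[0] += 1
        return _GNode(f"g{counter[0]}", children=[build(k) for k in kids])

    return build(tree.seed_node)


def _postorder(root: _GNode) -> list[_GNode]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out[::-1]


def _unrooted_rootings(tree: dendropy.Tree, species: SpeciesTree) -> list[_GNode]:
    """All rootings of an unrooted gene tree, as rooted structures."""
    base = _gene_struct_any(tree, species)
    edges: list[tuple] = []
    adj: dict[int, list] = {}

    def index(node, parent):
        adj.setdefault(id(node), [])
        if parent is not None:
            adj[id(node)].append(parent)
            adj[id(parent)].append(node)
            edges.append((parent, node))
        for c in node.children:
            index(c, node)

    index(base, None)

    def hang(node, come_from) -> _GNode:
        kids = [n for n in adj[id(node)] if n is not come_from]
        if not kids:
            return _GNode(node.gid, genome=node.genome)
        if len(kids) == 1:
            return hang(kids[0], node)  # suppress the old root's unifurcation
        return _GNode(node.gid, children=[hang(k, node) for k in kids])

    rootings = []
    for a, b in edges:
        left = hang(a, b)
        right = hang(b, a)
        rootings.append(_GNode("root", children=[left, right]))
    return rootings


def _gene_struct_any(tree: dendropy.Tree, species: SpeciesTree) -> _GNode:
    counter = [0]

    def build(node):
        if node.is_leaf():
            label = node_label(node)
            genome = label.split("|", 1)[0]
            if genome not in species.leaves:
                raise ReconciliationError(
                    f"gene-tree leaf '{label}' maps to unknown genome '{genome}'")
            return _GNode(label, genome=genome)
        counter[0] += 1
        return _GNode(f"g{counter[0]}",
                      children=[build(k) for k in node.child_nodes()])

    return build(tree.seed_node)


# ---------------------------------------------------------------------------
# the dynamic program

def _vadd(*vs):
    c = t = d = 0
    for v in vs:
        if v[0] == INF:
            return _INFV
        c += v[0]
        t += v[1]
        d += v[2]
    return (c, t, d)


def reconcile_undated(gene_tree: dendropy.Tree, species_tree,
                      costs: EventCosts = EventCosts(),
                      completeness: Mapping[str, float] | None = None,
                      family_id: str = "", rooted: bool = True) -> Reconciliation:
    """Minimum-cost undated DTL reconciliation of one gene tree.

    ``completeness`` maps genome ids to fractions in (0, 1]; terminal loss
    costs are scaled by the genome's completeness. With ``rooted=False``
    every rooting of the gene tree is evaluated and the cheapest is kept.
    """
    sp = _as_species_tree(species_tree)
    comp = dict(completeness or {})
    for g, c in comp.items():
        if not 0 < c <= 1:
            raise ReconciliationError(f"completeness for {g} must be in (0, 1]")

    if rooted:
        roots = [_gene_struct(gene_tree, sp)]
    else:
        roots = _unrooted_rootings(gene_tree, sp)
        if not roots:  # single-leaf tree
            roots = [_gene_struct(gene_tree, sp)]

    best = None
    for groot in roots:
        rec = _reconcile_rooted(groot, sp, costs, comp, family_id)
        key = (rec.cost, rec.n_transfer, rec.n_dup)
        if best is None or key < (best.cost, best.n_transfer, best.n_dup):
            best = rec
    return best


def _reconcile_rooted(groot: _GNode, sp: SpeciesTree, costs: EventCosts,
                      comp: Mapping[str, float], family_id: str) -> Reconciliation:
    loss_w = {lab: (costs.loss * comp.get(lab, 1.0) if sp.is_leaf(lab)
                    else costs.loss) for lab in sp.postorder}
    S = sp.postorder
    c: dict[int, dict[str, tuple]] = {}
    inn: dict[int, dict[str, tuple]] = {}
    choice_c: dict[tuple[int, str], tuple] = {}
    choice_in: dict[tuple[int, str], str | None] = {}

    gpost = _postorder(groot)
    for g in gpost:
        cg: dict[str, tuple] = {}
        if not g.children:
            for s in S:
                cg[s] = _ZERO if s == g.genome else _INFV
                choice_c[(id(g), s)] = ("leaf",)
        else:
            a, b = g.children
            out_a = _best_out(c[id(a)], sp)
            out_b = _best_out(c[id(b)], sp)
            for s in S:
                best_v, best_ch = _INFV, None
                kids = sp.children[s]
                cands = []
                if kids:
                    l, r = kids
                    cands.append((_vadd(inn[id(a)][l], inn[id(b)][r]),
                                  ("S", l, r)))
                    cands.append((_vadd(inn[id(a)][r], inn[id(b)][l]),
                                  ("S", r, l)))
                cands.append((_vadd((costs.dup, 0, 1), inn[id(a)][s],
                                    inn[id(b)][s]), ("D",)))
                va, src_a = out_a[s]
                vb, src_b = out_b[s]
                cands.append((_vadd((costs.transfer, 1, 0), inn[id(a)][s], vb),
                              ("T", "b", src_b)))
                cands.append((_vadd((costs.transfer, 1, 0), inn[id(b)][s], va),
                              ("T", "a", src_a)))
                for v, ch in cands:
                    if v < best_v:
                        best_v, best_ch = v, ch
                cg[s] = best_v
                choice_c[(id(g), s)] = best_ch
        c[id(g)] = cg
        ig: dict[str, tuple] = {}
        for s in S:  # postorder: children before parents
            best_v, best_ch = cg[s], None
            for ch in sorted(sp.children[s]):
                sib = sp.sibling(ch)
                cand = _vadd(ig[ch], (loss_w[sib], 0, 0))
                if cand < best_v:
                    best_v, best_ch = cand, ch
            ig[s] = best_v
            choice_in[(id(g), s)] = best_ch
        inn[id(g)] = ig

    root_v, root_s = _INFV, None
    for s in sp.labels_sorted:
        if c[id(groot)][s] < root_v:
            root_v, root_s = c[id(groot)][s], s
    if root_s is None:
        raise ReconciliationError("gene tree cannot be reconciled")

    # ---- backtrack ------------------------------------------------------
    dup: dict[str, int] = {}
    tra: dict[str, int] = {}
    los: dict[str, int] = {}
    presence: dict[str, int] = {}
    events: list[tuple[str, str]] = []
    node_map: dict[str, tuple[str, str]] = {}

    def resolve_c(g: _GNode, s: str):
        ch = choice_c[(id(g), s)]
        kind = ch[0]
        if kind == "leaf":
            presence[s] = presence.get(s, 0) + 1
            node_map[g.gid] = ("leaf", s)
            return
        a, b = g.children
        if kind == "S":
            presence[s] = presence.get(s, 0) + 1
            node_map[g.gid] = ("speciation", s)
            resolve_in(a, ch[1])
            resolve_in(b, ch[2])
        elif kind == "D":
            dup[s] = dup.get(s, 0) + 1
            events.append(("D", s))
            node_map[g.gid] = ("duplication", s)
            resolve_in(a, s)
            resolve_in(b, s)
        else:  # transfer: one child stays, the other lands on ch[2]
            recv = ch[2]
            tra[recv] = tra.get(recv, 0) + 1
            events.append(("T", recv))
            node_map[g.gid] = ("transfer", s)
            if ch[1] == "b":
                resolve_in(a, s)
                resolve_c(b, recv)
            else:
                resolve_in(b, s)
                resolve_c(a, recv)

    def resolve_in(g: _GNode, s: str):
        while True:
            ch = choice_in[(id(g), s)]
            if ch is None:
                resolve_c(g, s)
                return
            presence[s] = presence.get(s, 0) + 1
            sib = sp.sibling(ch)
            los[sib] = los.get(sib, 0) + 1
            events.append(("L", sib))
            s = ch

    resolve_c(groot, root_s)
    events.append(("O", root_s))
    return Reconciliation(
        family_id=family_id, cost=root_v[0], origination=root_s,
        duplications=dup, transfers=tra, losses=los, presence=presence,
        events=events, node_map=node_map)


def _best_out(c_row: Mapping[str, tuple], sp: SpeciesTree):
    """For each branch s, the cheapest mapping on a branch incomparable to s."""
    out: dict[str, tuple] = {}
    for s in sp.postorder:
        best_v, best_s = _INFV, None
        for o in sp.incomparable[s]:
            if c_row[o] < best_v:
                best_v, best_s = c_row[o], o
        out[s] = (best_v, best_s)
    return out


# ---------------------------------------------------------------------------
# gain classification

def classify_gains(reconciliations, species_tree) -> pd.DataFrame:
    """Per-branch decomposition of gains into duplication / intra-LGT /
    origination.

    Every duplication is a gain on its branch, every transfer a gain on the
    receiving branch (all in-tree transfers count as intra-LGT), and every
    family contributes exactly one origination gain where its root maps.
    """
    sp = _as_species_tree(species_tree)
    table = pd.DataFrame(0, index=sp.postorder,
                         columns=["duplication", "intra_lgt", "origination"])
    for rec in reconciliations:
        for b, n in rec.duplications.items():
            if b not in table.index:
                raise ReconciliationError(
                    f"{rec.family_id}: branch '{b}' not in the species tree "
                    "(mixed species trees?)")
            table.loc[b, "duplication"] += n
        for b, n in rec.transfers.items():
            if b not in table.index:
                raise ReconciliationError(
                    f"{rec.family_id}: branch '{b}' not in the species tree "
                    "(mixed species trees?)")
            table.loc[b, "intra_lgt"] += n
        table.loc[rec.origination, "origination"] += 1
    return table


def gain_percentages(duplication: int, intra_lgt: int,
                     origination: int) -> dict:
    """Total gains and integer-rounded percentage per gain mechanism."""
    total = duplication + intra_lgt + origination
    if total <= 0:
        raise ReconciliationError("no gains to summarize")

    def pct(x):
        return int(math.floor(100.0 * x / total + 0.5))

    return {
        "total": total,
        "pct_duplication": pct(duplication),
        "pct_intra_lgt": pct(intra_lgt),
        "pct_origination": pct(origination),
    }
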