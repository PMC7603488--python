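"""Forward simulation of gene-family evolution along a species tree.

Gene families originate once on the tree and then evolve by per-copy
duplication, transfer and loss as competing exponential processes along
branches. The simulator records the exact per-branch event tallies and
per-node copy numbers (:class:`TrueHistory`), the copy genealogies (gene
trees), protein sequences under a uniform 20-state replacement model, and a
probabilistic observation-loss step that mimics genome incompleteness.

Every branch of the species tree is identified by the label of the node
below it; the root label stands for the root stem.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .io import label_internal_nodes, node_label, tree_newick

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EvolParams:
    """Rates and sizes governing one simulated dataset.

    Rates are per gene copy per unit branch length; ``origination`` selects
    how the single origination branch of each family is drawn (``"length"``:
    proportional to branch length; ``"root"``: always the root stem).
    """

    n_families: int = 100
    origination_rate: float = 1.0
    dup_rate: float = 0.1
    transfer_rate: float = 0.05
    loss_rate: float = 0.1
    seq_length: int = 200
    subst_rate: float = 0.5
    seed: int = 0
    origination: str = "length"
    condition_on_survival: bool = False

    def __post_init__(self):
        if self.n_families < 1:
            raise SimulationError("n_families must be >= 1")
        if self.seq_length < 1:
            raise SimulationError("seq_length must be >= 1")
        for name in ("origination_rate", "dup_rate", "transfer_rate",
                     "loss_rate", "subst_rate"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.origination not in ("length", "root"):
            raise SimulationError("origination must be 'length' or 'root'")


@dataclass
class TrueHistory:
    """Exact per-branch event tallies and per-node copy numbers."""

    branch_events: dict[str, dict[str, int]]
    copy_number: dict[tuple[str, str], int]

    def counts(self, branch: str) -> dict[str, int]:
        return self.branch_events.get(branch, {"o": 0, "d": 0, "t": 0, "l": 0})

    def copies(self, node: str, family: str) -> int:
        return self.copy_number.get((node, family), 0)

    def as_frame(self) -> pd.DataFrame:
        rows = [{"branch_id": b, **ev}
                for b, ev in sorted(self.branch_events.items())]
        return pd.DataFrame(rows, columns=["branch_id", "o", "d", "t", "l"])


@dataclass
class SimulatedDataset:
    """Species tree, gene trees, proteomes, metadata and ground truth."""

    species_tree: dendropy.Tree
    gene_trees: dict[str, dendropy.Tree | None]
    proteomes: dict[str, list[str]]
    gene_genome: dict[str, str]
    gene_family: dict[str, str]
    metadata: pd.DataFrame
    true_history: TrueHistory
    alignments: dict[str, dict[str, str]] | None = None

    @property
    def genomes(self) -> list[str]:
        return sorted(self.proteomes)

    def observed_gene_trees(self) -> dict[str, dendropy.Tree]:
        """Gene trees of families with at least one surviving, observed copy."""
        return {f: t for f, t in self.gene_trees.items()
                if t is not None and sum(1 for _ in t.leaf_node_iter()) >= 1}


# ---------------------------------------------------------------------------
# species tree

def simulate_species_tree(n_taxa: int, birth: float = 1.0, death: float = 0.0,
                          seed: int = 0) -> dendropy.Tree:
    """Sample a rooted binary birth-death tree with ``n_taxa`` extant leaves.

    Leaves are relabelled ``T01..`` and internal nodes ``N1..`` (preorder);
    all branch lengths are strictly positive and the result is a
    deterministic function of ``seed``.
    """
    if n_taxa < 2:
        raise SimulationError("n_taxa must be >= 2")
    if not birth > death or death < 0:
        raise SimulationError("need birth > death >= 0")
    from dendropy.model import birthdeath

    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=n_taxa, rng=rng)
    tree.seed_node.edge.length = None
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"T{i + 1:02d}"
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None or node.edge.length <= 0:
            # degenerate zero-length branches can arise when the stopping
            # condition coincides with a birth; nudge them positive
            node.edge.length = 1e-6 + rng.random() * 1e-6
    label_internal_nodes(tree)
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if n_leaves != n_taxa:
        raise SimulationError(f"simulated {n_leaves} leaves, expected {n_taxa}")
    return tree


# ---------------------------------------------------------------------------
# gene content

def _species_index(tree: dendropy.Tree):
    """Per-node label, descendant sets and incomparable branch lists."""
    label_internal_nodes(tree)
    desc: dict[int, set[str]] = {}
    for node in tree.postorder_node_iter():
        s = {node_label(node)}
        for ch in node.child_nodes():
            s |= desc[id(ch)]
        desc[id(node)] = s
    anc: dict[int, set[str]] = {}
    for node in tree.preorder_node_iter():
        p = node.parent_node
        anc[id(node)] = set() if p is None else anc[id(p)] | {node_label(p)}
    branches = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    incomparable: dict[int, list[dendropy.Node]] = {}
    for node in branches:
        lab = node_label(node)
        incomparable[id(node)] = [
            b for b in branches
            if node_label(b) != lab
            and node_label(b) not in desc[id(node)]
            and node_label(b) not in anc[id(node)]
            and lab not in desc[id(b)]
        ]
    return branches, incomparable


def simulate_gene_content(tree: dendropy.Tree, params: EvolParams) -> SimulatedDataset:
    """Evolve ``params.n_families`` families along ``tree``.

    Each family originates exactly once, then every copy independently
    duplicates, transfers (to a uniformly drawn incomparable branch, credited
    to the receiver) or dies along branches. Gene trees record the realized
    copy genealogy; tallies and per-node copy numbers are exact.
    """
    rng = np.random.default_rng((params.seed, 0))
    branches, incomparable = _species_index(tree)
    root = tree.seed_node
    root_label = node_label(root)
    all_labels = [node_label(n) for n in tree.preorder_node_iter()]

    if (params.dup_rate == 0 and params.transfer_rate == 0
            and params.loss_rate == 0 and params.origination_rate == 0):
        import warnings
        warnings.warn("all event rates are zero: dataset will be static")

    lengths = np.array([n.edge.length for n in branches])
    total_rate = params.dup_rate + params.transfer_rate + params.loss_rate

    branch_events = {lab: {"o": 0, "d": 0, "t": 0, "l": 0} for lab in all_labels}
    copy_number: dict[tuple[str, str], int] = {}
    proteomes: dict[str, list[str]] = {node_label(lf): []
                                       for lf in tree.leaf_node_iter()}
    gene_genome: dict[str, str] = {}
    gene_family: dict[str, str] = {}
    gene_trees: dict[str, dendropy.Tree | None] = {}

    max_attempts = 1000
    for fi in range(params.n_families):
        fam = f"F{fi + 1:05d}"
        serial = [0]
        # per-attempt buffers, merged into the dataset only when the family
        # history is accepted (matters when conditioning on survival)
        ev: dict[str, dict[str, int]] = {}
        cn: dict[tuple[str, str], int] = {}
        new_genes: list[tuple[str, str]] = []

        def bump(lab: str, kind: str):
            ev.setdefault(lab, {"o": 0, "d": 0, "t": 0, "l": 0})[kind] += 1

        def new_gene(genome: str) -> str:
            serial[0] += 1
            gid = f"{fam}.{serial[0]}"
            new_genes.append((gid, genome))
            return gid

        def copy_on_branch(node: dendropy.Node, pos: float):
            """Evolve one copy from ``pos`` on the branch above ``node``.

            Returns ``(gene_node, pending_edge_length)`` or ``None`` if the
            lineage leaves no surviving descendants.
            """
            length = node.edge.length
            t = pos
            while True:
                wait = (rng.exponential(1.0 / total_rate)
                        if total_rate > 0 else np.inf)
                if t + wait >= length:
                    return at_node(node, pos)
                t += wait
                u = rng.random() * total_rate
                if u < params.loss_rate:
                    bump(node_label(node), "l")
                    return None
                if u < params.loss_rate + params.dup_rate:
                    bump(node_label(node), "d")
                    return join(copy_on_branch(node, t),
                                copy_on_branch(node, t), t - pos)
                # transfer
                recipients = incomparable[id(node)]
                if not recipients:
                    continue  # nowhere to go on this branch; no event
                recv = recipients[rng.integers(len(recipients))]
                bump(node_label(recv), "t")
                rpos = rng.random() * recv.edge.length
                return join(copy_on_branch(node, t),
                            copy_on_branch(recv, rpos), t - pos)

        def at_node(node: dendropy.Node, pos: float):
            """Copy reaches the bottom of its branch (the node itself)."""
            lab = node_label(node)
            cn[(lab, fam)] = cn.get((lab, fam), 0) + 1
            span = node.edge.length - pos if node.edge.length is not None else 0.0
            if node.is_leaf():
                gid = new_gene(lab)
                leaf = dendropy.Node()
                leaf._gx_label = f"{lab}|{gid}"
                return leaf, span
            kids = [copy_on_branch(ch, 0.0) for ch in node.child_nodes()]
            alive = [k for k in kids if k is not None]
            if not alive:
                return None
            if len(alive) == 1:
                sub, d = alive[0]
                return sub, span + d
            return join(alive[0], alive[1], span)

        def join(left, right, pending: float):
            """Bind two resolved child lineages under a new gene-tree node."""
            if left is None and right is None:
                return None
            if left is None or right is None:
                sub, d = left if left is not None else right
                return sub, pending + d
            parent = dendropy.Node()
            for sub, d in (left, right):
                parent.add_child(sub)
                sub.edge.length = d
            return parent, pending

        result = None
        for _attempt in range(max_attempts):
            ev.clear()
            cn.clear()
            new_genes.clear()
            serial[0] = 0
            if params.origination == "root":
                bump(root_label, "o")
                result = at_node(root, 0.0)
            else:
                probs = lengths / lengths.sum()
                bi = rng.choice(len(branches), p=probs)
                bnode = branches[bi]
                bump(node_label(bnode), "o")
                pos = rng.random() * bnode.edge.length
                result = copy_on_branch(bnode, pos)
            if result is not None or not params.condition_on_survival:
                break
        else:
            raise SimulationError(
                f"{fam}: no surviving history in {max_attempts} attempts; "
                "loss rate is too high to condition on survival")

        for lab, kinds in ev.items():
            for k, n in kinds.items():
                branch_events[lab][k] += n
        copy_number.update(cn)
        for gid, genome in new_genes:
            proteomes[genome].append(gid)
            gene_genome[gid] = genome
            gene_family[gid] = fam
        if result is None:
            gene_trees[fam] = None
            continue
        gnode, _ = result
        gene_trees[fam] = _to_gene_tree(gnode)

    metadata = pd.DataFrame({
        "genome_id": sorted(proteomes),
        "completeness": 1.0,
        "contamination": 0.0,
        "size_bp": [1000 * len(proteomes[g]) for g in sorted(proteomes)],
    })
    history = TrueHistory(branch_events=branch_events, copy_number=copy_number)
    return SimulatedDataset(
        species_tree=tree, gene_trees=gene_trees, proteomes=proteomes,
        gene_genome=gene_genome, gene_family=gene_family,
        metadata=metadata, true_history=history)


def _to_gene_tree(gnode: dendropy.Node) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = gnode
    gnode.edge.length = None
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tns.new_taxon(getattr(leaf, "_gx_label"))
    return tree


# ---------------------------------------------------------------------------
# incompleteness degradation

def degrade_completeness(dataset: SimulatedDataset,
                         completeness_map: dict[str, float],
                         seed: int = 0) -> SimulatedDataset:
    """Drop each gene of genome ``g`` independently with probability ``1-c_g``.

    Metadata records the assigned completeness; the ground-truth history is
    carried over unchanged (truth is pre-degradation).
    """
    for g, c in completeness_map.items():
        if not 0 < c <= 1:
            raise SimulationError(f"completeness for {g} must be in (0, 1]")
    rng = np.random.default_rng((seed, 17))
    kept: set[str] = set()
    proteomes: dict[str, list[str]] = {}
    for g in sorted(dataset.proteomes):
        c = completeness_map.get(g, 1.0)
        genes = []
        for gid in sorted(dataset.proteomes[g]):
            if rng.random() < c:
                genes.append(gid)
                kept.add(gid)
        proteomes[g] = genes

    gene_trees = {}
    for fam in sorted(dataset.gene_trees):
        tree = dataset.gene_trees[fam]
        gene_trees[fam] = None if tree is None else _prune_gene_tree(tree, kept)

    metadata = dataset.metadata.copy()
    comp = metadata["genome_id"].map(
        lambda g: completeness_map.get(g, 1.0)).astype(float)
    metadata["completeness"] = comp
    metadata["size_bp"] = (metadata["size_bp"] * comp).round().astype(int)

    alignments = None
    if dataset.alignments is not None:
        alignments = {
            fam: {gid: seq for gid, seq in aln.items() if gid in kept}
            for fam, aln in dataset.alignments.items()}

    return SimulatedDataset(
        species_tree=dataset.species_tree, gene_trees=gene_trees,
        proteomes=proteomes,
        gene_genome={g: v for g, v in dataset.gene_genome.items() if g in kept},
        gene_family={g: v for g, v in dataset.gene_family.items() if g in kept},
        metadata=metadata, true_history=dataset.true_history,
        alignments=alignments)


def _prune_gene_tree(tree: dendropy.Tree, kept: set[str]) -> dendropy.Tree | None:
    """Rebuild ``tree`` keeping only leaves whose gene id is in ``kept``."""

    def rebuild(node: dendropy.Node):
        if node.is_leaf():
            label = node_label(node)
            gid = label.split("|", 1)[1]
            if gid not in kept:
                return None
            nn = dendropy.Node()
            nn._gx_label = label
            return nn, (node.edge.length or 0.0)
        subs = [rebuild(ch) for ch in node.child_nodes()]
        subs = [s for s in subs if s is not None]
        if not subs:
            return None
        base = node.edge.length or 0.0
        if len(subs) == 1:
            sub, d = subs[0]
            return sub, base + d
        nn = dendropy.Node()
        for sub, d in subs:
            nn.add_child(sub)
            sub.edge.length = d
        return nn, base
    result = rebuild(tree.seed_node)
    if result is None:
        return None
    return _to_gene_tree(result[0])


# ---------------------------------------------------------------------------
# sequences

def simulate_sequences(dataset: SimulatedDataset,
                       params: EvolParams) -> SimulatedDataset:
    """Evolve gap-free aligned protein sequences along each gene tree.

    The model is uniform 20-state replacement: each site substitutes at rate
    ``subst_rate`` per unit branch length, jumping to one of the 19 other
    residues uniformly. Expected identity between two leaves at total path
    distance d is ``0.05 + 0.95 * exp(-(20/19) * subst_rate * d)``.
    """
    rng = np.random.default_rng((params.seed, 1))
    L = params.seq_length
    alignments: dict[str, dict[str, str]] = {}
    for fam in sorted(dataset.gene_trees):
        tree = dataset.gene_trees[fam]
        if tree is None:
            continue
        aln: dict[str, str] = {}
        root_seq = rng.integers(0, 20, size=L)

        def descend(node: dendropy.Node, seq: np.ndarray):
            if node.is_leaf():
                gid = node_label(node).split("|", 1)[1]
                aln[gid] = "".join(AMINO_ACIDS[i] for i in seq)
                return
            for ch in node.child_nodes():
                descend(ch, _mutate(seq, (ch.edge.length or 0.0)
                                    * params.subst_rate, rng))

        descend(tree.seed_node, root_seq)
        alignments[fam] = aln
    return replace(dataset, alignments=alignments)


def _mutate(seq: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if mu <= 0:
        return out
    hits = rng.poisson(mu, size=out.size)
    for idx in np.nonzero(hits)[0]:
        for _ in range(hits[idx]):
            step = rng.integers(0, 19)
            if step >= out[idx]:
                step += 1
            out[idx] = step
    return out


# ---------------------------------------------------------------------------
# derived tables

def all_vs_all_hits(dataset: SimulatedDataset,
                    min_report_pct_id: float = 25.0) -> pd.DataFrame:
    """Pairwise identity of every gene pair, as a 12-column hit table.

    Both hit directions are emitted (the table is symmetric); the bitscore is
    a monotone stand-in (2 x matching columns). Pairs below
    ``min_report_pct_id`` are omitted, mimicking a search reporting cutoff.
    """
    if dataset.alignments is None:
        raise SimulationError("simulate_sequences must run before all_vs_all_hits")
    genes = []
    for fam in sorted(dataset.alignments):
        for gid in sorted(dataset.alignments[fam]):
            genes.append((gid, dataset.alignments[fam][gid]))
    if not genes:
        return pd.DataFrame(columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"])
    ids = [g[0] for g in genes]
    mat = np.vstack([np.frombuffer(g[1].encode(), dtype=np.uint8)
                     for g in genes])
    L = mat.shape[1]
    rows = []
    for i in range(len(ids)):
        matches = (mat[i] == mat).sum(axis=1)
        pid = 100.0 * matches / L
        for j in np.nonzero(pid >= min_report_pct_id)[0]:
            if j == i:
                continue
            m = int(matches[j])
            rows.append((ids[i], ids[j], round(float(pid[j]), 2), L, L - m, 0,
                         1, L, 1, L, float(10.0 ** (-min(m / 4.0, 180.0))),
                         2.0 * m))
    return pd.DataFrame(rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore"])


def write_dataset(dataset: SimulatedDataset, out_dir: str) -> None:
    """Write the dataset as Newick / FASTA / TSV files under ``out_dir``."""
    import pathlib

    from .io import write_fasta, write_metadata, write_tree

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tree(dataset.species_tree, out / "species_tree.nwk")
    gt_dir = out / "gene_trees"
    gt_dir.mkdir(exist_ok=True)
    for fam, tree in sorted(dataset.gene_trees.items()):
        if tree is not None and sum(1 for _ in tree.leaf_node_iter()) >= 2:
            with open(gt_dir / f"{fam}.nwk", "w") as fh:
                fh.write(tree_newick(tree))
    prot_dir = out / "proteomes"
    prot_dir.mkdir(exist_ok=True)
    for g in dataset.genomes:
        seqs = {}
        for gid in sorted(dataset.proteomes[g]):
            fam = dataset.gene_family[gid]
            seq = ""
            if dataset.alignments and fam in dataset.alignments:
                seq = dataset.alignments[fam].get(gid, "")
            seqs[f"{g}|{gid}|{fam}"] = seq or "M"
        write_fasta(seqs, prot_dir / f"{g}.faa")
    write_metadata(dataset.metadata, out / "metadata.tsv")
    dataset.true_history.as_frame().to_csv(
        out / "true_history.tsv", sep="\t", index=False)
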