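"""Readers and writers for the plain-text formats used across the pipeline.

Trees are Newick (dendropy), proteins are FASTA (Biopython), tabular data
(similarity hits, metadata, family maps, event tables) are TSV handled with
pandas. Reconciliations round-trip through JSON.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: column order of the 12-column tabular hit format (BLAST outfmt 6 dialect)
HITS_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: optional trailing columns carrying taxonomic labels for annotation hits
HITS_TAXON_COLUMNS = ["subject_taxon_domain", "subject_taxon_phylum"]

METADATA_COLUMNS = ["genome_id", "completeness", "contamination", "size_bp"]


# ---------------------------------------------------------------------------
# trees

def node_label(node: dendropy.Node) -> str:
    """Label of a node: taxon label for leaves, node label for internals."""
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "N") -> dendropy.Tree:
    """Assign ``N1..Nk`` labels (preorder) to unlabelled internal nodes."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        i += 1
        if not node.label:
            node.label = f"{prefix}{i}"
    return tree


def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree_newick(tree))


def tree_newick(tree: dendropy.Tree) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True)
    return s.strip() + "\n"


# ---------------------------------------------------------------------------
# tabular

def read_hits(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 12-column hit table; two optional taxon columns are detected."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == len(HITS_COLUMNS):
        df.columns = HITS_COLUMNS
    elif df.shape[1] == len(HITS_COLUMNS) + 2:
        df.columns = HITS_COLUMNS + HITS_TAXON_COLUMNS
    else:
        raise ValueError(
            f"{path}: expected 12 or 14 tab-separated columns, got {df.shape[1]}")
    return df


def write_hits(hits: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in HITS_COLUMNS + HITS_TAXON_COLUMNS if c in hits.columns]
    hits[cols].to_csv(path, sep="\t", header=False, index=False)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata is missing columns {missing}")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | os.PathLike) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_term_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a two-column ``family_id<TAB>term_id`` map into family -> terms."""
    df = pd.read_csv(path, sep="\t", header=None, names=["family_id", "term_id"])
    out: dict[str, set[str]] = {}
    for fam, term in zip(df["family_id"], df["term_id"]):
        out.setdefault(str(fam), set()).add(str(term))
    return out


def read_families_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       names=["family_id", "gene_id", "genome_id"], header=0)


def write_families_tsv(rows: Iterable[tuple[str, str, str]],
                       path: str | os.PathLike) -> None:
    df = pd.DataFrame(rows, columns=["family_id", "gene_id", "genome_id"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# reconciliations

def write_reconciliations(recs, path: str | os.PathLike) -> None:
    payload = [rec.to_dict() for rec in recs]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_reconciliations(path: str | os.PathLike):
    from .reconcile import Reconciliation
    with open(path) as fh:
        payload = json.load(fh)
    return [Reconciliation.from_dict(d) for d in payload]
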