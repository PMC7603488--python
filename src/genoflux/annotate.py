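"""Homology-hit filtering, proteome novelty, origination-source
classification and ancestral function gain/loss."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .reconcile import _as_species_tree


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# hit filter

def filter_hits(hits: pd.DataFrame, max_evalue: float = 1e-5,
                min_pct_id: float = 35.0, min_aln_len: int = 80,
                min_bitscore: float = 100.0, best_hit: bool = False,
                min_posterior: float | None = None) -> pd.DataFrame:
    """Keep hits passing all thresholds; boundary values are kept.

    A hit survives iff evalue <= max_evalue, pident >= min_pct_id,
    length >= min_aln_len and bitscore >= min_bitscore. With ``best_hit``
    only the highest-bitscore qualifying hit per query is retained
    (ties: lowest evalue, then lexicographic subject). ``min_posterior``
    additionally thresholds an optional ``posterior`` column.
    """
    required = {"qseqid", "sseqid", "pident", "length", "evalue", "bitscore"}
    missing = required - set(hits.columns)
    if missing:
        raise AnnotationError(f"hit table is missing columns {sorted(missing)}")
    for col in ("pident", "length", "evalue", "bitscore"):
        if hits[col].isna().any():
            bad = hits.index[hits[col].isna()][0]
            raise AnnotationError(f"malformed hit row {bad}: NaN in '{col}'")
    keep = ((hits["evalue"] <= max_evalue)
            & (hits["pident"] >= min_pct_id)
            & (hits["length"] >= min_aln_len)
            & (hits["bitscore"] >= min_bitscore))
    if min_posterior is not None:
        if "posterior" not in hits.columns:
            raise AnnotationError("min_posterior given but no 'posterior' column")
        keep &= hits["posterior"] >= min_posterior
    out = hits[keep]
    if best_hit:
        out = out.sort_values(["qseqid", "bitscore", "evalue", "sseqid"],
                              ascending=[True, False, True, True])
        out = out.drop_duplicates("qseqid", keep="first")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# novelty

def proteome_novelty(proteomes: Mapping[str, Iterable[str]],
                     qualifying_hits: pd.DataFrame) -> pd.DataFrame:
    """Percentage of each genome's proteins with no qualifying hit.

    Novelty is invariant to duplicate hit rows: only the set of query ids
    with at least one qualifying hit matters.
    """
    with_hit = set(qualifying_hits["qseqid"])
    rows = []
    for g in sorted(proteomes):
        genes = list(proteomes[g])
        if not genes:
            raise AnnotationError(f"genome '{g}' has no proteins")
        n_hit = sum(1 for gid in genes if gid in with_hit)
        rows.append({
            "genome_id": g, "n_proteins": len(genes), "n_with_hit": n_hit,
            "novelty_pct": 100.0 * (len(genes) - n_hit) / len(genes),
        })
    return pd.DataFrame(rows).set_index("genome_id")


# ---------------------------------------------------------------------------
# origination sources

def classify_origination(medoids: Mapping[str, str],
                         external_hits: pd.DataFrame,
                         self_phylum: str) -> pd.DataFrame:
    """Lateral-vs-de-novo call per family from its medoid's external hits.

    Hits whose subject phylum equals ``self_phylum`` are discarded. A family
    with no remaining hit is 'de_novo'; otherwise the donor domain is taken
    from the best remaining hit (highest bitscore, then lowest evalue, then
    lexicographic subject id).
    """
    if "subject_taxon_domain" not in external_hits.columns:
        raise AnnotationError(
            "external hits need 'subject_taxon_domain' (and phylum) columns")
    hits = external_hits
    if "subject_taxon_phylum" in hits.columns:
        hits = hits[hits["subject_taxon_phylum"] != self_phylum]
    hits = hits.sort_values(["qseqid", "bitscore", "evalue", "sseqid"],
                            ascending=[True, False, True, True])
    best = hits.drop_duplicates("qseqid", keep="first")
    best_by_query = best.set_index("qseqid")
    rows = []
    for fam in sorted(medoids):
        medoid = medoids[fam]
        if medoid in best_by_query.index:
            rows.append({"family_id": fam, "origin": "lateral",
                         "donor_domain":
                             best_by_query.loc[medoid, "subject_taxon_domain"]})
        else:
            rows.append({"family_id": fam, "origin": "de_novo",
                         "donor_domain": ""})
    return pd.DataFrame(rows).set_index("family_id")


def donor_summary(classified: pd.DataFrame) -> pd.Series:
    """Percentage of lateral families per donor domain."""
    lateral = classified[classified["origin"] == "lateral"]
    if len(lateral) == 0:
        return pd.Series(dtype=float)
    return (100.0 * lateral["donor_domain"].value_counts()
            / len(lateral)).sort_index()


# ---------------------------------------------------------------------------
# ancestral function changes

def ancestral_function_changes(content: pd.DataFrame,
                               term_map: Mapping[str, Iterable[str]],
                               species_tree, parent: str,
                               child: str) -> tuple[set[str], set[str]]:
    """(gained, lost) term sets between a node and its immediate child.

    A term is present at a node iff at least one family carrying it has copy
    number >= 1 there; the map may be partial.
    """
    sp = _as_species_tree(species_tree)
    if sp.parent.get(child) != parent:
        raise AnnotationError(f"'{child}' is not an immediate child of '{parent}'")

    def terms_at(node):
        present = set()
        for fam in content.columns:
            if content.loc[node, fam] >= 1:
                present |= set(term_map.get(fam, ()))
        return present

    tp, tc = terms_at(parent), terms_at(child)
    return tc - tp, tp - tc
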