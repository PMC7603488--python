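# genoflux

Toolkit for analysing gene-content evolution along a rooted species tree:

- **simulate** — forward simulation of gene families evolving by
  origination, duplication, transfer (to incomparable branches) and loss,
  with exact per-branch event tallies and per-node copy numbers as ground
  truth; protein sequences under a uniform 20-state replacement model; and
  probabilistic observation loss mimicking genome incompleteness.
- **families** — protein families from pairwise similarity tables (Markov
  clustering of the identity-thresholded, bitscore-weighted hit graph),
  genome quality filters, single-copy core-marker selection, BLOSUM62
  medoids.
- **reconcile** — minimum-cost *undated* duplication–transfer–loss
  reconciliation of gene trees against the species tree (dynamic program
  over gene-node × species-branch pairs; transfers restricted to
  incomparable branches; terminal loss costs discounted by genome
  completeness; optional root search for unrooted gene trees), plus the
  decomposition of gains into duplication / intra-LGT / origination.
- **flux** — per-branch event tables, ancestral proteome content, >n-fold
  family expansion/contraction detection, completeness-corrected fate
  analysis of originating families, permutation tests for clade event
  rates, completeness-corrected genome size.
- **taxonomy** — average amino acid identity from reciprocal best hits,
  genus/species clusters from strict AAI thresholds (70/95), upper ranks
  from Pearson distances between patristic-distance profiles
  (0.34/0.13/0.015), per-group maximum divergence.
- **annotate** — homology-hit filtering (e-value/identity/length/bitscore),
  proteome novelty, origination-source classification from medoid hits,
  ancestral function gains/losses from family→term maps.

## Command line

Everything is exposed under one entry point:

```sh
genoflux simulate --n-taxa 16 --n-families 200 --dup-rate 0.3 \
    --transfer-rate 0.1 --loss-rate 0.5 --seed 1 --out-dir sim/

genoflux reconcile --species-tree sim/species_tree.nwk \
    --gene-trees-dir sim/gene_trees --metadata sim/metadata.tsv \
    --out-dir rec/

genoflux flux aggregate --reconciliations rec/reconciliations.json \
    --species-tree sim/species_tree.nwk --out branch_events.tsv
genoflux flux fate --origin-branch N3 ...
genoflux flux compare --table branch_events.tsv --clade N4,N5,T01 \
    --event-class dup --n-perm 9999 --seed 7

genoflux families --hits hits.tsv --proteins sim/proteomes \
    --metadata sim/metadata.tsv --min-id 35 --out-dir fam/
genoflux taxonomy --hits hits.tsv --proteins sim/proteomes \
    --tree sim/species_tree.nwk --out-dir tax/
genoflux annotate novelty --hits ref_hits.tsv --proteins sim/proteomes \
    --out novelty.tsv
```

File formats are plain text throughout: Newick trees, FASTA proteomes with
`<genome>|<gene>|<family>` headers, 12-column tabular hit tables (BLAST
outfmt-6 dialect, optionally with two trailing taxon columns), TSV metadata
(`genome_id  completeness  contamination  size_bp`), and JSON
reconciliations.

## Testing notes

The suite (`tests/`) checks every operation against independent oracles
where possible: an exhaustively enumerating undated-DTL reconciler, a
plain-Python Markov clustering, brute-force medoid/RBH/divergence scans,
and closed-form expectations (Yule mean copy number, 20-state identity
decay, binomial retention) for the simulator. `tests/test_acceptance.py`
holds one test per acceptance criterion.
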