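import pytest

import genoflux as gf
from genoflux.io import tree_from_newick


@pytest.fixture(scope="session")
def species16():
    return gf.simulate_species_tree(16, seed=1)


@pytest.fixture(scope="session")
def quartet_tree():
    return tree_from_newick("((A:1.0,B:1.0)N2:1.0,(C:1.0,D:1.0)N3:1.0)N1;")


@pytest.fixture(scope="session")
def sim_dataset():
    """8 taxa, 40 families, moderate rates, with sequences."""
    tree = gf.simulate_species_tree(8, seed=5)
    params = gf.EvolParams(n_families=40, dup_rate=0.15, transfer_rate=0.05,
                           loss_rate=0.2, seq_length=200, subst_rate=0.1,
                           seed=5, condition_on_survival=True)
    data = gf.simulate_gene_content(tree, params)
    return gf.simulate_sequences(data, params)


@pytest.fixture(scope="session")
def sim_reconciliations(sim_dataset):
    sp = gf.SpeciesTree(sim_dataset.species_tree)
    recs = [gf.reconcile_undated(gt, sp, family_id=fam)
            for fam, gt in sorted(sim_dataset.observed_gene_trees().items())]
    return recs, sp
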