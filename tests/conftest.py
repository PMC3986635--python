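import numpy as np
import pytest

from metaconsist.simulate import make_mock_genomes
from metaconsist.taxonomy import TaxonomyTree, TaxonNode, load_taxonomy_table


@pytest.fixture(scope="session")
def mini_tree() -> TaxonomyTree:
    """Hand-built taxonomy: two bacterial genera in one family, a virus
    lacking every rank between domain and family, and an archaeal domain."""
    rows = [
        # taxon_id, parent_id, rank, name
        ("root", "root", "no rank", "root"),
        ("bact", "root", "superkingdom", "Bacteria"),
        ("arch", "root", "superkingdom", "Archaea"),
        ("vir", "root", "superkingdom", "Viruses"),
        ("proteo", "bact", "phylum", "Proteobacteria"),
        ("gamma", "proteo", "class", "Gammaproteobacteria"),
        ("entero_o", "gamma", "order", "Enterobacterales"),
        ("entero_f", "entero_o", "family", "Enterobacteriaceae"),
        ("esch", "entero_f", "genus", "Escherichia"),
        ("ecoli", "esch", "species", "Escherichia coli"),
        ("salm", "entero_f", "genus", "Salmonella"),
        ("senterica", "salm", "species", "Salmonella enterica"),
        ("styphi", "salm", "species", "Salmonella typhi"),
        ("myo", "vir", "family", "Myoviridae"),
        ("t4", "myo", "species", "Tequatrovirus T4"),
    ]
    return TaxonomyTree(TaxonNode(*r) for r in rows)


@pytest.fixture(scope="session")
def mock_world():
    """10 compositionally well-separated mock genomes with taxonomy."""
    records, taxonomy_tsv, genome_to_taxon = make_mock_genomes(
        n_genomes=10, genome_length=30_000,
        gc_content=list(np.linspace(0.25, 0.70, 10)), seed=42)
    tree = load_taxonomy_table(taxonomy_tsv.splitlines())
    return dict(records=records, tree=tree, genome_to_taxon=genome_to_taxon,
                taxonomy_tsv=taxonomy_tsv)


@pytest.fixture(scope="session")
def nbc_model(mock_world):
    from metaconsist.assign import train_nbc

    return train_nbc(mock_world["records"], mock_world["genome_to_taxon"], k=8)
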