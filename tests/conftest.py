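import numpy as np
import pandas as pd
import pytest

from jointprofiler import (
    CommunitySpec,
    FeatureTable,
    TaxonomyTable,
    generate_community,
    write_community,
)


@pytest.fixture(scope="session")
def toy_taxonomy() -> TaxonomyTable:
    """root -> Bacteria -> two genera -> three species; one rankless node."""
    return TaxonomyTable(
        {
            "1": ("1", "no rank", "root"),
            "2": ("1", "superkingdom", "Bacteria"),
            "g1": ("2", "genus", "Bacteroides"),
            "g2": ("2", "genus", "Prevotella"),
            "sA": ("g1", "species", "Bacteroides alpha"),
            "sB": ("g1", "species", "Bacteroides beta"),
            "sC": ("g2", "species", "Prevotella gamma"),
            "x1": ("2", "no rank", "environmental clade"),
        }
    )


@pytest.fixture(scope="session")
def small_community():
    spec = CommunitySpec(
        n_species=4, genome_length=40_000, genes_per_genome=6, seed=11
    )
    return generate_community(spec)


@pytest.fixture(scope="session")
def small_community_dir(small_community, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("community")
    paths = write_community(small_community, outdir)
    return small_community, paths


def make_table(values, samples, keys) -> FeatureTable:
    index = pd.MultiIndex.from_tuples(keys, names=["taxon_label", "gene_id"])
    return FeatureTable(
        pd.DataFrame(np.asarray(values, dtype=float), index=index, columns=samples)
    )
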