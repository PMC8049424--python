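import numpy as np
import pytest

from jointprofiler import (
    AlignedFragment,
    DataError,
    GeneRegion,
    SequenceRecord,
    TaxonAssignmentRow,
    depth_per_genome,
    fpkm,
    mean_depth,
    profile_sample,
    region_depth,
)

F = AlignedFragment
R = TaxonAssignmentRow


def _region(contig="c1", start=0, end=300, gene="K1"):
    return GeneRegion(contig, start, end, "+", gene, 100.0, 1.0, 100.0)


# ---------------------------------------------------- region counting


def test_region_depth_empty():
    assert region_depth([], _region()) == (0, 0)


def test_region_depth_exact_tiling():
    frags = [F(f"f{i}", "c1", 100 * i, 100 * (i + 1)) for i in range(3)]
    count, bases = region_depth(frags, _region())
    assert (count, bases) == (3, 300)
    assert mean_depth(bases, 300) == 1.0


def test_region_depth_clips_partial_overlaps():
    frags = [F("f1", "c1", -0 + 250, 350)]  # 50 bases inside [0,300)
    assert region_depth(frags, _region()) == (1, 50)


def test_region_depth_deduplicates_mates_but_sums_bases():
    mates = [F("f1", "c1", 0, 100), F("f1", "c1", 150, 250)]
    assert region_depth(mates, _region()) == (1, 200)


def test_region_depth_ignores_other_contigs():
    assert region_depth([F("f1", "c2", 0, 100)], _region()) == (0, 0)


# ------------------------------------------------------ normalisations


def test_mean_depth_and_errors():
    assert mean_depth(0, 500) == 0.0
    assert mean_depth(3000, 300) == 10.0
    with pytest.raises(ValueError):
        mean_depth(10, 0)


def test_fpkm_formula_and_scale_invariance():
    assert fpkm(0, 1000, 10**6) == 0.0
    assert fpkm(10, 1000, 10**6) == 10.0
    assert fpkm(20, 1000, 2 * 10**6) == fpkm(10, 1000, 10**6)
    with pytest.raises(ValueError):
        fpkm(1, 1000, 0)


def test_depth_per_genome_cases():
    assert depth_per_genome(5.0, 5.0) == 1.0
    assert depth_per_genome(0.0, 5.0) == 0.0
    with pytest.raises(ValueError):
        depth_per_genome(1.0, 0.0)


# --------------------------------------------------- profile_sample


@pytest.fixture()
def toy_scene(toy_taxonomy):
    """Two annotated contigs: species A carries two copies of gene g,
    species B one; one read per copy."""
    contigs = [
        SequenceRecord("cA", "cA", "A" * 2000),
        SequenceRecord("cB", "cB", "A" * 1000),
    ]
    assignments = [R("cA", "sA", 100), R("cB", "sB", 100)]
    regions = [
        _region("cA", 0, 300, "g"),
        _region("cA", 600, 900, "g"),
        _region("cB", 100, 400, "g"),
    ]
    fragments = [
        F("r1", "cA", 50, 150),
        F("r2", "cA", 700, 800),
        F("r3", "cB", 200, 300),
    ]
    return contigs, assignments, regions, fragments, toy_taxonomy


def test_joint_profile_separates_gene_copies_by_species(toy_scene):
    contigs, assignments, regions, fragments, taxonomy = toy_scene
    profile = profile_sample(contigs, assignments, regions, fragments, "species", taxonomy)
    counts = {(f.taxon_label, f.gene_id): f.stats.fragment_count for f in profile}
    assert counts == {("Bacteroides alpha", "g"): 2, ("Bacteroides beta", "g"): 1}


def test_profile_invariant_to_input_order(toy_scene):
    contigs, assignments, regions, fragments, taxonomy = toy_scene
    a = profile_sample(contigs, assignments, regions, fragments, "species", taxonomy)
    b = profile_sample(
        contigs[::-1], assignments[::-1], regions[::-1], fragments[::-1], "species", taxonomy
    )
    assert a == b


def test_ambiguous_contig_regions_are_dropped(toy_scene):
    contigs, assignments, regions, fragments, taxonomy = toy_scene
    assignments = assignments + [R("cA", "sC", 100)]  # tie on cA
    profile = profile_sample(contigs, assignments, regions, fragments, "species", taxonomy)
    labels = {f.taxon_label for f in profile}
    assert labels == {"Bacteroides beta"}


def test_unassigned_contig_is_unclassified(toy_scene):
    contigs, assignments, regions, fragments, taxonomy = toy_scene
    profile = profile_sample(contigs, assignments[:1], regions, fragments, "species", taxonomy)
    labels = {f.taxon_label for f in profile}
    assert labels == {"Bacteroides alpha", "unclassified"}


def test_depth_modes_on_merged_regions(toy_taxonomy):
    """Two 300-bp copies, each exactly tiled by 3 100-bp fragments:
    dosage depth sums per-copy depths (2.0); pooled depth averages (1.0)."""
    contigs = [SequenceRecord("cA", "cA", "A" * 2000)]
    assignments = [R("cA", "sA", 100)]
    regions = [_region("cA", 0, 300, "g"), _region("cA", 1000, 1300, "g")]
    fragments = [F(f"f{i}", "cA", 100 * i, 100 * (i + 1)) for i in range(3)] + [
        F(f"h{i}", "cA", 1000 + 100 * i, 1100 + 100 * i) for i in range(3)
    ]
    args = (contigs, assignments, regions, fragments, "species", toy_taxonomy)
    (dosage,) = profile_sample(*args, depth_mode="dosage")
    assert dosage.stats.fragment_count == 6
    assert dosage.stats.region_length == 600
    assert dosage.stats.mean_depth == pytest.approx(2.0)
    (pooled,) = profile_sample(*args, depth_mode="pooled")
    assert pooled.stats.mean_depth == pytest.approx(1.0)


def test_empty_fragments_give_zero_stats_or_empty_profile(toy_scene):
    contigs, assignments, regions, fragments, taxonomy = toy_scene
    profile = profile_sample(contigs, assignments, regions, [], "species", taxonomy)
    assert all(f.stats.fragment_count == 0 and f.stats.mean_depth == 0.0 for f in profile)
    assert profile_sample(
        contigs, assignments, regions, [], "species", taxonomy, drop_zeros=True
    ) == []


def test_fragment_count_conservation_with_disjoint_regions(toy_scene):
    contigs, assignments, regions, fragments, taxonomy = toy_scene
    profile = profile_sample(contigs, assignments, regions, fragments, "species", taxonomy)
    assert sum(f.stats.fragment_count for f in profile) <= len(fragments)


def test_dangling_contig_reference_is_data_error(toy_scene):
    contigs, assignments, regions, fragments, taxonomy = toy_scene
    with pytest.raises(DataError, match="ghost"):
        profile_sample(
            contigs, assignments, regions + [_region("ghost")], fragments, "species", taxonomy
        )


def test_genus_rank_pools_species(toy_scene):
    contigs, assignments, regions, fragments, taxonomy = toy_scene
    profile = profile_sample(contigs, assignments, regions, fragments, "genus", taxonomy)
    counts = {(f.taxon_label, f.gene_id): f.stats.fragment_count for f in profile}
    assert counts == {("Bacteroides", "g"): 3}
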