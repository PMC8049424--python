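import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from jointprofiler import (
    DataError,
    OpenReadingFrame,
    ProteinAlignment,
    SequenceRecord,
    derive_gene_regions,
    filter_by_coverage,
    find_orfs,
    revcomp,
    translate,
)
from jointprofiler.annotation import START_CODONS, STOP_CODONS

# ---------------------------------------------------------- translate


def test_translate_basics():
    assert translate("ATG") == "M"
    assert translate("CAT", strand="-") == "M"  # revcomp of CAT is ATG
    assert translate("ATGNNA") == "MX"


def test_translate_rejects_partial_codons():
    with pytest.raises(ValueError):
        translate("ATGA")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=0, max_size=60).map(lambda s: s[: 3 * (len(s) // 3)]))
def test_translate_matches_biopython_table11(seq):
    # unambiguous codons only: this package maps every N-containing codon
    # to X rather than resolving partial ambiguity (Biopython gives ACN -> T)
    ours = translate(seq)
    oracle = str(Seq(seq).translate(table=11))
    assert ours == oracle


# ---------------------------------------------------------- find_orfs


def test_single_plus_strand_orf():
    (orf,) = find_orfs(SequenceRecord("c", "c", "ATGAAATAA"), min_codons=2)
    assert (orf.start, orf.end, orf.strand, orf.aa_seq, orf.partial) == (0, 9, "+", "MK", False)


def test_too_short_sequence_has_no_orfs():
    assert find_orfs(SequenceRecord("c", "c", "ATGTAA"), min_codons=3) == []


def _oracle_orfs(seq: str, min_codons: int):
    """Brute-force six-frame scan, independent of the implementation."""
    found = []
    L = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            seg_start = 0
            segments = []
            for i, c in enumerate(codons):
                if c in STOP_CODONS:
                    segments.append((seg_start, i, True))
                    seg_start = i + 1
            segments.append((seg_start, len(codons), False))
            for begin, stop, has_stop in segments:
                start_idx = next(
                    (i for i in range(begin, stop) if codons[i] in START_CODONS), None
                )
                if start_idx is None:
                    if begin != 0 or not has_stop:
                        continue
                    start_idx = 0
                    partial = True
                else:
                    partial = not has_stop
                if stop - start_idx < min_codons:
                    continue
                nt_start = frame + 3 * start_idx
                nt_end = frame + 3 * (stop + 1 if has_stop else stop)
                if strand == "-":
                    nt_start, nt_end = L - nt_end, L - nt_start
                found.append((nt_start, nt_end, strand))
    return sorted(found)


@pytest.mark.parametrize("seed", range(10))
def test_find_orfs_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
    got = sorted((o.start, o.end, o.strand) for o in find_orfs(SequenceRecord("c", "c", seq)))
    assert got == _oracle_orfs(seq, 30)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=0, max_size=300))
def test_find_orfs_strand_symmetry(seq):
    rec = SequenceRecord("c", "c", seq)
    flipped = SequenceRecord("c", "c", revcomp(seq))
    fwd = sorted((o.start, o.end, o.strand, o.aa_seq) for o in find_orfs(rec, min_codons=5))
    L = len(seq)
    mirrored = sorted(
        (L - o.end, L - o.start, "+" if o.strand == "-" else "-", o.aa_seq)
        for o in find_orfs(flipped, min_codons=5)
    )
    assert fwd == mirrored


# ------------------------------------------------- coverage filter


def _align(qstart=1, qend=100, sstart=1, send=80, slen=100, bitscore=200.0, pident=99.0,
           query="orf1", subject="P1"):
    return ProteinAlignment(query, subject, pident, send - sstart + 1, 0, 0,
                            qstart, qend, sstart, send, 1e-50, bitscore, slen)


def test_coverage_boundary_is_inclusive_at_threshold():
    kept = filter_by_coverage([_align(send=80)], min_coverage=0.8)  # 80/100 = 0.8
    assert len(kept) == 1
    assert filter_by_coverage([_align(send=79)], min_coverage=0.8) == []


def test_zero_min_coverage_is_identity():
    aligns = [_align(send=5), _align(send=100)]
    assert filter_by_coverage(aligns, min_coverage=0.0) == aligns


def test_raising_min_coverage_is_monotone():
    rng = np.random.default_rng(1)
    aligns = [_align(send=int(s)) for s in rng.integers(1, 101, 50)]
    sizes = [len(filter_by_coverage(aligns, c)) for c in np.linspace(0, 1, 21)]
    assert sizes == sorted(sizes, reverse=True)


# -------------------------------------------- gene-region projection


def _orf(start, end, strand="+", contig="c1", orf_id="orf1"):
    aa_len = (end - start) // 3
    return OpenReadingFrame(orf_id, contig, start, end, strand, "M" * aa_len, partial=True)


def test_projection_full_and_partial_query_intervals():
    orf = _orf(0, 300)
    (full,) = derive_gene_regions([orf], [_align(qstart=1, qend=100, send=100)])
    assert (full.start, full.end) == (0, 300)
    (part,) = derive_gene_regions([orf], [_align(qstart=11, qend=100, send=100)])
    assert (part.start, part.end) == (30, 300)


def test_projection_minus_strand():
    orf = _orf(100, 400, strand="-")
    (region,) = derive_gene_regions([orf], [_align(qstart=11, qend=100, send=100)])
    # qend maps to the 5' side of the gene = high forward coordinate
    assert (region.start, region.end, region.strand) == (100, 370, "-")


def test_best_alignment_wins_by_bitscore():
    orf = _orf(0, 300)
    aligns = [
        _align(bitscore=150.0, subject="P_low", send=100),
        _align(bitscore=200.0, subject="P_high", send=100),
    ]
    (region,) = derive_gene_regions([orf], aligns)
    assert region.gene_id == "P_high"


def test_bitscore_tie_breaks_by_identity_then_subject_id():
    orf = _orf(0, 300)
    aligns = [
        _align(bitscore=200.0, pident=98.0, subject="P_a", send=100),
        _align(bitscore=200.0, pident=99.0, subject="P_b", send=100),
    ]
    assert derive_gene_regions([orf], aligns)[0].gene_id == "P_b"
    tied = [
        _align(bitscore=200.0, pident=99.0, subject="P_z", send=100),
        _align(bitscore=200.0, pident=99.0, subject="P_a", send=100),
    ]
    assert derive_gene_regions([orf], tied)[0].gene_id == "P_a"


def test_no_alignments_no_regions_and_dangling_query_errors():
    assert derive_gene_regions([_orf(0, 300)], []) == []
    with pytest.raises(DataError):
        derive_gene_regions([_orf(0, 300)], [_align(query="ghost")])


def test_gene_map_translates_subject_ids():
    orf = _orf(0, 300)
    (region,) = derive_gene_regions(
        [orf], [_align(send=100)], gene_map={"P1": "K00001"}
    )
    assert region.gene_id == "K00001"


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.data())
def test_every_region_lies_inside_its_orf(data):
    start = data.draw(st.integers(0, 50)) * 3
    n_codons = data.draw(st.integers(40, 120))
    strand = data.draw(st.sampled_from("+-"))
    orf = _orf(start, start + 3 * n_codons, strand=strand)
    qstart = data.draw(st.integers(1, n_codons // 2))
    qend = data.draw(st.integers(qstart, n_codons))
    (region,) = derive_gene_regions(
        [orf], [_align(qstart=qstart, qend=qend, sstart=1, send=90, slen=100)]
    )
    assert orf.start <= region.start < region.end <= orf.end
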