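"""Gene annotation on contigs.

Six-frame ORF detection with prokaryotic conventions (start codons ATG/
GTG/TTG, stops TAA/TAG/TGA, translation table 11), subject-coverage
filtering of translated-search alignments, and projection of accepted
protein alignments back to nucleotide gene regions on the contig.

Translation is vectorised over codon indices with the genetic code taken
from Biopython's table 11, so contig-scale six-frame scans stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .errors import DataError
from .io_formats import ProteinAlignment, SequenceRecord

__all__ = [
    "OpenReadingFrame",
    "GeneRegion",
    "revcomp",
    "translate",
    "find_orfs",
    "filter_by_coverage",
    "derive_gene_regions",
]

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> index; anything outside ACGT (i.e. N) maps to 4 and poisons its codon to 'X'
_BASE_IDX = np.full(256, 4, dtype=np.int16)
for _i, _b in enumerate("ACGT"):
    _BASE_IDX[ord(_b)] = _i

_table11 = CodonTable.unambiguous_dna_by_id[11]
_CODON_AA = np.full(64, "X", dtype="<U1")
for _c0 in range(4):
    for _c1 in range(4):
        for _c2 in range(4):
            codon = "ACGT"[_c0] + "ACGT"[_c1] + "ACGT"[_c2]
            idx = 16 * _c0 + 4 * _c1 + _c2
            _CODON_AA[idx] = "*" if codon in _table11.stop_codons else _table11.forward_table[codon]


@dataclass(frozen=True)
class OpenReadingFrame:
    """A (possibly edge-truncated) open reading frame on a contig.

    Coordinates are 0-based half-open on the forward contig axis, for
    both strands. ``end - start`` is divisible by 3 and includes the stop
    codon when one terminates the ORF (``partial`` is False); ``aa_seq``
    never includes the stop.
    """

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    aa_seq: str
    partial: bool = False

    @property
    def aa_len(self) -> int:
        return len(self.aa_seq)


@dataclass(frozen=True)
class GeneRegion:
    """A nucleotide gene interval on a contig, carrying its gene id and
    the quality of the protein alignment it came from."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    bitscore: float
    coverage: float
    identity: float

    def __len__(self) -> int:
        return self.end - self.start


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_indices(seq: str) -> np.ndarray:
    """Per-codon index 0..63, or -1 for codons containing non-ACGT bases."""
    b = _BASE_IDX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(b) // 3
    b = b[: 3 * n].reshape(n, 3)
    idx = 16 * b[:, 0] + 4 * b[:, 1] + b[:, 2]
    idx[(b == 4).any(axis=1)] = -1
    return idx


def translate(nt_seq: str, strand: str = "+") -> str:
    """Translate a nucleotide sequence (table 11); codons containing N
    yield 'X'. For strand '-', the reverse complement is translated."""
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} not divisible by 3")
    if strand == "-":
        nt_seq = revcomp(nt_seq)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = nt_seq.upper()
    idx = _codon_indices(seq)
    aa = np.where(idx >= 0, _CODON_AA[np.clip(idx, 0, 63)], "X")
    return "".join(aa)


_START_IDX = np.array(
    [16 * "ACGT".index(c[0]) + 4 * "ACGT".index(c[1]) + "ACGT".index(c[2]) for c in START_CODONS]
)
_STOP_IDX = np.array(
    [16 * "ACGT".index(c[0]) + 4 * "ACGT".index(c[1]) + "ACGT".index(c[2]) for c in STOP_CODONS]
)


def _scan_frame(codons: np.ndarray, min_codons: int):
    """Yield (start_codon, end_codon, has_stop, partial5) per maximal ORF
    in one frame; codon coordinates, end exclusive of the stop codon."""
    is_stop = np.isin(codons, _STOP_IDX)
    is_start = np.isin(codons, _START_IDX)
    stop_pos = np.flatnonzero(is_stop)
    start_pos = np.flatnonzero(is_start)
    n = len(codons)

    seg_begin = 0
    bounds = list(stop_pos) + [n]
    for stop in bounds:
        has_stop = stop < n
        # first start codon within [seg_begin, stop)
        i = np.searchsorted(start_pos, seg_begin)
        first_start = start_pos[i] if i < len(start_pos) and start_pos[i] < stop else None
        if first_start is not None:
            orf_start, partial5 = int(first_start), False
        elif seg_begin == 0 and has_stop:  # 5'-truncated gene at the contig edge
            orf_start, partial5 = 0, True
        else:
            # no anchoring signal (neither start codon nor terminating stop)
            seg_begin = stop + 1
            continue
        if stop - orf_start >= min_codons:
            yield orf_start, int(stop), has_stop, partial5
        seg_begin = stop + 1


def find_orfs(record: SequenceRecord, min_codons: int = 30) -> list[OpenReadingFrame]:
    """Detect maximal ORFs in all six frames of a contig.

    An ORF runs from the first start codon of a stop-bounded segment to
    that stop; segments touching a contig edge are also emitted without a
    start (5'-truncated) or without a stop (3'-truncated) and flagged
    ``partial``. Only ORFs with at least ``min_codons`` codons (stop
    excluded) are reported. Minus-strand ORFs are reported on the
    forward contig axis. ORF ids are ``<contig>_<n>`` in coordinate order.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    L = len(record.seq)
    found: list[tuple[int, int, str, str, bool]] = []
    for strand in "+-":
        seq = record.seq if strand == "+" else revcomp(record.seq)
        for frame in range(3):
            codons = _codon_indices(seq[frame:])
            for c_start, c_stop, has_stop, partial5 in _scan_frame(codons, min_codons):
                nt_start = frame + 3 * c_start
                nt_end = frame + 3 * (c_stop + 1) if has_stop else frame + 3 * c_stop
                aa = "".join(_CODON_AA[np.clip(codons[c_start:c_stop], 0, 63)])
                # restore X for N-containing codons
                bad = codons[c_start:c_stop] < 0
                if bad.any():
                    aa = "".join("X" if m else a for a, m in zip(aa, bad))
                if strand == "-":
                    nt_start, nt_end = L - nt_end, L - nt_start
                found.append((nt_start, nt_end, strand, aa, partial5 or not has_stop))
    found.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        OpenReadingFrame(f"{record.id}_{i}", record.id, s, e, strand, aa, partial)
        for i, (s, e, strand, aa, partial) in enumerate(found, 1)
    ]


def filter_by_coverage(
    aligns: Iterable[ProteinAlignment], min_coverage: float = 0.8
) -> list[ProteinAlignment]:
    """Keep alignments whose subject coverage (send - sstart + 1) /
    subject_len is at least ``min_coverage``."""
    kept = []
    for a in aligns:
        if a.subject_len is None or a.subject_len <= 0:
            raise ValueError(f"alignment {a.query_id}->{a.subject_id} lacks subject_len")
        if a.subject_coverage >= min_coverage:
            kept.append(a)
    return kept


def derive_gene_regions(
    orfs: Sequence[OpenReadingFrame],
    filtered_aligns: Iterable[ProteinAlignment],
    gene_map: Mapping[str, str] | None = None,
) -> list[GeneRegion]:
    """Project each ORF's best protein alignment to a nucleotide gene region.

    Per ORF only the best alignment survives (max bitscore, ties broken
    by max percent identity, then lexicographically smallest subject id).
    The aligned query sub-interval [qstart, qend] (1-based aa) is mapped
    to contig nucleotides respecting strand. ``gene_map`` translates
    subject ids to gene ids; subjects absent from the map keep their own id.
    """
    by_orf: dict[str, OpenReadingFrame] = {o.orf_id: o for o in orfs}
    best: dict[str, ProteinAlignment] = {}
    for a in filtered_aligns:
        if a.query_id not in by_orf:
            raise DataError(f"alignment query {a.query_id!r} matches no ORF")
        cur = best.get(a.query_id)
        if cur is None or (a.bitscore, a.pct_identity, _neg_lex(a.subject_id)) > (
            cur.bitscore,
            cur.pct_identity,
            _neg_lex(cur.subject_id),
        ):
            best[a.query_id] = a

    regions: list[GeneRegion] = []
    for orf_id in sorted(best):
        a = best[orf_id]
        orf = by_orf[orf_id]
        nt_off_start = 3 * (a.qstart - 1)
        nt_off_end = 3 * a.qend
        if orf.strand == "+":
            start, end = orf.start + nt_off_start, orf.start + nt_off_end
        else:
            start, end = orf.end - nt_off_end, orf.end - nt_off_start
        gene_id = gene_map.get(a.subject_id, a.subject_id) if gene_map else a.subject_id
        regions.append(
            GeneRegion(
                contig_id=orf.contig_id,
                start=start,
                end=end,
                strand=orf.strand,
                gene_id=gene_id,
                bitscore=a.bitscore,
                coverage=a.subject_coverage,
                identity=a.pct_identity,
            )
        )
    return regions


class _neg_lex(str):
    """Inverts lexicographic order so max() picks the smallest subject id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
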