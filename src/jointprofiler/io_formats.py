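"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are always 0-based half-open. SAM POS (1-based) and
tabular protein-alignment coordinates (1-based inclusive, amino acids) are
converted at this boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pysam

from .errors import FormatError

__all__ = [
    "SequenceRecord",
    "AlignedFragment",
    "ProteinAlignment",
    "read_fasta",
    "write_fasta",
    "read_sam_fragments",
    "read_protein_alignments",
    "read_subject_lengths",
    "read_feature_tsv",
    "write_feature_tsv",
]

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence (contig or genome) with its FASTA header.

    ``id`` is the first whitespace-delimited token of the header;
    ``seq`` is uppercase over the alphabet {A,C,G,T,N}.
    """

    id: str
    description: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignedFragment:
    """One aligned mate interval on a contig, 0-based half-open.

    The two mates of a paired template share ``fragment_id``; counting
    logic deduplicates by fragment_id so a template is a single fragment.
    """

    fragment_id: str
    contig_id: str
    start: int
    end: int
    mapq: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class ProteinAlignment:
    """One row of a 12/13-column tabular translated-search alignment."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    subject_len: int

    def __post_init__(self) -> None:
        if self.qstart > self.qend or self.sstart > self.send:
            raise ValueError("alignment coordinates must satisfy start <= end")
        if self.subject_len < self.send:
            raise ValueError("subject_len shorter than alignment end")

    @property
    def subject_coverage(self) -> float:
        """Fraction of the database protein spanned by the alignment."""
        return (self.send - self.sstart + 1) / self.subject_len


def _normalize_seq(chunks: list[str]) -> str:
    seq = "".join(chunks).upper()
    seq = re.sub(r"\s", "", seq)
    return _NON_ACGTN.sub("N", seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Lowercase bases are uppercased and characters outside {A,C,G,T,N}
    are replaced by N. A sequence line before the first header is a
    :class:`FormatError` naming the offending line.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid = header.split()[0] if header.split() else ""
        if not rid:
            raise FormatError(f"{path}: empty FASTA header")
        records.append(SequenceRecord(rid, header, _normalize_seq(chunks)))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                flush()
                header = stripped[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(stripped)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_sam_fragments(path: str | Path, min_mapq: int = 0) -> list[AlignedFragment]:
    """Extract aligned mate intervals from a SAM file.

    Unmapped, secondary (0x100) and supplementary (0x800) records are
    excluded, as are records below ``min_mapq``. The reference-consumed
    interval is derived from the CIGAR (M/D/N/=/X consume reference).
    """
    fragments: list[AlignedFragment] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        ref_lengths = dict(zip(sam.references, sam.lengths))
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            start = rec.reference_start
            end = rec.reference_end
            if end is None:  # mapped record without CIGAR: nothing consumed
                continue
            limit = ref_lengths.get(rec.reference_name)
            if limit is not None and end > limit:
                raise FormatError(
                    f"{path}: read {rec.query_name!r} CIGAR extends to {end} "
                    f"beyond contig {rec.reference_name!r} length {limit}"
                )
            fragments.append(
                AlignedFragment(
                    fragment_id=rec.query_name,
                    contig_id=rec.reference_name,
                    start=start,
                    end=end,
                    mapq=rec.mapping_quality,
                )
            )
    return fragments


def read_subject_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of protein id -> length in amino acids."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            lengths[cols[0]] = int(cols[1])
    return lengths


def read_protein_alignments(
    path: str | Path,
    subject_lengths: Mapping[str, int] | str | Path | None = None,
) -> list[ProteinAlignment]:
    """Read tabular protein alignments (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore [slen]).

    The subject (database protein) length is required for the coverage
    filter: it is taken from a 13th column when present, else from the
    ``subject_lengths`` table (a mapping or a two-column TSV path).
    """
    if isinstance(subject_lengths, (str, Path)):
        subject_lengths = read_subject_lengths(subject_lengths)

    alignments: list[ProteinAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns, got {len(cols)}"
                )
            if len(cols) >= 13:
                slen = int(float(cols[12]))
            elif subject_lengths is not None and cols[1] in subject_lengths:
                slen = subject_lengths[cols[1]]
            else:
                raise FormatError(
                    f"{path}:{lineno}: no subject length for {cols[1]!r}; provide "
                    "a 13th 'slen' column or a subject-length table"
                )
            try:
                alignments.append(
                    ProteinAlignment(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pct_identity=float(cols[2]),
                        align_len=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        qstart=int(cols[6]),
                        qend=int(cols[7]),
                        sstart=int(cols[8]),
                        send=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                        subject_len=slen,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return alignments


# Feature-table TSV round-trip lives here so every on-disk format shares one
# module; the FeatureTable container itself is defined in tables.py.

def write_feature_tsv(table, path: str | Path) -> None:
    """Write a FeatureTable as TSV with a 'taxonLabel|geneId' key column."""
    table.to_frame().to_csv(path, sep="\t", index_label="feature", float_format="%.6g")


def read_feature_tsv(path: str | Path):
    """Read a feature table written by :func:`write_feature_tsv`."""
    import pandas as pd

    from .tables import FeatureTable

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicate feature keys: {dupes[:5]}")
    return FeatureTable.from_frame(df)
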