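"""Synthetic shotgun-metagenome communities with exact ground truth.

Builds bacterial communities in which every genome carries a shared pool
of synthetic KO-style genes at known copy number, simulates error-free
(or noisy) paired fragments at a target fold coverage, and emits every
input format the profiling pipeline consumes — contig FASTA, SAM read
alignments with true coordinates, contig-taxon assignments, a taxonomy
table, protein alignments and a gene map — together with a truth table
whose per-(taxon, gene) true abundance is coverage × copy number.

Fragments are emitted pre-aligned (the SAM records carry the true
positions), so no aligner or assembler is ever involved and the whole
fixture is deterministic for a fixed seed. Fragment start positions are
stratified-uniform: one uniform draw inside each of N equal-width bins,
which keeps each start marginally uniform while realising the even,
low-discrepancy coverage that an idealised error-free uniform-coverage
experiment provides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import STOP_CODONS, find_orfs, revcomp, translate
from .io_formats import SequenceRecord, write_fasta
from .taxonomy import TaxonomyTable

__all__ = [
    "CommunitySpec",
    "GenePlacement",
    "Community",
    "generate_community",
    "simulate_fragments",
    "emit_annotation_inputs",
    "write_community",
]

GENE_LENGTH = 900  # bp per cassette: start codon + 298 stop-free codons + stop

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]


@dataclass(frozen=True)
class CommunitySpec:
    """Study conditions for a synthetic community.

    Defaults follow the benchmark conditions: paired 100-bp reads from
    fragments of size Normal(200, 50) at 10X coverage, 20 species each
    carrying the same pool of 50 genes at 1–5 copies.
    """

    n_species: int = 20
    genome_length: int = 300_000
    genes_per_genome: int = 50
    copy_number_range: tuple[int, int] = (1, 5)
    coverage: float = 10.0
    read_length: int = 100
    fragment_mean: int = 200
    fragment_sd: int = 50
    error_rate: float = 0.0
    seed: int = 42
    contigs_per_genome: int = 1
    ambiguous_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.fragment_mean < self.read_length:
            raise ValueError("fragment_mean must be >= read_length")
        if self.copy_number_range[0] < 1 or self.copy_number_range[0] > self.copy_number_range[1]:
            raise ValueError("copy_number_range must satisfy 1 <= min <= max")
        if self.contigs_per_genome < 1:
            raise ValueError("contigs_per_genome must be >= 1")


@dataclass(frozen=True)
class GenePlacement:
    """One planted gene cassette: 0-based half-open contig interval of the
    full 900-bp CDS including its stop codon."""

    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str


@dataclass
class Community:
    spec: CommunitySpec
    contigs: list[SequenceRecord]
    placements: list[GenePlacement]
    taxonomy: TaxonomyTable
    contig_taxon: dict[str, str]  # contig id -> species taxon id
    gene_proteins: dict[str, str]  # gene id -> protein sequence (aa)
    truth: pd.DataFrame = field(repr=False)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.gene_proteins)


def _random_cds(rng: np.random.Generator) -> str:
    """A 900-bp CDS: ATG + 298 random sense codons + TAA."""
    body = rng.choice(len(_SENSE_CODONS), size=(GENE_LENGTH // 3) - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _build_taxonomy(n_species: int) -> tuple[TaxonomyTable, list[str]]:
    """Toy taxonomy: root -> Bacteria -> genera (2 species each) -> species."""
    nodes: dict[str, tuple[str, str, str]] = {
        "1": ("1", "no rank", "root"),
        "2": ("1", "superkingdom", "Bacteria"),
    }
    species_ids = []
    for i in range(n_species):
        genus_idx = i // 2 + 1
        gid = f"g{genus_idx:02d}"
        if gid not in nodes:
            nodes[gid] = ("2", "genus", f"Genus{genus_idx:02d}")
        sid = f"s{i + 1:02d}"
        nodes[sid] = (gid, "species", f"Genus{genus_idx:02d} species{i + 1:02d}")
        species_ids.append(sid)
    return TaxonomyTable(nodes), species_ids


def generate_community(spec: CommunitySpec) -> Community:
    """Build the genomes, placements, taxonomy and truth table.

    Each genome is a random ACGT background with each pool gene's
    cassette inserted at a copy number drawn uniformly from
    ``copy_number_range``; placements are disjoint, on random strands,
    separated by uniformly partitioned background gaps. With
    ``contigs_per_genome > 1`` the genome is split into contigs at
    breakpoints chosen inside inter-gene gaps, so no cassette is cut.
    Byte-identical output for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    taxonomy, species_ids = _build_taxonomy(spec.n_species)
    gene_ids = [f"K{i + 1:05d}" for i in range(spec.genes_per_genome)]
    gene_cds = {g: _random_cds(rng) for g in gene_ids}
    gene_proteins = {g: translate(gene_cds[g][:-3]) for g in gene_ids}

    contigs: list[SequenceRecord] = []
    placements: list[GenePlacement] = []
    contig_taxon: dict[str, str] = {}
    truth_rows = []
    cmin, cmax = spec.copy_number_range

    for sp_idx, taxon_id in enumerate(species_ids):
        copies = rng.integers(cmin, cmax + 1, size=len(gene_ids))
        cassettes: list[str] = []  # gene id per cassette
        for g, c in zip(gene_ids, copies):
            cassettes.extend([g] * int(c))
            truth_rows.append(
                {
                    "taxon_id": taxon_id,
                    "taxon_name": taxonomy.name(taxon_id),
                    "gene_id": g,
                    "copy_number": int(c),
                    "true_abundance": spec.coverage * int(c),
                }
            )
        order = rng.permutation(len(cassettes))
        cassettes = [cassettes[i] for i in order]
        total_gene_bp = GENE_LENGTH * len(cassettes)
        free = spec.genome_length - total_gene_bp
        if free < 0:
            raise ValueError(
                f"genome_length {spec.genome_length} too short for "
                f"{len(cassettes)} cassettes ({total_gene_bp} bp)"
            )
        cuts = np.sort(rng.uniform(0, free, size=len(cassettes)))
        gaps = np.diff(np.concatenate([[0.0], cuts, [float(free)]])).astype(int)
        # rounding slack goes into the final gap
        gaps[-1] += free - int(gaps.sum())

        genome_parts: list[str] = []
        genome_placements: list[tuple[str, int, int, str]] = []
        pos = 0
        for gene, gap in zip(cassettes, gaps[:-1]):
            genome_parts.append(_random_bases(rng, gap))
            pos += int(gap)
            cds = gene_cds[gene]
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            genome_parts.append(cds if strand == "+" else revcomp(cds))
            genome_placements.append((gene, pos, pos + GENE_LENGTH, strand))
            pos += GENE_LENGTH
        genome_parts.append(_random_bases(rng, int(gaps[-1])))
        genome = "".join(genome_parts)

        # split into contigs at gap-interior breakpoints
        n_pieces = spec.contigs_per_genome
        if n_pieces == 1:
            bounds = [0, len(genome)]
        else:
            targets = [len(genome) * k // n_pieces for k in range(1, n_pieces)]
            gene_iv = [(s, e) for _, s, e, _ in genome_placements]
            bounds = [0]
            for t in targets:
                bp = t
                while any(s < bp < e for s, e in gene_iv):
                    bp += 1
                if bounds[-1] < bp < len(genome):
                    bounds.append(bp)
            bounds.append(len(genome))
        for piece_idx in range(len(bounds) - 1):
            lo, hi = bounds[piece_idx], bounds[piece_idx + 1]
            cid = (
                f"ctg_{taxon_id}"
                if len(bounds) == 2
                else f"ctg_{taxon_id}_p{piece_idx + 1}"
            )
            contigs.append(SequenceRecord(cid, cid, genome[lo:hi]))
            contig_taxon[cid] = taxon_id
            for gene, s, e, strand in genome_placements:
                if lo <= s and e <= hi:
                    placements.append(GenePlacement(cid, gene, s - lo, e - lo, strand))

    truth = pd.DataFrame(truth_rows)
    return Community(
        spec=spec,
        contigs=contigs,
        placements=placements,
        taxonomy=taxonomy,
        contig_taxon=contig_taxon,
        gene_proteins=gene_proteins,
        truth=truth,
    )


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def simulate_fragments(
    community: Community,
    sam_path: str | Path,
    with_seq: bool = False,
    fastq_prefix: str | Path | None = None,
) -> int:
    """Write paired fragments as SAM with true coordinates; returns the
    number of fragments.

    Per contig, N = coverage × length / (2 × read_length) fragments are
    placed with stratified-uniform starts; lengths are Normal(mean, sd)
    clipped to [read_length, 3 × mean]; the two read-length mates sit at
    the fragment ends (FR orientation). Substitution errors at
    ``error_rate`` alter read sequences but never positions. With
    ``fastq_prefix`` set, paired FASTQ files are written as well.
    """
    spec = community.spec
    rng = np.random.default_rng(spec.seed + 1)
    rl = spec.read_length
    need_seq = with_seq or fastq_prefix is not None or spec.error_rate > 0

    fq1 = open(f"{fastq_prefix}_R1.fastq", "w") if fastq_prefix else None
    fq2 = open(f"{fastq_prefix}_R2.fastq", "w") if fastq_prefix else None
    n_total = 0
    with open(sam_path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig in community.contigs:
            out.write(f"@SQ\tSN:{contig.id}\tLN:{len(contig)}\n")
        for contig in community.contigs:
            L = len(contig)
            n_frag = int(round(spec.coverage * L / (2 * rl)))
            if n_frag <= 0 or L < rl:
                continue
            lengths = np.clip(
                np.rint(rng.normal(spec.fragment_mean, spec.fragment_sd, n_frag)),
                rl,
                3 * spec.fragment_mean,
            ).astype(np.int64)
            lengths = np.minimum(lengths, L)
            starts = (
                (np.arange(n_frag) + rng.uniform(0.0, 1.0, n_frag)) * (L / n_frag)
            ).astype(np.int64)
            starts = np.minimum(starts, L - lengths)
            lines: list[str] = []
            for i in range(n_frag):
                s, flen = int(starts[i]), int(lengths[i])
                p1, p2 = s, s + flen - rl
                qname = f"{contig.id}_f{i + 1}"
                if need_seq:
                    seq1 = _apply_errors(contig.seq[p1 : p1 + rl], rng, spec.error_rate)
                    seq2_fwd = _apply_errors(
                        contig.seq[p2 : p2 + rl], rng, spec.error_rate
                    )
                    sam_seq1, sam_seq2 = seq1, seq2_fwd
                    qual = "I" * rl
                else:
                    sam_seq1 = sam_seq2 = "*"
                    qual = "*"
                lines.append(
                    f"{qname}\t99\t{contig.id}\t{p1 + 1}\t60\t{rl}M\t=\t{p2 + 1}"
                    f"\t{flen}\t{sam_seq1}\t{qual}\n"
                )
                lines.append(
                    f"{qname}\t147\t{contig.id}\t{p2 + 1}\t60\t{rl}M\t=\t{p1 + 1}"
                    f"\t{-flen}\t{sam_seq2}\t{qual}\n"
                )
                if fq1 is not None:
                    fq1.write(f"@{qname}/1\n{seq1}\n+\n{'I' * rl}\n")
                    fq2.write(f"@{qname}/2\n{revcomp(seq2_fwd)}\n+\n{'I' * rl}\n")
            out.write("".join(lines))
            n_total += n_frag
    if fq1 is not None:
        fq1.close()
        fq2.close()
    return n_total


def emit_annotation_inputs(
    community: Community, min_codons: int = 30
) -> tuple[list[tuple[str, str, float]], list[str], dict[str, str]]:
    """Synthesize the annotation-side inputs a real pipeline would get
    from a taxonomic classifier and a translated search.

    Returns (taxon assignment rows, 13-column protein-alignment lines,
    gene map). Each contig is assigned its true taxon with score 100;
    with ``ambiguous_fraction`` > 0 that fraction of contigs receives a
    second tied top-score row to exercise the ambiguity filter. Protein
    alignments are emitted for each planted cassette at identity 100 and
    subject coverage 1.0, addressed to the ORF (found with the same
    ``min_codons`` the pipeline will use) that contains the cassette.
    """
    spec = community.spec
    rng = np.random.default_rng(spec.seed + 2)

    taxa_rows: list[tuple[str, str, float]] = []
    contig_ids = [c.id for c in community.contigs]
    n_amb = int(round(spec.ambiguous_fraction * len(contig_ids)))
    ambiguous = set(
        rng.choice(len(contig_ids), size=n_amb, replace=False) if n_amb else []
    )
    species = sorted(set(community.contig_taxon.values()))
    for idx, cid in enumerate(contig_ids):
        true_taxon = community.contig_taxon[cid]
        taxa_rows.append((cid, true_taxon, 100.0))
        if idx in ambiguous and len(species) > 1:
            others = [s for s in species if s != true_taxon]
            taxa_rows.append((cid, others[rng.integers(0, len(others))], 100.0))

    by_contig: dict[str, list[GenePlacement]] = {}
    for p in community.placements:
        by_contig.setdefault(p.contig_id, []).append(p)

    align_lines: list[str] = []
    gene_map: dict[str, str] = {}
    aa_len = GENE_LENGTH // 3 - 1  # 299
    for contig in community.contigs:
        plist = by_contig.get(contig.id, [])
        if not plist:
            continue
        orfs = find_orfs(contig, min_codons=min_codons)
        # index ORFs by the coordinate pinned to the cassette stop codon
        plus_by_end: dict[int, list] = {}
        minus_by_start: dict[int, list] = {}
        for o in orfs:
            (plus_by_end if o.strand == "+" else minus_by_start).setdefault(
                o.end if o.strand == "+" else o.start, []
            ).append(o)
        for p in sorted(plist, key=lambda q: q.start):
            if p.strand == "+":
                hosts = [
                    o
                    for o in plus_by_end.get(p.end, [])
                    if o.start <= p.start and (p.start - o.start) % 3 == 0
                ]
                if not hosts:
                    raise AssertionError(f"no ORF hosts cassette {p}")
                orf = hosts[0]
                qstart = (p.start - orf.start) // 3 + 1
            else:
                hosts = [
                    o
                    for o in minus_by_start.get(p.start, [])
                    if o.end >= p.end and (o.end - p.end) % 3 == 0
                ]
                if not hosts:
                    raise AssertionError(f"no ORF hosts cassette {p}")
                orf = hosts[0]
                qstart = (orf.end - p.end) // 3 + 1
            subject = f"{p.gene_id}.p"
            gene_map[subject] = p.gene_id
            align_lines.append(
                "\t".join(
                    [
                        orf.orf_id,
                        subject,
                        "100.0",
                        str(aa_len),
                        "0",
                        "0",
                        str(qstart),
                        str(qstart + aa_len - 1),
                        "1",
                        str(aa_len),
                        "1e-180",
                        f"{2.0 * aa_len:.1f}",
                        str(aa_len),
                    ]
                )
            )
    return taxa_rows, align_lines, gene_map


def write_community(
    community: Community,
    outdir: str | Path,
    with_seq: bool = False,
    fastq: bool = False,
) -> dict[str, Path]:
    """Materialise every pipeline input plus the truth table in ``outdir``.

    Writes contigs.fasta, reads.sam, taxa.tsv, taxonomy.tsv, genes.tsv
    (13-column protein alignments), gene_map.tsv and truth.tsv; returns
    the path of each.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": outdir / "contigs.fasta",
        "sam": outdir / "reads.sam",
        "taxa": outdir / "taxa.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "genes": outdir / "genes.tsv",
        "gene_map": outdir / "gene_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(community.contigs, paths["contigs"])
    simulate_fragments(
        community,
        paths["sam"],
        with_seq=with_seq,
        fastq_prefix=(outdir / "reads") if fastq else None,
    )
    taxa_rows, align_lines, gene_map = emit_annotation_inputs(community)
    with open(paths["taxa"], "w") as fh:
        for cid, tid, score in taxa_rows:
            fh.write(f"{cid}\t{tid}\t{score:g}\n")
    community.taxonomy.to_tsv(paths["taxonomy"])
    with open(paths["genes"], "w") as fh:
        fh.write("\n".join(align_lines) + ("\n" if align_lines else ""))
    with open(paths["gene_map"], "w") as fh:
        for subject, gene in sorted(gene_map.items()):
            fh.write(f"{subject}\t{gene}\n")
    community.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
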