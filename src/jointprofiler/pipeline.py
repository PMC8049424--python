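"""File-level orchestration: run the joint profiler from on-disk inputs.

This is the layer the CLI and batch scripts call; every step is a thin
composition of the library modules (io_formats, taxonomy, annotation,
profiler).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import pandas as pd

from .annotation import derive_gene_regions, filter_by_coverage, find_orfs
from .io_formats import read_fasta, read_protein_alignments, read_sam_fragments
from .profiler import DepthStats, JointFeature, profile_sample
from .taxonomy import TaxonomyTable, read_taxon_assignments

__all__ = ["profile_files", "profile_to_frame", "write_profile_tsv", "read_profile_tsv"]

_PROFILE_COLUMNS = [
    "taxon_id",
    "taxon_label",
    "gene_id",
    "fragment_count",
    "aligned_bases",
    "region_length",
    "mean_depth",
    "fpkm",
    "depth_per_genome",
]


def profile_files(
    contigs_path: str | Path,
    taxa_path: str | Path,
    taxonomy_path: str | Path,
    alignments_path: str | Path,
    sam_path: str | Path,
    *,
    rank: str = "species",
    sample_id: str = "sample",
    min_coverage: float = 0.8,
    min_mapq: int = 0,
    min_codons: int = 30,
    gene_map_path: str | Path | None = None,
    subject_lengths_path: str | Path | None = None,
    depth_mode: Literal["dosage", "pooled"] = "dosage",
    tie_policy: Literal["drop", "lca"] = "drop",
    drop_zeros: bool = False,
) -> list[JointFeature]:
    """Run the full single-sample joint-profiling pipeline from files.

    Contigs are ORF-scanned, protein alignments are coverage-filtered
    (subject coverage >= ``min_coverage``) and projected to gene
    regions, contig taxonomy is resolved at ``rank`` with ambiguous
    contigs removed, and fragments from the SAM are counted into
    per-(taxon, gene) abundance statistics.
    """
    contigs = read_fasta(contigs_path)
    assignments = read_taxon_assignments(taxa_path)
    taxonomy = TaxonomyTable.from_tsv(taxonomy_path)
    aligns = read_protein_alignments(alignments_path, subject_lengths_path)
    gene_map = None
    if gene_map_path is not None:
        gene_map = {}
        with open(gene_map_path) as fh:
            for line in fh:
                if line.strip():
                    subject, gene = line.rstrip("\n").split("\t")[:2]
                    gene_map[subject] = gene

    orfs = [orf for contig in contigs for orf in find_orfs(contig, min_codons=min_codons)]
    kept = filter_by_coverage(aligns, min_coverage=min_coverage)
    regions = derive_gene_regions(orfs, kept, gene_map)
    fragments = read_sam_fragments(sam_path, min_mapq=min_mapq)
    return profile_sample(
        contigs,
        assignments,
        regions,
        fragments,
        rank,
        taxonomy,
        sample_id=sample_id,
        depth_mode=depth_mode,
        tie_policy=tie_policy,
        drop_zeros=drop_zeros,
    )


def profile_to_frame(profile: list[JointFeature]) -> pd.DataFrame:
    rows = []
    for f in profile:
        s = f.stats
        rows.append(
            {
                "taxon_id": f.taxon_id if f.taxon_id is not None else "",
                "taxon_label": f.taxon_label,
                "gene_id": f.gene_id,
                "fragment_count": s.fragment_count,
                "aligned_bases": s.aligned_bases,
                "region_length": s.region_length,
                "mean_depth": s.mean_depth,
                "fpkm": s.fpkm,
                "depth_per_genome": s.depth_per_genome if s.depth_per_genome is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=_PROFILE_COLUMNS)


def write_profile_tsv(profile: list[JointFeature], path: str | Path) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_profile_tsv(path: str | Path, sample_id: str | None = None) -> list[JointFeature]:
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str}, keep_default_na=False)
    sid = sample_id if sample_id is not None else Path(path).stem
    profile = []
    for row in df.itertuples(index=False):
        dpg = getattr(row, "depth_per_genome")
        stats = DepthStats(
            fragment_count=int(row.fragment_count),
            aligned_bases=int(row.aligned_bases),
            region_length=int(row.region_length),
            mean_depth=float(row.mean_depth),
            fpkm=float(row.fpkm),
            depth_per_genome=float(dpg) if dpg not in ("", None) else None,
        )
        profile.append(
            JointFeature(
                sid,
                str(row.taxon_label),
                str(row.gene_id),
                stats,
                taxon_id=str(row.taxon_id) or None,
            )
        )
    return profile
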