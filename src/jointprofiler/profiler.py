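"""The core joint-profiling algorithm.

Contigs carry both a taxonomic assignment and gene regions; fragments
aligned to a contig therefore inherit a (taxon, gene) identity when they
fall into a gene region. Per (taxon label, gene id) the profiler reports
the fragment count and three normalisations:

mean depth
    Sum over the feature's gene regions of per-region depth
    (aligned bases in the region / region length). Under uniform
    c-fold coverage a gene with k copies scores c·k, i.e. mean depth
    measures gene dosage. The pooled variant Σbases/Σlength, which
    measures per-copy depth instead, is available as depth_mode="pooled".

FPKM
    fragment_count × 1e9 / (region length in bp × total mapped fragments).

depth per genome
    mean depth divided by the genome-wide mean depth of the feature's
    taxon (total aligned bases on the taxon's contigs / their total
    length); interpretable as gene copies per genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .annotation import GeneRegion
from .errors import DataError
from .io_formats import AlignedFragment, SequenceRecord
from .taxonomy import (
    UNCLASSIFIED,
    TaxonAssignmentRow,
    TaxonomyTable,
    lineage_at_rank,
    resolve_contig_taxa,
)

__all__ = [
    "DepthStats",
    "JointFeature",
    "region_depth",
    "mean_depth",
    "fpkm",
    "depth_per_genome",
    "profile_sample",
]


@dataclass
class DepthStats:
    """Abundance statistics for one joint feature in one sample."""

    fragment_count: int = 0
    aligned_bases: int = 0
    region_length: int = 0
    mean_depth: float = 0.0
    fpkm: float = 0.0
    depth_per_genome: float | None = 0.0


@dataclass
class JointFeature:
    """A (taxon label, gene id) abundance in one sample."""

    sample_id: str
    taxon_label: str
    gene_id: str
    stats: DepthStats = field(default_factory=DepthStats)
    taxon_id: str | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.taxon_label, self.gene_id)


class _ContigIndex:
    """Mate intervals of one contig as flat arrays for vectorised overlap."""

    def __init__(self, fragments: Sequence[AlignedFragment], frag_index: dict[str, int]):
        self.starts = np.array([f.start for f in fragments], dtype=np.int64)
        self.ends = np.array([f.end for f in fragments], dtype=np.int64)
        self.fids = np.array([frag_index[f.fragment_id] for f in fragments], dtype=np.int64)

    def overlap(self, start: int, end: int) -> tuple[int, int]:
        """(distinct fragments overlapping, per-base overlap sum) for [start, end)."""
        mask = (self.starts < end) & (self.ends > start)
        if not mask.any():
            return 0, 0
        count = int(np.unique(self.fids[mask]).size)
        bases = int(
            np.sum(
                np.minimum(self.ends[mask], end) - np.maximum(self.starts[mask], start)
            )
        )
        return count, bases

    @property
    def total_bases(self) -> int:
        return int(np.sum(self.ends - self.starts))


def region_depth(
    fragments: Iterable[AlignedFragment], region: GeneRegion
) -> tuple[int, int]:
    """Count fragments and aligned bases in a gene region.

    A fragment counts once if any of its mate intervals overlaps the
    region by >= 1 base; aligned bases sum the per-base overlap of all
    its intervals clipped to the region.
    """
    frags = [f for f in fragments if f.contig_id == region.contig_id]
    ids = {}
    for f in frags:
        ids.setdefault(f.fragment_id, len(ids))
    if not frags:
        return 0, 0
    return _ContigIndex(frags, ids).overlap(region.start, region.end)


def mean_depth(aligned_bases: int, region_length: int) -> float:
    """Average per-base coverage: aligned bases / region length."""
    if region_length <= 0:
        raise ValueError("region_length must be > 0")
    return aligned_bases / region_length


def fpkm(fragment_count: int, region_length_bp: int, total_mapped_fragments: int) -> float:
    """Fragments per kilobase of region per million mapped fragments."""
    if total_mapped_fragments <= 0:
        raise ValueError("total_mapped_fragments must be > 0")
    if region_length_bp <= 0:
        raise ValueError("region_length_bp must be > 0")
    return fragment_count * 1e9 / (region_length_bp * total_mapped_fragments)


def depth_per_genome(gene_mean_depth: float, taxon_genome_mean_depth: float) -> float:
    """Gene mean depth relative to its taxon's genome-wide mean depth
    (gene copies per genome under uniform coverage)."""
    if taxon_genome_mean_depth <= 0:
        raise ValueError("taxon genome mean depth must be > 0")
    return gene_mean_depth / taxon_genome_mean_depth


def profile_sample(
    contigs: Sequence[SequenceRecord],
    contig_taxa: Iterable[TaxonAssignmentRow],
    gene_regions: Sequence[GeneRegion],
    fragments: Sequence[AlignedFragment],
    rank: str,
    taxonomy: TaxonomyTable,
    *,
    sample_id: str = "sample",
    depth_mode: Literal["dosage", "pooled"] = "dosage",
    tie_policy: Literal["drop", "lca"] = "drop",
    keep_unassigned: bool = True,
    drop_zeros: bool = False,
) -> list[JointFeature]:
    """Profile one sample into joint (taxon, gene) features.

    Gene regions on contigs removed by the ambiguity filter are dropped.
    Per (taxon label at ``rank``, gene id), fragment counts, aligned
    bases and region lengths are summed over all matching regions; mean
    depth combines regions according to ``depth_mode`` (see module
    docstring). Output is sorted by (taxon label, gene id).
    """
    contig_ids = {c.id for c in contigs}
    missing_regions = sorted({r.contig_id for r in gene_regions} - contig_ids)
    if missing_regions:
        raise DataError(f"gene regions reference unknown contigs: {missing_regions[:10]}")
    missing_frags = sorted({f.contig_id for f in fragments} - contig_ids)
    if missing_frags:
        raise DataError(f"fragments reference unknown contigs: {missing_frags[:10]}")
    contig_len = {c.id: len(c) for c in contigs}
    for r in gene_regions:
        if r.start < 0 or r.end > contig_len[r.contig_id]:
            raise DataError(
                f"gene region [{r.start},{r.end}) outside contig {r.contig_id!r}"
            )

    resolved = resolve_contig_taxa(
        sorted(contig_ids),
        contig_taxa,
        taxonomy,
        tie_policy=tie_policy,
        keep_unassigned=keep_unassigned,
    )

    def contig_label(cid: str) -> tuple[str, str | None] | None:
        ct = resolved[cid]
        if ct is None:  # ambiguous (or dropped unassigned) contig
            return None
        if ct.taxon_id is None:
            return UNCLASSIFIED, None
        label = lineage_at_rank(ct.taxon_id, rank, taxonomy)
        return (label, ct.taxon_id) if label is not None else (UNCLASSIFIED, ct.taxon_id)

    # fragment intervals grouped per contig, fragment ids interned globally
    frag_index: dict[str, int] = {}
    for f in fragments:
        frag_index.setdefault(f.fragment_id, len(frag_index))
    per_contig: dict[str, list[AlignedFragment]] = {}
    for f in fragments:
        per_contig.setdefault(f.contig_id, []).append(f)
    index = {cid: _ContigIndex(fs, frag_index) for cid, fs in per_contig.items()}
    total_fragments = len(frag_index)

    # genome-wide depth per taxon label (over that label's contigs)
    label_bases: dict[str, int] = {}
    label_length: dict[str, int] = {}
    for cid in contig_ids:
        lab = contig_label(cid)
        if lab is None:
            continue
        label, _ = lab
        label_length[label] = label_length.get(label, 0) + contig_len[cid]
        if cid in index:
            label_bases[label] = label_bases.get(label, 0) + index[cid].total_bases
    genome_depth = {
        label: label_bases.get(label, 0) / length
        for label, length in label_length.items()
        if length > 0
    }

    acc: dict[tuple[str, str], dict] = {}
    for region in sorted(gene_regions, key=lambda r: (r.contig_id, r.start, r.end)):
        lab = contig_label(region.contig_id)
        if lab is None:
            continue
        label, taxon_id = lab
        count, bases = (
            index[region.contig_id].overlap(region.start, region.end)
            if region.contig_id in index
            else (0, 0)
        )
        length = len(region)
        slot = acc.setdefault(
            (label, region.gene_id),
            {"count": 0, "bases": 0, "length": 0, "depth": 0.0, "taxon_id": taxon_id},
        )
        slot["count"] += count
        slot["bases"] += bases
        slot["length"] += length
        slot["depth"] += bases / length if length > 0 else 0.0

    features: list[JointFeature] = []
    for (label, gene_id) in sorted(acc):
        slot = acc[(label, gene_id)]
        if drop_zeros and slot["count"] == 0:
            continue
        md = slot["depth"] if depth_mode == "dosage" else (
            slot["bases"] / slot["length"] if slot["length"] > 0 else 0.0
        )
        gdepth = genome_depth.get(label, 0.0)
        stats = DepthStats(
            fragment_count=slot["count"],
            aligned_bases=slot["bases"],
            region_length=slot["length"],
            mean_depth=md,
            fpkm=(
                fpkm(slot["count"], slot["length"], total_fragments)
                if total_fragments > 0 and slot["length"] > 0
                else 0.0
            ),
            depth_per_genome=(md / gdepth) if gdepth > 0 else None,
        )
        features.append(
            JointFeature(sample_id, label, gene_id, stats, taxon_id=slot["taxon_id"])
        )
    return features
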