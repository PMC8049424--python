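"""Contig taxonomy: assignment parsing, ambiguity filtering, lineage lookup.

A contig inherits the taxon of its best reference hit; contigs whose top
score is tied across several taxa are ambiguous and are excluded from
joint profiling (optionally resolved to their lowest common ancestor
instead). Contigs with no assignment at all are retained under the label
``"unclassified"`` so their read mass still contributes to totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .errors import DataError, FormatError

__all__ = [
    "RANKS",
    "TaxonAssignmentRow",
    "ContigTaxon",
    "TaxonomyTable",
    "read_taxon_assignments",
    "filter_ambiguous",
    "lineage_at_rank",
    "resolve_contig_taxa",
]

UNCLASSIFIED = "unclassified"

#: Canonical rank order, most inclusive first.
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class TaxonAssignmentRow:
    contig_id: str
    taxon_id: str
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("assignment score must be >= 0")


@dataclass
class ContigTaxon:
    """A contig's resolved taxonomic assignment with (partial) lineage."""

    contig_id: str
    taxon_id: str | None
    lineage: dict[str, str] = field(default_factory=dict)

    def label(self, rank: str) -> str:
        return self.lineage.get(rank, UNCLASSIFIED)


class TaxonomyTable:
    """taxon_id -> (parent_id, rank, name), with parent-chain walking.

    The on-disk dialect is a 4-column TSV: taxon_id, parent_id, rank, name.
    A node is the root when its parent is itself, empty, or absent from
    the table. The table must be acyclic.
    """

    def __init__(self, nodes: dict[str, tuple[str, str, str]]):
        self._nodes = dict(nodes)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for start in self._nodes:
            seen = set()
            tid = start
            while tid in self._nodes and tid not in seen:
                seen.add(tid)
                parent = self._nodes[tid][0]
                if parent == tid or not parent:
                    break
                tid = parent
            else:
                if tid in seen:
                    raise FormatError(f"taxonomy cycle involving taxon {tid!r}")

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def rank(self, taxon_id: str) -> str:
        return self._node(taxon_id)[1]

    def name(self, taxon_id: str) -> str:
        return self._node(taxon_id)[2]

    def parent(self, taxon_id: str) -> str | None:
        parent = self._node(taxon_id)[0]
        if parent == taxon_id or not parent or parent not in self._nodes:
            return None
        return parent

    def _node(self, taxon_id: str) -> tuple[str, str, str]:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise DataError(f"unknown taxon id {taxon_id!r}") from None

    def ancestors(self, taxon_id: str) -> list[str]:
        """Taxon and its parents up to the root, inclusive of taxon_id."""
        chain = [taxon_id]
        self._node(taxon_id)
        while (parent := self.parent(chain[-1])) is not None:
            chain.append(parent)
        return chain

    def lineage(self, taxon_id: str) -> dict[str, str]:
        """rank -> name for every named rank on the path to the root."""
        out: dict[str, str] = {}
        for tid in self.ancestors(taxon_id):
            _, rank, name = self._nodes[tid]
            if rank in RANKS and rank not in out:
                out[rank] = name
        return out

    def lca(self, taxon_ids: Iterable[str]) -> str | None:
        """Lowest common ancestor of a set of taxa, or None if disjoint."""
        chains = [self.ancestors(t) for t in taxon_ids]
        if not chains:
            return None
        common = set(chains[0])
        for chain in chains[1:]:
            common &= set(chain)
        for tid in chains[0]:  # deepest-first along the first chain
            if tid in common:
                return tid
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        nodes: dict[str, tuple[str, str, str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 columns")
                if lineno == 1 and cols[0].lower() in {"taxon_id", "taxid"}:
                    continue
                nodes[cols[0]] = (cols[1], cols[2], cols[3])
        return cls(nodes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid, (parent, rank, name) in self._nodes.items():
                fh.write(f"{tid}\t{parent}\t{rank}\t{name}\n")


def read_taxon_assignments(path: str | Path) -> list[TaxonAssignmentRow]:
    """Read a >=3-column TSV of contig id, taxon id, score (header optional)."""
    rows: list[TaxonAssignmentRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                score = float(cols[2])
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise FormatError(f"{path}:{lineno}: non-numeric score {cols[2]!r}")
            rows.append(TaxonAssignmentRow(cols[0], cols[1], score))
    return rows


def filter_ambiguous(
    rows: Iterable[TaxonAssignmentRow],
    tie_policy: Literal["drop", "lca"] = "drop",
    taxonomy: TaxonomyTable | None = None,
) -> dict[str, str]:
    """Resolve contig assignments, removing ambiguous contigs.

    A contig is kept iff exactly one taxon attains its maximum score
    (ties are judged on exact score equality). With ``tie_policy="lca"``
    tied contigs are resolved to the lowest common ancestor of the tied
    taxa instead of being dropped.

    Returns contig_id -> taxon_id for kept contigs. Idempotent: feeding
    the output back (as single rows) returns the same mapping.
    """
    if tie_policy == "lca" and taxonomy is None:
        raise ValueError("tie_policy='lca' requires a taxonomy")
    by_contig: dict[str, list[TaxonAssignmentRow]] = {}
    for row in rows:
        by_contig.setdefault(row.contig_id, []).append(row)
    kept: dict[str, str] = {}
    for contig_id, candidates in by_contig.items():
        best = max(r.score for r in candidates)
        top_taxa = sorted({r.taxon_id for r in candidates if r.score == best})
        if len(top_taxa) == 1:
            kept[contig_id] = top_taxa[0]
        elif tie_policy == "lca":
            lca = taxonomy.lca(top_taxa)
            if lca is not None:
                kept[contig_id] = lca
    return kept


def lineage_at_rank(taxon_id: str, rank: str, taxonomy: TaxonomyTable) -> str | None:
    """Name of the ancestor of ``taxon_id`` at ``rank``; None if the walk
    reaches the root without meeting that rank."""
    for tid in taxonomy.ancestors(taxon_id):
        if taxonomy.rank(tid) == rank:
            return taxonomy.name(tid)
    return None


def resolve_contig_taxa(
    contig_ids: Iterable[str],
    rows: Iterable[TaxonAssignmentRow],
    taxonomy: TaxonomyTable,
    tie_policy: Literal["drop", "lca"] = "drop",
    keep_unassigned: bool = True,
) -> dict[str, ContigTaxon | None]:
    """Full per-contig resolution: contig_id -> ContigTaxon, or None for
    contigs excluded by the ambiguity filter.

    Unassigned contigs (no row at all) get an empty lineage (label
    ``unclassified`` at every rank) unless ``keep_unassigned`` is False,
    in which case they are excluded like ambiguous ones.
    """
    rows = list(rows)
    kept = filter_ambiguous(rows, tie_policy=tie_policy, taxonomy=taxonomy)
    seen = {r.contig_id for r in rows}
    out: dict[str, ContigTaxon | None] = {}
    for cid in contig_ids:
        if cid in kept:
            tid = kept[cid]
            out[cid] = ContigTaxon(cid, tid, taxonomy.lineage(tid))
        elif cid in seen:  # ambiguous, filtered out
            out[cid] = None
        else:
            out[cid] = ContigTaxon(cid, None, {}) if keep_unassigned else None
    return out
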