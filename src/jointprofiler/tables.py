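"""Samples × joint-features tables: merging, rank aggregation, TSV keys.

The on-disk key format is "taxonLabel|geneId"; '|' inside taxon names is
escaped as '\\|'. Missing (sample, feature) cells are true zeros — the
depth of a gene never observed in a sample — not NA.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profiler import DepthStats, JointFeature
from .taxonomy import RANKS, UNCLASSIFIED, TaxonomyTable, lineage_at_rank

__all__ = ["FeatureTable", "merge_profiles", "aggregate_rank", "format_key", "parse_key"]

_UNESCAPED_PIPE = re.compile(r"(?<!\\)\|")


def format_key(taxon_label: str, gene_id: str) -> str:
    return taxon_label.replace("|", r"\|") + "|" + gene_id


def parse_key(key: str) -> tuple[str, str]:
    parts = _UNESCAPED_PIPE.split(key)
    if len(parts) < 2:
        raise ValueError(f"feature key {key!r} lacks a '|' separator")
    gene_id = parts[-1]
    taxon = "|".join(parts[:-1]).replace(r"\|", "|")
    return taxon, gene_id


class FeatureTable:
    """A dense samples × joint-features abundance matrix.

    Rows are (taxon_label, gene_id) feature keys, columns are samples;
    values are one chosen abundance statistic, non-negative, with 0 for
    features absent from a sample.
    """

    def __init__(self, frame: pd.DataFrame):
        if not isinstance(frame.index, pd.MultiIndex) or frame.index.nlevels != 2:
            raise ValueError("frame index must be a (taxon_label, gene_id) MultiIndex")
        if frame.index.duplicated().any():
            raise ValueError("duplicate feature keys")
        values = frame.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ValueError("abundance values must be >= 0")
        self.frame = frame.astype(float)

    # -- basic views ---------------------------------------------------
    @property
    def feature_keys(self) -> list[tuple[str, str]]:
        return [tuple(k) for k in self.frame.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.frame.equals(other.frame)

    def subset(
        self,
        features: Sequence[tuple[str, str]] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "FeatureTable":
        frame = self.frame
        if features is not None:
            frame = frame.loc[list(features)]
        if samples is not None:
            frame = frame[list(samples)]
        return FeatureTable(frame)

    # -- string-keyed frame for TSV ------------------------------------
    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.index = pd.Index(
            [format_key(t, g) for t, g in self.frame.index], name="feature"
        )
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        keys = [parse_key(str(k)) for k in df.index]
        out = df.copy()
        out.index = pd.MultiIndex.from_tuples(keys, names=["taxon_label", "gene_id"])
        return cls(out)


def merge_profiles(
    profiles: Sequence[Sequence[JointFeature]], stat_name: str = "mean_depth"
) -> FeatureTable:
    """Merge per-sample profiles into one table of ``stat_name`` values.

    Feature keys are the sorted union across samples; absent pairs are
    filled with 0. Column order follows input order. Duplicate sample
    ids are rejected.
    """
    sample_ids: list[str] = []
    columns: list[dict[tuple[str, str], float]] = []
    for profile in profiles:
        profile = list(profile)
        sid = profile[0].sample_id if profile else f"sample{len(sample_ids) + 1}"
        if sid in sample_ids:
            raise ValueError(f"duplicate sample id {sid!r}")
        sample_ids.append(sid)
        col: dict[tuple[str, str], float] = {}
        for feat in profile:
            value = getattr(feat.stats, stat_name)
            col[feat.key] = float(value) if value is not None else 0.0
        columns.append(col)

    keys = sorted({k for col in columns for k in col})
    index = pd.MultiIndex.from_tuples(keys, names=["taxon_label", "gene_id"]) if keys else (
        pd.MultiIndex.from_arrays([[], []], names=["taxon_label", "gene_id"])
    )
    data = {
        sid: [col.get(k, 0.0) for k in keys] for sid, col in zip(sample_ids, columns)
    }
    frame = pd.DataFrame(data, index=index, columns=sample_ids, dtype=float)
    return FeatureTable(frame)


def aggregate_rank(
    profiles: Sequence[Sequence[JointFeature]],
    from_rank: str,
    to_rank: str,
    taxonomy: TaxonomyTable,
) -> list[list[JointFeature]]:
    """Re-label profiles at a more inclusive rank and pool their statistics.

    Works on profile-level inputs (not finished tables) because depth
    statistics must be recomputed from pooled aligned bases and region
    lengths. Counts, bases, lengths, dosage mean depth and FPKM are all
    additive and are summed; depth per genome is re-derived as the summed
    dosage relative to each source taxon's genome depth and is therefore
    also summed. Features whose lineage lacks ``to_rank`` are bucketed
    under ``unclassified``.
    """
    if from_rank in RANKS and to_rank in RANKS:
        if RANKS.index(to_rank) > RANKS.index(from_rank):
            raise ValueError(f"cannot aggregate downward from {from_rank} to {to_rank}")
    if from_rank == to_rank:
        return [list(p) for p in profiles]

    out: list[list[JointFeature]] = []
    for profile in profiles:
        acc: dict[tuple[str, str], DepthStats] = {}
        sid = profile[0].sample_id if profile else "sample"
        for feat in profile:
            if feat.taxon_id is not None and feat.taxon_id in taxonomy:
                label = lineage_at_rank(feat.taxon_id, to_rank, taxonomy) or UNCLASSIFIED
            else:
                label = UNCLASSIFIED
            key = (label, feat.gene_id)
            slot = acc.setdefault(key, DepthStats())
            s = feat.stats
            slot.fragment_count += s.fragment_count
            slot.aligned_bases += s.aligned_bases
            slot.region_length += s.region_length
            slot.mean_depth += s.mean_depth
            slot.fpkm += s.fpkm
            if s.depth_per_genome is not None and slot.depth_per_genome is not None:
                slot.depth_per_genome += s.depth_per_genome
            else:
                slot.depth_per_genome = None
        out.append(
            [JointFeature(sid, label, gene, acc[(label, gene)]) for label, gene in sorted(acc)]
        )
    return out
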