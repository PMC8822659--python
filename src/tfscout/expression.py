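"""Expression mapping of predicted TF regions.

Read alignments from (meta)transcriptomic libraries are cross-referenced
with predicted TF regions: a region's read count and covered fraction
decide whether the TF is expressed in that sample. Per-sample profiles
aggregate into a TF-family x sample matrix that can be clustered
hierarchically to compare libraries by their expressed TF repertoires.

Only primary, mapped alignments are counted; a read counts for a region
when at least one aligned base overlaps it (configurable). The covered
fraction is the union of aligned-base intervals intersected with the
region, divided by the region length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ConsistencyError, ParameterError
from .translate import Region

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionParams:
    """Thresholds for calling a region expressed."""

    min_reads: int = 1
    min_covered_fraction: float = 0.0

    def __post_init__(self):
        if self.min_reads < 0:
            raise ParameterError(f"min_reads must be >= 0, got {self.min_reads}")
        if not 0.0 <= self.min_covered_fraction <= 1.0:
            raise ParameterError(
                f"min_covered_fraction must be in [0, 1], got {self.min_covered_fraction}"
            )


@dataclass
class ExpressionProfile:
    """Per-region expression calls for one sample."""

    sample_id: str
    table: pd.DataFrame  # region_id, contig, start, end, strand, family, read_count, covered_fraction, expressed
    params: ExpressionParams = field(default_factory=ExpressionParams)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def crossref(
    alignments,
    regions: list[tuple[Region, str]],
    params: ExpressionParams | None = None,
    sample_id: str | None = None,
) -> ExpressionProfile:
    """Cross-reference one SAM/BAM library with predicted TF regions.

    ``regions`` pairs each region with its TF family. Streams the
    alignment file once (no index required); raises ConsistencyError
    when a region's contig is absent from the alignment header.
    """
    params = params or ExpressionParams()
    path = Path(alignments)
    sample_id = sample_id or path.stem
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        refs = set(af.references or ())
        missing = sorted({r.contig_id for r, _ in regions} - refs)
        if missing:
            raise ConsistencyError(
                f"region contigs absent from alignment header of {path.name}: {missing[:5]}"
            )
        by_contig: dict[str, list[int]] = {}
        for i, (region, _) in enumerate(regions):
            by_contig.setdefault(region.contig_id, []).append(i)
        counts = [0] * len(regions)
        covers: list[list[tuple[int, int]]] = [[] for _ in regions]
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            idxs = by_contig.get(read.reference_name)
            if not idxs:
                continue
            blocks = read.get_blocks()
            for i in idxs:
                region = regions[i][0]
                hit = False
                for bs, be in blocks:
                    s, e = max(bs, region.start), min(be, region.end)
                    if s < e:
                        hit = True
                        covers[i].append((s, e))
                if hit:
                    counts[i] += 1
    rows = []
    for i, (region, family) in enumerate(regions):
        covered = _union_length(covers[i]) / region.length
        rows.append(
            {
                "region_id": region.region_id,
                "contig": region.contig_id,
                "start": region.start,
                "end": region.end,
                "strand": region.strand,
                "family": family,
                "read_count": counts[i],
                "covered_fraction": covered,
                "expressed": counts[i] >= params.min_reads
                and covered >= params.min_covered_fraction,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "region_id", "contig", "start", "end", "strand",
            "family", "read_count", "covered_fraction", "expressed",
        ],
    )
    return ExpressionProfile(sample_id=sample_id, table=table, params=params)


def family_matrix(profiles: list[ExpressionProfile]) -> pd.DataFrame:
    """TF-family x sample matrix of expressed-region counts.

    All profiles must cover the same region set. Cell (f, s) counts the
    regions of family f flagged expressed in sample s.
    """
    if not profiles:
        raise ParameterError("at least one profile is required")
    ref_regions = list(profiles[0].table["region_id"])
    for p in profiles[1:]:
        if list(p.table["region_id"]) != ref_regions:
            raise ConsistencyError(
                f"profile {p.sample_id!r} covers a different region set"
            )
    families = sorted(set(profiles[0].table["family"]))
    data = {}
    for p in profiles:
        expressed = p.table[p.table["expressed"]]
        data[p.sample_id] = expressed.groupby("family").size().reindex(families, fill_value=0)
    return pd.DataFrame(data, index=families).fillna(0).astype(int)


@dataclass
class ClusterResult:
    """Hierarchical clustering of the family x sample matrix."""

    row_labels: list[str]
    col_labels: list[str]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list[str]
    col_order: list[str]
    row_newick: str
    col_newick: str

    def cut_rows(self, k: int) -> dict[str, int]:
        return _cut(self.row_linkage, self.row_labels, k)

    def cut_cols(self, k: int) -> dict[str, int]:
        return _cut(self.col_linkage, self.col_labels, k)


def _cut(linkage_matrix, labels, k) -> dict[str, int]:
    if linkage_matrix is None:
        return {lab: 1 for lab in labels}
    assignment = hierarchy.fcluster(linkage_matrix, t=k, criterion="maxclust")
    return dict(zip(labels, (int(a) for a in assignment)))


def _linkage_for(matrix: np.ndarray, method: str, metric: str):
    if matrix.shape[0] < 2:
        return None
    return hierarchy.linkage(pdist(matrix, metric=metric), method=method)


def _newick(linkage_matrix, labels) -> str:
    if linkage_matrix is None:
        return f"{labels[0]};" if labels else ";"
    tree = hierarchy.to_tree(linkage_matrix)

    def render(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def cluster_matrix(
    matrix: pd.DataFrame,
    linkage: str = "average",
    distance: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of rows (families) and columns (samples).

    Counts are log1p-transformed first. Rows and columns are sorted by
    label before linkage so the result is deterministic regardless of
    input order (ties broken by label). A single row or column yields a
    trivial dendrogram with a logged notice.
    """
    if matrix.empty:
        raise ParameterError("matrix must be non-empty")
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    values = np.log1p(matrix.to_numpy(dtype=float))
    row_labels = [str(x) for x in matrix.index]
    col_labels = [str(x) for x in matrix.columns]
    if len(row_labels) < 2 or len(col_labels) < 2:
        logger.info("single row or column: trivial dendrogram")
    row_linkage = _linkage_for(values, linkage, distance)
    col_linkage = _linkage_for(values.T, linkage, distance)
    row_order = (
        [row_labels[i] for i in hierarchy.leaves_list(row_linkage)]
        if row_linkage is not None
        else list(row_labels)
    )
    col_order = (
        [col_labels[i] for i in hierarchy.leaves_list(col_linkage)]
        if col_linkage is not None
        else list(col_labels)
    )
    return ClusterResult(
        row_labels=row_labels,
        col_labels=col_labels,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
        row_order=row_order,
        col_order=col_order,
        row_newick=_newick(row_linkage, row_labels),
        col_newick=_newick(col_linkage, col_labels),
    )
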