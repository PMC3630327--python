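"""Combinatorial GSCA: co-occupancy clustering of enriched datasets.

From the datasets flagged by the enrichment stage, a binary region x dataset
matrix is built, regions bound by only one of those datasets are dropped
(uninformative for combinatorial control), and the datasets are clustered
agglomeratively with 1 - Pearson correlation as the distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .compendium import Compendium
from .enrichment import DEFAULT_ALPHA, GscaReport, run_gsca
from .errors import ValidationError
from .gene_model import PeakGeneMap, map_gene_set_to_regions

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryOccupancyMatrix",
    "Dendrogram",
    "CombinatorialResult",
    "build_binary_matrix",
    "pearson_distance",
    "hierarchical_cluster",
    "run_cgsca",
]

LINKAGES = ("average", "complete", "single")
DEFAULT_CUT_HEIGHT = 0.5


@dataclass
class BinaryOccupancyMatrix:
    """Region x dataset 0/1 matrix restricted to informative rows.

    Every retained row has sum >= 2 over the selected (enriched) columns.
    ``row_indices`` are indices into the compendium universe.
    """

    row_indices: np.ndarray
    dataset_ids: list[str]
    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("region_index\t" + "\t".join(self.dataset_ids) + "\n")
            for idx, row in zip(self.row_indices.tolist(), self.values.tolist()):
                fh.write(str(idx) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def build_binary_matrix(
    compendium: Compendium,
    enriched: Sequence[str],
    restrict_to: Iterable[int] | None = None,
) -> BinaryOccupancyMatrix:
    """Extract the enriched datasets' occupancy columns and drop rows bound
    by fewer than two of them.

    ``restrict_to`` optionally limits candidate rows to a region subset
    (typically the query gene set's regions).
    """
    enriched = list(enriched)
    if len(enriched) < 2:
        raise ValidationError(
            f"combinatorial analysis undefined: {len(enriched)} enriched dataset(s), need >= 2"
        )
    cols = [compendium.column(d) for d in enriched]
    sub = compendium.occupancy[:, cols]
    if restrict_to is not None:
        rows = np.fromiter(sorted(set(restrict_to)), dtype=int)
        if rows.size and (rows[0] < 0 or rows[-1] >= compendium.n_regions):
            raise ValidationError("restrict_to contains indices outside the universe")
        sub = sub[rows]
    else:
        rows = np.arange(compendium.n_regions)
    keep = sub.sum(axis=1) >= 2
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValidationError(
            f"no region is bound by >= 2 of the {len(enriched)} enriched datasets "
            f"({len(rows)} candidate rows, all single-factor or empty)"
        )
    logger.info(
        "binary matrix: kept %d of %d candidate rows (%d single-factor/empty rows dropped)",
        int(keep.sum()), len(rows), n_dropped,
    )
    return BinaryOccupancyMatrix(rows[keep], enriched, sub[keep].astype(np.uint8).copy())


def pearson_distance(matrix: BinaryOccupancyMatrix | np.ndarray) -> np.ndarray:
    """Column-wise distance d(i, j) = 1 - r(column_i, column_j) in [0, 2].

    Zero-variance columns (all 0 or all 1 over the retained rows) have no
    defined correlation; by convention they sit at distance 0 from columns
    identical to them and at distance 1 from everything else, with a
    logged warning.
    """
    X = (matrix.values if isinstance(matrix, BinaryOccupancyMatrix) else np.asarray(matrix))
    X = X.astype(float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("pearson_distance needs a matrix with >= 2 rows and >= 2 columns")
    sd = X.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    d = 1.0 - r
    if degenerate.any():
        logger.warning(
            "%d zero-variance column(s); distance by convention: 0 to identical columns, 1 otherwise",
            int(degenerate.sum()),
        )
        deg = np.nonzero(degenerate)[0]
        for i in deg.tolist():
            same = (X == X[:, [i]]).all(axis=0)
            d[i, :] = np.where(same, 0.0, 1.0)
            d[:, i] = d[i, :]
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def _validate_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-9):
        raise ValidationError("distance matrix must have a zero diagonal")
    if np.any(D < -1e-12):
        raise ValidationError("distance matrix must be non-negative")
    return D


@dataclass
class Dendrogram:
    """Agglomeration result over labeled leaves.

    ``merges`` follows the SciPy linkage convention: row t merges cluster
    ids ``merges[t, 0]`` and ``merges[t, 1]`` (ids < K are leaves, id K + t
    is the cluster created at step t) at height ``merges[t, 2]`` into a
    cluster of ``merges[t, 3]`` leaves.
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _members_after(self, n_merges: int) -> list[list[int]]:
        members: dict[int, list[int]] = {i: [i] for i in range(self.n_leaves)}
        for t in range(n_merges):
            a, b = int(self.merges[t, 0]), int(self.merges[t, 1])
            members[self.n_leaves + t] = members.pop(a) + members.pop(b)
        return sorted(members.values(), key=min)

    def _labelled(self, clusters: list[list[int]]) -> dict[str, int]:
        out: dict[str, int] = {}
        for cl, group in enumerate(clusters, start=1):
            for leaf in group:
                out[self.labels[leaf]] = cl
        return out

    def cut_k(self, k: int) -> dict[str, int]:
        """Cut into exactly k clusters (labels 1..k, ordered by smallest
        leaf index)."""
        if k < 1:
            raise ValidationError("k must be >= 1")
        k = min(k, self.n_leaves)
        return self._labelled(self._members_after(self.n_leaves - k))

    def cut_height(self, height: float) -> dict[str, int]:
        """Cut applying every merge with height <= the threshold."""
        n = int(np.searchsorted(self.merges[:, 2], height, side="right")) if len(self.merges) else 0
        return self._labelled(self._members_after(n))

    def to_newick(self) -> str:
        """Rooted Newick string; branch lengths are merge-height differences."""
        if self.n_leaves == 1:
            return f"{self.labels[0]}:0;"
        height = {i: 0.0 for i in range(self.n_leaves)}
        children: dict[int, tuple[int, int]] = {}
        for t in range(len(self.merges)):
            a, b, h = int(self.merges[t, 0]), int(self.merges[t, 1]), float(self.merges[t, 2])
            node = self.n_leaves + t
            height[node] = h
            children[node] = (a, b)

        def render(node: int, parent_h: float) -> str:
            length = parent_h - height[node]
            if node < self.n_leaves:
                return f"{self.labels[node]}:{length:.6g}"
            a, b = children[node]
            h = height[node]
            return f"({render(a, h)},{render(b, h)}):{length:.6g}"

        root = self.n_leaves + len(self.merges) - 1
        a, b = children[root]
        h = height[root]
        return f"({render(a, h)},{render(b, h)});"

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order of the tree (for heatmap display)."""
        if self.n_leaves == 1:
            return [0]
        children = {
            self.n_leaves + t: (int(self.merges[t, 0]), int(self.merges[t, 1]))
            for t in range(len(self.merges))
        }

        def walk(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            a, b = children[node]
            return walk(a) + walk(b)

        return walk(self.n_leaves + len(self.merges) - 1)


def hierarchical_cluster(
    distance: np.ndarray,
    linkage: str = "average",
    labels: Sequence[str] | None = None,
) -> Dendrogram:
    """Agglomerative clustering with Lance-Williams distance updates.

    Ties in the minimum inter-cluster distance are broken deterministically
    by the lowest cluster index pair.  Merge heights are non-decreasing for
    average, complete and single linkage.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    D = _validate_distance(distance)
    K = D.shape[0]
    if labels is None:
        labels = [str(i) for i in range(K)]
    elif len(labels) != K:
        raise ValidationError("labels length must match the distance matrix")

    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(K) for j in range(i + 1, K)
    }
    size = {i: 1 for i in range(K)}
    active = set(range(K))
    merges: list[list[float]] = []
    next_id = K
    for _ in range(K - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            if linkage == "average":
                dn = (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
            elif linkage == "complete":
                dn = max(dac, dbc)
            else:
                dn = min(dac, dbc)
            dist[(c, new)] = dn
        for pair in [p for p in dist if a in p or b in p]:
            del dist[pair]
        active.discard(a)
        active.discard(b)
        active.add(new)
        size[new] = size[a] + size[b]
        merges.append([float(a), float(b), h, float(size[new])])
    Z = np.array(merges, dtype=float).reshape(max(K - 1, 0), 4)
    return Dendrogram(Z, list(labels))


@dataclass
class CombinatorialResult:
    """Full combinatorial-analysis output for one query."""

    report: GscaReport
    matrix: BinaryOccupancyMatrix
    distance: np.ndarray
    dendrogram: Dendrogram
    clusters: dict[str, int]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.write_tsv(out / "report.tsv")
        self.matrix.write_tsv(out / "matrix.tsv")
        ids = self.matrix.dataset_ids
        with open(out / "distance.tsv", "w") as fh:
            fh.write("dataset_id\t" + "\t".join(ids) + "\n")
            for i, d in enumerate(ids):
                row = "\t".join(f"{v:.6f}" for v in self.distance[i])
                fh.write(f"{d}\t{row}\n")
        (out / "dendrogram.nwk").write_text(self.dendrogram.to_newick() + "\n")
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("dataset_id\tcluster\n")
            for d in ids:
                fh.write(f"{d}\t{self.clusters[d]}\n")


def run_cgsca(
    compendium: Compendium,
    pgmap: PeakGeneMap,
    gene_set: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    correction: str = "bonferroni",
    linkage: str = "average",
    cut_k: int | None = None,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    restrict_to_gene_set: bool = True,
    query_name: str = "query",
) -> CombinatorialResult:
    """Full combinatorial pipeline: enrichment -> binary matrix ->
    correlation distance -> hierarchical clustering -> cluster labels.

    By default the matrix rows are restricted to the query gene set's
    regions, so the clusters describe co-occupancy at the gene set's own
    loci; ``restrict_to_gene_set=False`` switches to the genome-wide
    universe.  Clusters come from a cut at ``cut_k`` groups when given,
    otherwise at correlation-distance ``cut_height``.
    """
    gene_set = set(gene_set)
    report = run_gsca(compendium, pgmap, gene_set, alpha, correction, query_name)
    sig = set(report.significant_datasets())
    enriched = [d for d in compendium.dataset_ids if d in sig]
    if len(enriched) < 2:
        raise ValidationError(
            f"combinatorial stage: only {len(enriched)} significant dataset(s) "
            f"at alpha={alpha}; need >= 2"
        )
    restrict = sorted(map_gene_set_to_regions(gene_set, pgmap)) if restrict_to_gene_set else None
    matrix = build_binary_matrix(compendium, enriched, restrict)
    distance = pearson_distance(matrix)
    dendro = hierarchical_cluster(distance, linkage, labels=matrix.dataset_ids)
    clusters = dendro.cut_k(cut_k) if cut_k is not None else dendro.cut_height(cut_height)
    n_clusters = len(set(clusters.values()))
    logger.info(
        "C-GSCA %r: %d enriched datasets, %d informative regions, %d cluster(s)",
        query_name, len(enriched), matrix.shape[0], n_clusters,
    )
    return CombinatorialResult(report, matrix, distance, dendro, clusters)
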