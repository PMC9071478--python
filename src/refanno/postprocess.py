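"""Post-classification steps: recapturing 'unassigned' cells and the
large-query speed-up.

Recapture relabels 'unassigned' cells sitting inside clusters dominated by
one assigned label.  The speed-up, for queries above a cell-count trigger,
merges transcriptionally homogeneous sub-clusters of cells into single
pseudo-cells before annotation and transfers labels back afterwards.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix, ValidationError

__all__ = [
    "ClusterPartition",
    "MergeMap",
    "cluster_cells",
    "recapture_unassigned",
    "merge_k",
    "merge_cells",
    "transfer_labels",
]


@dataclass
class ClusterPartition:
    """Dense cluster assignment of query cells (cluster ids 0..K-1)."""

    assignment: dict[str, int]
    n_pcs: int
    resolution: float
    embedding: np.ndarray = None  # cells x PCs, in assignment key order

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for b, c in self.assignment.items():
            out.setdefault(c, []).append(b)
        return out


@dataclass
class MergeMap:
    """Partition of query cells into merged pseudo-cells."""

    members: dict[str, list[str]]  # merged_cell_id -> barcodes
    merged: CountMatrix
    identity: bool = False


def cluster_cells(
    query: CountMatrix,
    n_pcs: int = 50,
    resolution: float = 3.0,
    n_neighbors: int = 20,
    seed: int = 1,
) -> ClusterPartition:
    """Unsupervised clustering of query cells.

    Log-normalize (CP10K), scale, PCA, shared-nearest-neighbor graph and
    modularity (Leiden) community detection at the given resolution; fully
    seeded.  With fewer than 3 cells each cell is its own cluster.
    """
    import scanpy as sc
    import anndata

    n_cells = len(query.cells)
    if n_cells < 2:
        raise ValidationError("clustering needs >= 2 cells")
    if n_cells < 3:
        return ClusterPartition(
            {b: i for i, b in enumerate(query.cells)}, n_pcs, resolution
        )
    x = query.counts.T if sp.issparse(query.counts) else np.asarray(query.counts).T
    adata = anndata.AnnData(
        X=sp.csr_matrix(x, dtype=np.float32) if not sp.issparse(x) else x.tocsr().astype(np.float32)
    )
    adata.obs_names = list(query.cells)
    adata.var_names = list(query.genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        sc.pp.scale(adata, max_value=10)
        n_comps = int(min(n_pcs, n_cells - 1, len(query.genes) - 1))
        sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
        sc.pp.neighbors(
            adata, n_neighbors=min(n_neighbors, n_cells - 1), random_state=seed
        )
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
    raw = [int(c) for c in adata.obs["leiden"]]
    remap = {c: i for i, c in enumerate(dict.fromkeys(raw))}
    assignment = {b: remap[c] for b, c in zip(query.cells, raw)}
    return ClusterPartition(
        assignment, n_comps, resolution, embedding=np.asarray(adata.obsm["X_pca"])
    )


def recapture_unassigned(
    labels: dict[str, str],
    partition: ClusterPartition,
    majority: float = 0.5,
    max_unassigned: float = 0.20,
) -> tuple[dict[str, str], set[str]]:
    """Relabel 'unassigned' cells inside label-dominated clusters.

    Within each cluster, if a single non-'unassigned' label covers strictly
    more than ``majority`` of ALL cluster cells and 'unassigned' cells make
    up strictly less than ``max_unassigned`` of the cluster, the cluster's
    'unassigned' cells take that label.  Returns the updated labels and the
    set of recaptured barcodes; already-labeled cells are never changed.
    """
    missing = [b for b in partition.assignment if b not in labels]
    if missing:
        raise ValidationError(f"labels missing for clustered cells: {missing[:5]}")
    out = dict(labels)
    recaptured: set[str] = set()
    for cluster, members in partition.members().items():
        lab_counts = Counter(out[b] for b in members)
        n = len(members)
        n_unassigned = lab_counts.get("unassigned", 0)
        if n_unassigned == 0:
            continue
        assigned = {l: c for l, c in lab_counts.items() if l != "unassigned"}
        if not assigned:
            continue
        top_label = min(assigned, key=lambda l: (-assigned[l], l))
        if assigned[top_label] / n > majority and n_unassigned / n < max_unassigned:
            for b in members:
                if out[b] == "unassigned":
                    out[b] = top_label
                    recaptured.add(b)
    return out, recaptured


def merge_k(cluster_size: int, n_total: int, divisor: int = 3000) -> int:
    """Sub-cluster count for one cluster: k = cluster_size / m, m = total / divisor."""
    m = n_total / divisor
    return min(max(1, int(round(cluster_size / m))), cluster_size)


def merge_cells(
    query: CountMatrix,
    trigger: int = 5000,
    divisor: int = 3000,
    n_pcs: int = 50,
    resolution: float = 3.0,
    seed: int = 1,
) -> MergeMap:
    """Merge cells of large queries into pseudo-cells to bound the workload.

    Queries with at most ``trigger`` cells get an identity map.  Otherwise
    cells are clustered, each cluster is split by k-means into
    ``k = max(1, round(cluster_size / m))`` sub-clusters with
    ``m = total_cells / divisor``, and every sub-cluster's cells are summed
    into one pseudo-cell (keeping counts integral), so the merged matrix
    holds about ``divisor`` pseudo-cells.
    """
    from sklearn.cluster import KMeans

    n_cells = len(query.cells)
    if n_cells <= trigger:
        return MergeMap(
            {b: [b] for b in query.cells},
            query,
            identity=True,
        )
    partition = cluster_cells(query, n_pcs=n_pcs, resolution=resolution, seed=seed)
    emb = partition.embedding
    pos = {b: i for i, b in enumerate(query.cells)}
    members: dict[str, list[str]] = {}
    for cluster, barcodes in sorted(partition.members().items()):
        k = merge_k(len(barcodes), n_cells, divisor)
        if k == 1:
            sub = {0: barcodes}
        else:
            coords = emb[[pos[b] for b in barcodes], :]
            km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(coords)
            sub = {}
            for b, lab in zip(barcodes, km.labels_):
                sub.setdefault(int(lab), []).append(b)
        for lab in sorted(sub):
            members[f"m{cluster}_{lab}"] = sub[lab]
    cols = []
    ids = []
    for mid in members:
        subm = query.counts[:, [pos[b] for b in members[mid]]]
        cols.append(np.asarray(subm.sum(axis=1)).ravel())
        ids.append(mid)
    merged = CountMatrix(list(query.genes), ids, np.column_stack(cols))
    return MergeMap(members, merged)


def transfer_labels(
    merged_labels: dict[str, str], merge_map: MergeMap
) -> dict[str, str]:
    """Propagate each merged pseudo-cell's label to its member cells verbatim."""
    out: dict[str, str] = {}
    for mid, barcodes in merge_map.members.items():
        if mid not in merged_labels:
            raise ValidationError(f"merged cell {mid!r} has no label")
        for b in barcodes:
            out[b] = merged_labels[mid]
    return out
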