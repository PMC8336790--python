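"""Per-variant effect matrix and Ward minimum-variance clustering.

Builds the SNP x adiposity-trait matrix of per-variant effect sizes
(beta x 100) and clusters rows (and optionally columns) with Ward's
minimum-variance method, so that groups of variants acting on the same fat
depot become visible as blocks in a heatmap.

The linkage is the Lance-Williams recursion on squared Euclidean
distances with heights reported on the distance scale (the "Ward.D2"
convention: the height of a merge is the square root of the recursively
updated squared distance, which is twice the increase in within-cluster
sum of squares). Ties are broken by the smallest (left, right) cluster
index pair, so dendrograms are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .internal_gwas import GwasResult
from .association_stats import ADIPOSITY_TRAITS


@dataclass
class EffectMatrix:
    """Variants (rows, annotated by source trait) x adiposity traits
    (columns), cells = internal-GWAS beta x 100."""

    values: pd.DataFrame  # index: variant keys, columns: adiposity traits
    row_source: pd.Series  # variant key -> source trait
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class LinkageTree:
    """Agglomerative merge history in scipy linkage format.

    ``merges[i] = (left, right, height, size)`` with cluster ids < n for
    leaves and n + i for the cluster created at step i; heights are
    non-decreasing (Ward is reducible).
    """

    merges: np.ndarray  # (n-1, 4)
    leaf_order: list[int]

    @property
    def n_leaves(self) -> int:
        return len(self.merges) + 1


def build_effect_matrix(results: list[GwasResult],
                        selected: dict[str, "RiskSet"]) -> EffectMatrix:
    """Assemble beta x 100 cells for every selected variant against each
    adiposity trait; variants missing any estimate are dropped with an
    audit row. ``selected`` maps source trait -> its risk set."""
    by_key = {(r.key, r.trait): r for r in results}
    rows, sources, audit_rows = [], [], []
    for source_trait, rs in selected.items():
        for e in rs.entries:
            cells = {}
            missing = False
            for t in ADIPOSITY_TRAITS:
                r = by_key.get((e.key, t))
                if r is None:
                    missing = True
                    break
                cells[t] = 100.0 * r.beta
            if missing:
                audit_rows.append({"key": e.key, "source_trait": source_trait,
                                   "reason": "missing_estimate"})
                continue
            rows.append(pd.Series(cells, name=e.key))
            sources.append(source_trait)
    values = pd.DataFrame(rows, columns=list(ADIPOSITY_TRAITS))
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValueError("non-finite effect estimates in matrix")
    return EffectMatrix(values=values,
                        row_source=pd.Series(sources, index=values.index),
                        audit=pd.DataFrame(audit_rows,
                                           columns=["key", "source_trait", "reason"]))


def ward_linkage(points: np.ndarray) -> LinkageTree:
    """Ward's minimum-variance agglomerative clustering.

    Lance-Williams update on squared Euclidean distances:
    ``d2(k, i+j) = ((n_i+n_k) d2_ik + (n_j+n_k) d2_jk - n_k d2_ij) / (n_i+n_j+n_k)``;
    the merged pair minimizes d2, ties broken by smallest (left, right)
    index; reported heights are sqrt(d2).
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if not np.isfinite(X).all():
        raise ValueError("non-finite input")

    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    dist: dict[frozenset, float] = {
        frozenset((i, j)): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                d = dist[frozenset((i, j))]
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d_ij, i, j = best
        ni, nj = active[i], active[j]
        merges[step] = (i, j, np.sqrt(max(d_ij, 0.0)), ni + nj)
        del active[i], active[j]
        for k in list(active):
            nk = active[k]
            d_ik = dist.pop(frozenset((i, k)))
            d_jk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (
                (ni + nk) * d_ik + (nj + nk) * d_jk - nk * d_ij) / (ni + nj + nk)
        del dist[frozenset((i, j))]
        active[next_id] = ni + nj
        next_id += 1

    from scipy.cluster.hierarchy import leaves_list
    order = leaves_list(merges.astype(float)).tolist()
    return LinkageTree(merges=merges, leaf_order=order)


def cut_tree_wss(points: np.ndarray, tree: LinkageTree, k: int) -> float:
    """Total within-cluster sum of squares after cutting the tree at k
    clusters (used to test monotonicity in k)."""
    from scipy.cluster.hierarchy import fcluster
    labels = fcluster(tree.merges, t=k, criterion="maxclust")
    X = np.atleast_2d(np.asarray(points, dtype=float))
    wss = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        wss += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return wss


def canonical_leaf_order(tree: LinkageTree, labels) -> list[int]:
    """Leaf order with children of every merge arranged by their subtree's
    smallest label. Unlike raw dendrogram order this depends only on the
    tree topology and the labels, so permuting the input rows permutes
    nothing in the rendered output."""
    labels = list(labels)
    n = tree.n_leaves
    node: dict[int, tuple] = {i: (labels[i], [i]) for i in range(n)}
    for step, (a, b, _, _) in enumerate(tree.merges):
        la, lb = node.pop(int(a)), node.pop(int(b))
        first, second = (la, lb) if la[0] <= lb[0] else (lb, la)
        node[n + step] = (first[0], first[1] + second[1])
    (_, order), = node.values()
    return order


def render_heatmap(em: EffectMatrix, rows_tree: LinkageTree,
                   cols_tree: LinkageTree | None, path: str,
                   tsv_path: str | None = None) -> tuple[str, str]:
    """Write a raster heatmap and a TSV of the matrix in canonical
    dendrogram leaf order (so the clustering is machine-checkable without
    image parsing). Returns (image path, tsv path)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    row_order = canonical_leaf_order(rows_tree, em.values.index)
    col_order = (canonical_leaf_order(cols_tree, em.values.columns)
                 if cols_tree is not None else list(range(em.values.shape[1])))
    ordered = em.values.iloc[row_order, col_order]
    tsv_path = tsv_path or (path.rsplit(".", 1)[0] + ".tsv")
    with open(tsv_path, "w") as fh:
        fh.write("# ward linkage, D2 height convention; rows/cols in dendrogram leaf order\n")
        fh.write("# row_leaf_order=" + ",".join(map(str, row_order)) + "\n")
        fh.write("# col_leaf_order=" + ",".join(map(str, col_order)) + "\n")
        src = em.row_source.iloc[row_order]
        out = ordered.copy()
        out.insert(0, "source_trait", src.values)
        out.to_csv(fh, sep="\t", index_label="key", lineterminator="\n",
                   float_format="%.6g")

    fig, ax = plt.subplots(figsize=(6, max(3, 0.18 * len(ordered))))
    im = ax.pcolormesh(ordered.to_numpy(dtype=float), cmap="RdBu_r")
    ax.set_xticks(np.arange(ordered.shape[1]) + 0.5, ordered.columns, rotation=45)
    ax.set_yticks(np.arange(ordered.shape[0]) + 0.5, ordered.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="beta x 100")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path, tsv_path
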