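"""Hierarchical clustering of contrasts on log2-fold-change profiles.

Contrasts (not genes) are the objects being clustered: each wildtype-mutant
pair contributes one column of per-gene log2 fold changes, restricted to
genes tested in every contrast. With a shared transcriptional response
planted in the regeneration pairs, those columns correlate and the
regeneration mutants form an exclusive clade — the qualitative structure
this module is built to expose.

Agglomeration is implemented directly (correlation or Euclidean distance,
average or complete linkage) with a deterministic tie-break — among equally
close cluster pairs the one with the smallest id pair merges first — so
merge order is stable across platforms. The merge table uses the SciPy
linkage layout, so standard dendrogram tooling applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import ContrastTable

__all__ = [
    "FoldChangeProfileError",
    "LinkageTree",
    "build_profile_matrix",
    "cluster_contrasts",
    "tree_to_newick",
    "smallest_clade_containing",
]


class FoldChangeProfileError(ValueError):
    """Raised for degenerate profile matrices (too few contrasts, flat columns)."""


@dataclass
class LinkageTree:
    """Agglomeration result: SciPy-style merge table plus leaf labels.

    ``merges`` has one row per merge: (node_a, node_b, height, size), where
    nodes 0..n-1 are leaves in ``labels`` order and node n+k is the cluster
    created by merge k. Heights are cophenetic distances.
    """

    merges: np.ndarray = field(repr=False)
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_members(self) -> dict[int, frozenset[str]]:
        """Leaf label set of every node, keyed by node id."""
        members: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        for k, (a, b, _h, _s) in enumerate(self.merges):
            members[self.n_leaves + k] = members[int(a)] | members[int(b)]
        return members

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["node_a", "node_b", "height", "size"]
        ).astype({"node_a": int, "node_b": int, "size": int})


def build_profile_matrix(
    contrasts: dict[str, ContrastTable],
    pair_order: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Genes x pairs matrix of log2 fold changes, complete cases only.

    Genes lacking a defined log2FC in any contrast are dropped.
    """
    if len(contrasts) < 2:
        raise FoldChangeProfileError("need at least 2 contrasts to cluster")
    order = list(pair_order) if pair_order is not None else list(contrasts)
    cols = {p: contrasts[p].table["log2fc"] for p in order}
    mat = pd.DataFrame(cols)
    mat = mat.dropna(axis=0, how="any")
    mat.index.name = "gene"
    return mat


def _pairwise_distances(profiles: pd.DataFrame, metric: str) -> np.ndarray:
    x = profiles.to_numpy(dtype=float)
    if metric == "euclidean":
        diff = x[:, :, None] - x[:, None, :]
        return np.sqrt((diff**2).sum(axis=0))
    if metric == "correlation":
        sd = x.std(axis=0)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            names = [profiles.columns[i] for i in flat]
            raise FoldChangeProfileError(
                f"zero-variance column(s) under correlation metric: {names}"
            )
        return 1.0 - np.corrcoef(x, rowvar=False)
    raise ValueError("metric must be 'correlation' or 'euclidean'")


def cluster_contrasts(
    profiles: pd.DataFrame,
    metric: str = "correlation",
    linkage: str = "average",
) -> LinkageTree:
    """Agglomerative clustering of contrast columns.

    Correlation distance is ``1 - Pearson r`` between columns. Cluster
    distances are recomputed from the leaf-level distance matrix (mean over
    cross pairs for average linkage, max for complete). Ties merge the pair
    with the lexicographically smallest (id_a, id_b).
    """
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    d = _pairwise_distances(profiles, metric)
    labels = tuple(str(c) for c in profiles.columns)
    n = len(labels)
    if n < 2:
        raise FoldChangeProfileError("need at least 2 columns")

    active: dict[int, list[int]] = {i: [i] for i in range(n)}  # node id -> leaf indices
    merges = np.zeros((n - 1, 4))
    next_id = n
    for k in range(n - 1):
        best = None
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                block = d[np.ix_(active[a], active[b])]
                dist = block.mean() if linkage == "average" else block.max()
                key = (dist, a, b)
                if best is None or key < best:
                    best = key
        dist, a, b = best
        merges[k] = (a, b, dist, len(active[a]) + len(active[b]))
        active[next_id] = active.pop(a) + active.pop(b)
        next_id += 1
    return LinkageTree(merges=merges, labels=labels)


def smallest_clade_containing(tree: LinkageTree, labels) -> frozenset[str]:
    """Leaf set of the smallest clade containing all of ``labels``."""
    want = frozenset(labels)
    if not want <= frozenset(tree.labels):
        raise KeyError(f"labels not in tree: {sorted(want - frozenset(tree.labels))}")
    best = frozenset(tree.labels)
    for members in tree.node_members().values():
        if want <= members and len(members) < len(best):
            best = members
    return best


def tree_to_newick(tree: LinkageTree) -> str:
    """Serialize to Newick with ultrametric branch lengths.

    Each node sits at half its merge height, so the two children of a merge
    at height h end at depth h/2 below it; leaves sit at height 0.
    """
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h, _s) in enumerate(tree.merges):
        node = n + k
        heights[node] = float(h) / 2.0
        children[node] = (int(a), int(b))

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            return f"{tree.labels[node]}:{length:.10g}"
        a, b = children[node]
        inner = ",".join(render(c, heights[node]) for c in (a, b))
        return f"({inner}):{length:.10g}"

    root = n + len(tree.merges) - 1
    a, b = children[root]
    inner = ",".join(render(c, heights[root]) for c in (a, b))
    return f"({inner});"
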