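"""Jaccard co-occurrence clustering of the binary presence matrix.

Both axes of the presence matrix are clustered independently: chemicals
(rows) by the similarity of the exposure-source categories they appear
in, and categories (columns) by the similarity of the chemicals they
contain.  Each axis goes through the same sequence:

1. Jaccard distance ``d(A, B) = 1 - |A n B| / |A u B|`` between binary
   vectors, a metric on non-empty sets;
2. agglomerative hierarchical clustering of the distance matrix;
3. cluster-count selection from the average-silhouette profile over
   ``2 <= k <= k_max`` (global argmax, or by default the first local
   maximum of the profile), with the within-cluster sum of squares
   (pairwise-distance form) reported alongside as an elbow diagnostic;
4. cluster labels renumbered 1..k in order of first appearance along the
   dendrogram leaf order, so cluster 1 is at the top of the heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "DendrogramTree",
    "KSelectionProfile",
    "ClusterSolution",
    "jaccard_distance",
    "hclust_tree",
    "cut_at_k",
    "average_silhouette",
    "silhouette_samples",
    "wss",
    "select_k",
    "assign_clusters",
    "biclustered_layout",
    "plot_heatmap",
]

LINKAGE_METHODS = ("single", "complete", "average", "ward")


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.labels):
            raise ValueError("distance matrix must be square and match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(d)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = d

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def jaccard_distance(m: pd.DataFrame, axis: str = "rows") -> DistanceMatrix:
    """Pairwise Jaccard distances between rows or columns of a 0/1 matrix.

    ``d(a, b) = 1 - |A n B| / |A u B|`` where A and B are the sets of
    positions holding a 1.  All-zero vectors have no defined distance and
    raise, naming the offending label.
    """
    if axis not in {"rows", "columns"}:
        raise ValueError("axis must be 'rows' or 'columns'")
    x = m.to_numpy(dtype=bool) if axis == "rows" else m.to_numpy(dtype=bool).T
    labels = [str(v) for v in (m.index if axis == "rows" else m.columns)]
    zero = ~x.any(axis=1)
    if zero.any():
        bad = [labels[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero vector(s) along {axis}: {bad}; Jaccard undefined")
    d = squareform(pdist(x, metric="jaccard"))
    return DistanceMatrix(labels, d)


@dataclass
class DendrogramTree:
    """Agglomerative merge history plus dendrogram leaf order."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 format
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        """Leaf indices in dendrogram (top-to-bottom) order."""
        return hierarchy.leaves_list(self.linkage_matrix)


def hclust_tree(d: DistanceMatrix, method: str = "ward") -> DendrogramTree:
    """Agglomerative clustering of a distance matrix.

    ``method`` is one of single, complete, average (UPGMA) or ward.  The
    agglomeration is deterministic for fixed input, so repeated runs give
    identical trees.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}, got {method!r}")
    if d.n < 2:
        raise ValueError("need at least 2 observations to build a tree")
    z = hierarchy.linkage(d.condensed, method=method)
    return DendrogramTree(list(d.labels), z, method)


def cut_at_k(tree: DendrogramTree, k: int) -> np.ndarray:
    """Cut the tree into exactly ``k`` clusters, numbered by leaf order.

    Labels are renumbered 1..k in order of first appearance along the
    dendrogram leaf order (top to bottom), so the numbering matches the
    heatmap layout.
    """
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in [1, {tree.n_leaves}], got {k}")
    raw = hierarchy.cut_tree(tree.linkage_matrix, n_clusters=k).ravel()
    renumber: dict[int, int] = {}
    for leaf in tree.leaf_order:
        renumber.setdefault(int(raw[leaf]), len(renumber) + 1)
    return np.array([renumber[int(c)] for c in raw], dtype=int)


def silhouette_samples(d: DistanceMatrix, labels: Sequence[int]) -> np.ndarray:
    """Per-point silhouette widths ``s(i) = (b(i) - a(i)) / max(a(i), b(i))``.

    ``a(i)`` is the mean distance from point i to the other members of
    its own cluster and ``b(i)`` the smallest mean distance to any other
    cluster.  Singleton clusters contribute ``s(i) = 0`` by convention.
    Requires at least two clusters.
    """
    lab = np.asarray(labels)
    if lab.shape[0] != d.n:
        raise ValueError("labels length must match distance matrix")
    uniq, inv = np.unique(lab, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    onehot = np.eye(uniq.size)[inv]  # n x k
    sums = d.values @ onehot  # total distance from i to each cluster
    sizes = onehot.sum(axis=0)

    own_size = sizes[inv]
    own_sum = sums[np.arange(d.n), inv]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = own_sum / (own_size - 1)
    means_other = sums / sizes
    means_other[np.arange(d.n), inv] = np.inf
    b = means_other.min(axis=1)
    with np.errstate(invalid="ignore"):
        s = (b - a) / np.maximum(a, b)
    s[own_size == 1] = 0.0  # singleton convention
    return s


def average_silhouette(d: DistanceMatrix, labels: Sequence[int]) -> float:
    """Mean silhouette width over all points (see :func:`silhouette_samples`)."""
    return float(silhouette_samples(d, labels).mean())


def wss(d: DistanceMatrix, labels: Sequence[int]) -> float:
    """Within-cluster sum of squares in the pairwise-distance form.

    For each cluster C, contributes ``sum_{i<j in C} d(i,j)^2 / |C|``.
    This equals the centroid-based WSS when the distances are Euclidean
    and needs no coordinates, so it is defined for a bare distance
    matrix.  Singletons contribute 0.
    """
    lab = np.asarray(labels)
    if lab.shape[0] != d.n:
        raise ValueError("labels length must match distance matrix")
    total = 0.0
    d2 = d.values**2
    for c in np.unique(lab):
        idx = np.flatnonzero(lab == c)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / 2.0 / idx.size
    return float(total)


@dataclass
class KSelectionProfile:
    """Silhouette and WSS across candidate cluster counts.

    ``wss_values`` includes k=1 (the elbow plot starts there) while the
    silhouette profile starts at k=2 where it is first defined.  The
    selected k maximizes the average silhouette width, ties going to the
    smaller k.
    """

    k_values: list[int]
    silhouette: list[float]
    wss_values: list[float]
    selected_k: int
    rule: str = "max_silhouette"

    def as_frame(self) -> pd.DataFrame:
        sil = dict(zip(self.k_values[1:], self.silhouette))
        return pd.DataFrame(
            {
                "k": self.k_values,
                "avg_silhouette": [sil.get(k, np.nan) for k in self.k_values],
                "wss": self.wss_values,
                "selected": [k == self.selected_k for k in self.k_values],
            }
        )


def select_k(d: DistanceMatrix, tree: DendrogramTree, k_max: int = 34) -> KSelectionProfile:
    """Profile silhouette and WSS over tree cuts and pick the best k.

    Cuts the tree at each ``k`` in ``1..min(k_max, n-1)``; the silhouette
    is evaluated for ``k >= 2`` (it is undefined at k=1, where only the
    WSS is recorded) and the selected k attains the maximum average
    silhouette width, with ties broken toward smaller k.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    hi = min(k_max, d.n - 1)
    ks = list(range(1, hi + 1))
    sils: list[float] = []
    wsss: list[float] = []
    for k in ks:
        lab = cut_at_k(tree, k)
        wsss.append(wss(d, lab))
        if k >= 2:
            sils.append(average_silhouette(d, lab))
    best = int(np.argmax(sils))  # argmax returns first (= smallest k) on ties
    return KSelectionProfile(ks, sils, wsss, selected_k=ks[1:][best])


@dataclass
class ClusterSolution:
    """Dual (row + column) clustering of a presence matrix."""

    row_labels: dict[str, int]
    col_labels: dict[str, int]
    row_profile: KSelectionProfile
    col_profile: KSelectionProfile
    row_leaf_order: list[str]
    col_leaf_order: list[str]
    linkage: str = "ward"
    extras: dict = field(default_factory=dict)

    @property
    def n_row_clusters(self) -> int:
        return self.row_profile.selected_k

    @property
    def n_col_clusters(self) -> int:
        return self.col_profile.selected_k

    def assignments_frame(self) -> pd.DataFrame:
        rows = [("row", lbl, c) for lbl, c in self.row_labels.items()]
        cols = [("column", lbl, c) for lbl, c in self.col_labels.items()]
        return pd.DataFrame(rows + cols, columns=["axis", "label", "cluster"])


def collapse_duplicates(m: pd.DataFrame, axis: str) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Group identical binary profiles along an axis.

    Returns the matrix restricted to one representative per distinct
    profile (the lexicographically first label) and a mapping
    representative -> all labels sharing that profile.
    """
    x = m if axis == "rows" else m.T
    groups: dict[tuple, list[str]] = {}
    for lbl in x.index:
        groups.setdefault(tuple(x.loc[lbl]), []).append(str(lbl))
    rep_groups = {min(labels): sorted(labels) for labels in groups.values()}
    reps = sorted(rep_groups)
    sub = x.loc[reps] if axis == "rows" else x.loc[reps].T
    return sub, rep_groups


SELECTION_RULES = ("max_silhouette", "first_silhouette_peak")


def _pick_k(means: dict[int, float], rule: str) -> int:
    """Apply a k-selection rule to the silhouette profile.

    ``max_silhouette``: global argmax, ties to the smaller k.

    ``first_silhouette_peak``: the smallest k at a local maximum of the
    profile (rising into k, non-increasing after it).  On discrete
    presence data the global argmax is dominated by fragmenting
    near-identical profiles into many tiny tight clusters at large k;
    taking the first peak reads the profile the way an analyst inspects
    it and is immune to that degeneracy.
    """
    ks = sorted(means)
    if rule == "max_silhouette":
        return max(ks, key=lambda k: (means[k], -k))
    for k in ks:
        rising = k == ks[0] or means[k] > means[k - 1]
        falling = k == ks[-1] or means[k] >= means[k + 1]
        if rising and falling:
            return k
    return ks[-1]


def _cluster_axis(m: pd.DataFrame, axis: str, linkage: str, k_max: int, rule: str):
    """Cluster one axis: tree over distinct profiles, silhouette over all points.

    Identical profiles are a single co-occurrence pattern, so the tree is
    built over distinct profiles only and every candidate partition keeps
    them together; the silhouette and WSS profiles are still evaluated on
    the full distance matrix, weighting each pattern by its multiplicity.
    Cutting below the zero-height ties would otherwise let the silhouette
    reward splitting identical points into trivial perfect clusters,
    driving the selected k toward n.
    """
    if rule not in SELECTION_RULES:
        raise ValueError(f"selection rule must be one of {SELECTION_RULES}, got {rule!r}")
    d_full = jaccard_distance(m, axis=axis)
    sub, rep_groups = collapse_duplicates(m, axis)
    reps = sorted(rep_groups)
    if len(reps) < 2:
        raise ValueError(f"all {axis} profiles are identical; nothing to cluster")
    d_u = jaccard_distance(sub, axis=axis) if len(reps) < d_full.n else d_full
    tree = hclust_tree(d_u, method=linkage)

    pos = {lbl: i for i, lbl in enumerate(d_full.labels)}

    def broadcast(lab_u: np.ndarray) -> np.ndarray:
        full = np.empty(d_full.n, dtype=int)
        for rep, cluster in zip(d_u.labels, lab_u):
            for lbl in rep_groups[rep]:
                full[pos[lbl]] = cluster
        return full

    # candidate k is capped at one below the distinct-profile count (the
    # all-distinct cut is the degenerate partition k-selection must avoid),
    # except when only two profiles exist and k=2 is the sole partition
    hi = min(k_max, d_full.n - 1, max(d_u.n - 1, 2))
    ks = list(range(1, hi + 1))
    wsss: list[float] = []
    means: dict[int, float] = {}
    for k in ks:
        lab = broadcast(cut_at_k(tree, k))
        wsss.append(wss(d_full, lab))
        if k >= 2:
            means[k] = average_silhouette(d_full, lab)
    selected = _pick_k(means, rule)
    profile = KSelectionProfile(
        ks, [means[k] for k in ks[1:]], wsss, selected_k=selected, rule=rule
    )

    lab_full = broadcast(cut_at_k(tree, profile.selected_k))
    order = [lbl for i in tree.leaf_order for lbl in rep_groups[d_u.labels[i]]]
    return dict(zip(d_full.labels, (int(v) for v in lab_full))), profile, order


def assign_clusters(
    m: pd.DataFrame,
    linkage: str = "ward",
    k_max_rows: int = 34,
    k_max_cols: int = 34,
    selection_rule: str = "first_silhouette_peak",
) -> ClusterSolution:
    """Cluster both axes of the presence matrix (dual clustering).

    Rows (chemicals) and columns (exposure-source categories) each run
    through Jaccard distance -> hierarchical tree -> silhouette-based k
    selection -> cut, independently.  Cluster indices on each axis follow
    first appearance in dendrogram leaf order.  ``selection_rule`` is
    ``first_silhouette_peak`` (default; see :func:`_pick_k`) or
    ``max_silhouette`` (plain argmax).
    """
    row_labels, row_profile, row_order = _cluster_axis(
        m, "rows", linkage, k_max_rows, selection_rule
    )
    col_labels, col_profile, col_order = _cluster_axis(
        m, "columns", linkage, k_max_cols, selection_rule
    )
    return ClusterSolution(
        row_labels, col_labels, row_profile, col_profile, row_order, col_order,
        linkage=linkage,
    )


def biclustered_layout(
    m: pd.DataFrame, sol: ClusterSolution
) -> tuple[pd.DataFrame, list[int], list[int]]:
    """Permute the matrix to dendrogram leaf order for heatmap display.

    Returns the reordered matrix plus the row and column boundary indices
    (positions where the cluster index changes, for drawing separators).
    Cell values are untouched; only the ordering changes.
    """
    if set(sol.row_leaf_order) != set(map(str, m.index)) or set(sol.col_leaf_order) != set(
        map(str, m.columns)
    ):
        raise ValueError("cluster solution labels do not match matrix labels")
    out = m.loc[sol.row_leaf_order, sol.col_leaf_order]
    row_b = [
        i
        for i in range(1, len(sol.row_leaf_order))
        if sol.row_labels[sol.row_leaf_order[i]] != sol.row_labels[sol.row_leaf_order[i - 1]]
    ]
    col_b = [
        j
        for j in range(1, len(sol.col_leaf_order))
        if sol.col_labels[sol.col_leaf_order[j]] != sol.col_labels[sol.col_leaf_order[j - 1]]
    ]
    return out, row_b, col_b


def plot_heatmap(m: pd.DataFrame, sol: ClusterSolution, path: str) -> None:
    """Render the biclustered presence heatmap (presence red, absence blue)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    ordered, row_b, col_b = biclustered_layout(m, sol)
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * ordered.shape[1]), max(6, 0.12 * ordered.shape[0])))
    ax.imshow(ordered.to_numpy(), cmap=ListedColormap(["#3b4cc0", "#b40426"]), aspect="auto")
    for r in row_b:
        ax.axhline(r - 0.5, color="white", lw=1)
    for c in col_b:
        ax.axvline(c - 0.5, color="white", lw=1)
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(ordered.shape[0]))
    ax.set_yticklabels(ordered.index, fontsize=5)
    ax.set_xlabel("exposure source category")
    ax.set_ylabel("chemical")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
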