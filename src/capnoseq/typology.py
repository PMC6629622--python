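"""Typology of respiratory state sequences by Ward hierarchical clustering.

The pairwise dissimilarity matrix is clustered with Ward's minimum-variance
agglomeration in the Ward.D2 convention (the Lance-Williams recurrence on
squared dissimilarities, i.e. ``scipy``'s ``linkage(..., method="ward")`` on
the condensed distances). Candidate solutions over a range of k are scored
with the average silhouette width and the point-biserial correlation between
dissimilarities and a same/different-cluster indicator; the final k is a
user decision informed by that report (defaulting to the four-cluster
typology). Clusters are auto-named by their modal member state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .distance import DissimilarityMatrix
from .states import STATE_ALPHABET, StateSequence

#: Fixed state -> color mapping for sequence index plots.
STATE_COLORS = {
    "NORMAL": "#2e8b57",
    "HYPOPNEA": "#f0a202",
    "BRADYPNEA": "#3a6ea5",
    "APNEA": "#c1292e",
    "MISSING": "#bdbdbd",
}


@dataclass
class ClusterSolution:
    """A k-cluster partition of the cohort with quality metrics."""

    k: int
    ids: list[str]
    labels: np.ndarray  # values in 1..k
    silhouette: float
    point_biserial: float
    dominant_state: dict[int, str] = field(default_factory=dict)

    def sizes(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in range(1, self.k + 1)}


def _ward_linkage(D: DissimilarityMatrix) -> np.ndarray:
    return linkage(squareform(D.values, checks=False), method="ward")


def cut_tree_labels(Z: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage at k clusters; relabel 1..k by order of first appearance."""
    raw = fcluster(Z, t=k, criterion="maxclust")
    seen: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in seen:
            seen[r] = len(seen) + 1
        out[i] = seen[r]
    return out


def cluster_quality(D: DissimilarityMatrix, labels: np.ndarray) -> dict[str, float]:
    """Average silhouette width and point-biserial correlation for a partition.

    Silhouette is computed directly from the precomputed dissimilarities;
    degenerate partitions (all singletons, or any quantity with zero
    variance) report 0 by convention. The point-biserial correlation is
    between d[i][j] over i<j and the different-cluster indicator, so larger
    is better for both metrics.
    """
    n = D.n
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    if k < 2 or k >= n:
        asw = 0.0
    else:
        asw = float(silhouette_score(D.values, labels, metric="precomputed"))
    iu = np.triu_indices(n, k=1)
    d = D.values[iu]
    diff = (labels[iu[0]] != labels[iu[1]]).astype(float)
    if d.std() == 0 or diff.std() == 0:
        pb = 0.0
    else:
        pb = float(np.corrcoef(d, diff)[0, 1])
    return {"silhouette": asw, "point_biserial": pb}


def ward_cluster(
    D: DissimilarityMatrix,
    k: int,
    seqs: list[StateSequence] | None = None,
) -> ClusterSolution:
    """Ward.D2 clustering of a dissimilarity matrix cut at k clusters.

    If the sequences are supplied, each cluster is named by the modal
    (non-missing) state across all member seconds.
    """
    n = D.n
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, {n - 1}]")
    labels = cut_tree_labels(_ward_linkage(D), k)
    q = cluster_quality(D, labels)
    dominant: dict[int, str] = {}
    if seqs is not None:
        by_id = {s.patient_id: s for s in seqs}
        for c in range(1, k + 1):
            counts = dict.fromkeys(STATE_ALPHABET, 0)
            for pid in np.asarray(D.ids, dtype=object)[labels == c]:
                for state in STATE_ALPHABET:
                    counts[state] += int(np.sum(by_id[pid].states == state))
            dominant[c] = max(STATE_ALPHABET, key=lambda s: counts[s])
    return ClusterSolution(
        k=k,
        ids=list(D.ids),
        labels=labels,
        silhouette=q["silhouette"],
        point_biserial=q["point_biserial"],
        dominant_state=dominant,
    )


def quality_report(
    D: DissimilarityMatrix, k_range: range | list[int] = range(2, 7)
) -> dict[int, dict[str, float]]:
    """Quality metrics for every candidate k, for judgment-based selection."""
    Z = _ward_linkage(D)
    report = {}
    for k in k_range:
        labels = cut_tree_labels(Z, k)
        report[k] = cluster_quality(D, labels)
    return report


def select_k(report: dict[int, dict[str, float]]) -> int:
    """The candidate k with the largest average silhouette width
    (smallest k wins ties)."""
    return min(report, key=lambda k: (-report[k]["silhouette"], k))


def merge_heights(D: DissimilarityMatrix) -> np.ndarray:
    """Agglomeration heights of the Ward dendrogram (non-decreasing)."""
    return _ward_linkage(D)[:, 2]


def sequence_index_plot(
    seqs: list[StateSequence],
    labels: np.ndarray | None,
    path: str,
    group_names: dict[int, str] | None = None,
) -> None:
    """Sequence index plot: one panel per group, one horizontal bar per
    patient, seconds on x, color-coded state segments; within each panel
    patients are sorted by decreasing sequence length."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    codes = list(STATE_COLORS)
    cmap = ListedColormap([STATE_COLORS[c] for c in codes])
    if labels is None:
        labels = np.ones(len(seqs), dtype=int)
    labels = np.asarray(labels)
    groups = sorted(np.unique(labels))
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(8, 1.2 + 1.6 * len(groups)), squeeze=False
    )
    max_len = max(len(s) for s in seqs)
    for ax, g in zip(axes.ravel(), groups):
        members = sorted(
            (s for s, l in zip(seqs, labels) if l == g),
            key=lambda s: (-len(s), s.patient_id),
        )
        img = np.full((len(members), max_len), np.nan)
        for row, s in enumerate(members):
            img[row, : len(s)] = [codes.index(c) for c in s.states]
        ax.imshow(
            img, aspect="auto", interpolation="nearest",
            cmap=cmap, vmin=-0.5, vmax=len(codes) - 0.5,
        )
        name = (group_names or {}).get(g, f"cluster {g}")
        ax.set_title(f"{name} (n = {len(members)})", fontsize=9, loc="left")
        ax.set_yticks([])
        ax.set_xlabel("seconds")
    handles = [Patch(color=STATE_COLORS[c], label=c) for c in codes]
    fig.legend(handles=handles, loc="upper right", fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
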