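"""Downstream reporting on fitted TF activities.

Covers the classification of TFs into ecotype-specific ("unique") versus
multi-responsive activity profiles, hierarchical clustering with
correlation distance and average linkage, bootstrap support for the
resulting tree, and a hypergeometric over-representation test for
user-supplied gene sets (Bonferroni-adjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

MAD_SCALE = 1.4826  # consistency factor: MAD -> sd under normality


@dataclass
class TFActivityProfile:
    """Per-TF responsive-condition calls derived from an activity matrix."""

    tf_ids: list[str]
    condition_labels: list[str]
    activities: np.ndarray               # tfs x conditions
    responsive_in: list[set[str]]        # per TF
    category: list[str]                  # unique / multi / none

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tf_id": self.tf_ids,
            "responsive_ecotypes": [";".join(sorted(s)) for s in self.responsive_in],
            "category": self.category,
        })


def classify_responsive(activities: np.ndarray, tf_ids: list[str],
                        condition_labels: list[str],
                        threshold_z: float = 2.0) -> TFActivityProfile:
    """Call the conditions in which each TF is responsive.

    Each TF's activity row is standardized robustly (median/MAD); a condition
    is responsive when |z| >= ``threshold_z``.  A TF responsive in exactly
    one condition is *unique*, in two or more *multi*, else *none*.  Rows
    with zero MAD fall back to calling every condition off the median
    responsive; constant rows therefore classify as none.
    """
    acts = np.asarray(activities, dtype=float)
    if acts.ndim != 2 or acts.shape != (len(tf_ids), len(condition_labels)):
        raise ValueError("activities must be tfs x conditions matching the id lists")
    if acts.shape[1] < 2:
        raise ValueError("need >= 2 conditions to classify responsiveness")
    if threshold_z <= 0:
        raise ValueError("threshold_z must be positive")

    responsive, category = [], []
    for row in acts:
        med = np.median(row)
        mad = np.median(np.abs(row - med))
        if mad == 0:
            # degenerate spread: a majority of conditions sit exactly at the
            # median, so any departure from it is infinitely many MADs out —
            # call those responsive (none for a constant row)
            hit_idx = np.nonzero(row != med)[0]
        else:
            z = (row - med) / (MAD_SCALE * mad)
            hit_idx = np.nonzero(np.abs(z) >= threshold_z)[0]
        hits = {condition_labels[j] for j in hit_idx}
        responsive.append(hits)
        category.append("unique" if len(hits) == 1 else
                        "multi" if len(hits) >= 2 else "none")
    return TFActivityProfile(list(tf_ids), list(condition_labels), acts,
                             responsive, category)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray        # scipy linkage matrix over kept items
    leaf_order: list[int]      # indices into the ORIGINAL item list
    kept: list[int]            # original indices clustered
    dropped: list[int]         # original indices dropped (constant profiles)


def _correlation_condensed(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson r distances between rows (norm-guarded)."""
    c = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1)
    safe = np.where(norm == 0, 1.0, norm)
    z = c / safe[:, None]
    corr = np.clip(z @ z.T, -1.0, 1.0)
    corr[norm == 0, :] = 0.0
    corr[:, norm == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    return 1.0 - corr[iu]


def hierarchical_cluster(matrix: np.ndarray, axis: str = "rows") -> ClusterResult:
    """Average-linkage (UPGMA) clustering under 1 - Pearson r distance.

    Constant profiles have undefined correlation and are dropped with a
    warning before clustering.  SciPy's linkage resolves merge ties by the
    smallest cluster index, making the result deterministic.
    """
    x = np.asarray(matrix, dtype=float)
    if axis == "columns":
        x = x.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")

    norms = np.linalg.norm(x - x.mean(axis=1, keepdims=True), axis=1)
    kept = [i for i in range(x.shape[0]) if norms[i] > 0]
    dropped = [i for i in range(x.shape[0]) if norms[i] == 0]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant profiles before "
                      "correlation clustering", stacklevel=2)
    if len(kept) < 2:
        raise ValueError("fewer than 2 non-constant profiles to cluster")
    sub = x[kept]
    z = hierarchy.linkage(_correlation_condensed(sub), method="average")
    order = hierarchy.leaves_list(z)
    return ClusterResult(linkage=z, leaf_order=[kept[i] for i in order],
                         kept=kept, dropped=dropped)


def _bipartitions(linkage: np.ndarray, n_leaves: int) -> list[frozenset[int]]:
    """Leaf set under each internal node, in linkage row order."""
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n_leaves)}
    out = []
    for k, (a, b, _, _) in enumerate(linkage):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[n_leaves + k] = merged
        out.append(merged)
    return out


def bootstrap_support(matrix: np.ndarray, n_boot: int, seed: int) -> np.ndarray:
    """Bootstrap support for each internal node of the row clustering.

    Columns (conditions) are resampled with replacement ``n_boot`` times; a
    node's support is the fraction of replicate trees containing the same
    leaf set.  Seeded and fully reproducible.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need >= 3 items for bootstrap support")
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    n = x.shape[0]
    base = hierarchy.linkage(_correlation_condensed(x), method="average")
    ref = _bipartitions(base, n)
    counts = np.zeros(len(ref))
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, x.shape[1], size=x.shape[1])
        rep = hierarchy.linkage(_correlation_condensed(x[:, cols]),
                                method="average")
        rep_sets = set(_bipartitions(rep, n))
        for i, node in enumerate(ref):
            if node in rep_sets:
                counts[i] += 1
    return counts / n_boot


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as a Newick tree with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
        heights[n + k] = h
    return nodes[n + len(linkage) - 1] + ";"


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def enrichment_test(gene_list: set[str], universe: set[str],
                    gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Each set is intersected with the universe first; the p-value is the
    upper tail P[X >= overlap] of drawing ``len(gene_list)`` genes without
    replacement.  Bonferroni adjustment multiplies by the number of sets
    tested (capped at 1).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    gene_list = set(gene_list)
    stray = gene_list - universe
    if stray:
        raise ValueError(
            f"gene_list contains genes outside the universe: {sorted(stray)[:5]}")
    m = len(universe)
    n_list = len(gene_list)
    rows = []
    tested = {sid: s & universe for sid, s in gene_sets.items()}
    n_tests = len(tested)
    for sid, members in sorted(tested.items()):
        overlap = len(gene_list & members)
        p = float(stats.hypergeom.sf(overlap - 1, m, len(members), n_list))
        rows.append({
            "set_id": sid,
            "overlap": overlap,
            "set_size": len(members),
            "list_size": n_list,
            "universe_size": m,
            "p_raw": min(p, 1.0),
            "p_adjusted": min(1.0, min(p, 1.0) * n_tests),
        })
    return pd.DataFrame(rows, columns=["set_id", "overlap", "set_size",
                                       "list_size", "universe_size",
                                       "p_raw", "p_adjusted"])


def plot_activity_heatmap(activities: np.ndarray, tf_ids: list[str],
                          condition_labels: list[str], path: str) -> None:
    """Basic TF-activity heat map (matplotlib imshow), rows clustered."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = list(range(len(tf_ids)))
    if len(tf_ids) >= 2:
        try:
            order = hierarchical_cluster(activities).leaf_order
        except ValueError:
            pass
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(condition_labels)),
                                    max(4, 0.25 * len(tf_ids))))
    im = ax.imshow(np.asarray(activities)[order], aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(condition_labels)), condition_labels,
                  rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), [tf_ids[i] for i in order], fontsize=6)
    fig.colorbar(im, ax=ax, label="TF activity (normalized)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
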