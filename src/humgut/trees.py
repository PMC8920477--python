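"""Dendrograms, rooted Robinson-Foulds congruence, and the phylosymbiosis test.

Microbiota dendrograms are built by UPGMA (average-linkage) clustering of a
Sorensen-Dice distance matrix; congruence with the host phylogeny is measured
by the rooted Robinson-Foulds distance (symmetric difference of the trees'
clade sets), normalised to [0, 1]; significance comes from comparing the
observed score against scores of randomised tree topologies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .dissimilarity import DistanceMatrix

__all__ = [
    "PhylosymbiosisResult",
    "upgma",
    "rooted_clusters",
    "rooted_rf",
    "normalized_rf",
    "random_pair_normalized_rf",
    "random_topology",
    "shuffled_labels_topology",
    "phylosymbiosis_test",
    "read_newick",
    "write_newick",
    "leaf_names",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def read_newick(source) -> TreeNode:
    """Read a rooted tree from a newick file path or literal newick string."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        return TreeNode.read(io.StringIO(source))
    return TreeNode.read(str(source))


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))


def leaf_names(tree: TreeNode) -> frozenset:
    return frozenset(t.name for t in tree.tips())


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) dendrogram of a distance matrix.

    At each step the pair of clusters with minimal mean cross-pair distance
    is merged; the merged node sits at height = merge distance / 2, so the
    result is ultrametric. Ties are broken by the lexicographic order of each
    cluster's smallest member label, making the dendrogram deterministic.
    Branch lengths encode height differences.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("UPGMA requires at least 2 labels")
    d = dm.values.astype(float).copy()
    active = list(range(n))
    nodes = {i: TreeNode(name=dm.labels[i]) for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    minlab = {i: dm.labels[i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    next_id = n
    # grow the working matrix as merges add rows
    d = np.pad(d, ((0, n - 1), (0, n - 1)), constant_values=np.inf)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (d[i, j], *sorted((minlab[i], minlab[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        merge_d = d[i, j]
        h = merge_d / 2.0
        left, right = nodes[i], nodes[j]
        left.length = h - heights[i]
        right.length = h - heights[j]
        new = TreeNode(children=[left, right])
        k = next_id
        next_id += 1
        nodes[k] = new
        heights[k] = h
        minlab[k] = min(minlab[i], minlab[j])
        sizes[k] = sizes[i] + sizes[j]
        for m in active:
            if m in (i, j):
                continue
            # UPGMA (unweighted) update: size-weighted mean of cross distances
            d[k, m] = d[m, k] = (sizes[i] * d[i, m] + sizes[j] * d[j, m]) / sizes[k]
        active = [m for m in active if m not in (i, j)] + [k]
    return nodes[active[0]]


# ---------------------------------------------------------------------------
# Rooted Robinson-Foulds
# ---------------------------------------------------------------------------

def rooted_clusters(tree: TreeNode) -> set:
    """Non-trivial clades of a rooted tree as a set of frozen leaf-name sets.

    Singletons and the full leaf set are excluded as uninformative.
    """
    all_leaves = leaf_names(tree)
    if len(all_leaves) != sum(1 for _ in tree.tips()):
        raise ValueError("leaf labels are not unique")
    out = set()
    for node in tree.non_tips(include_self=True):
        s = frozenset(t.name for t in node.tips())
        if 1 < len(s) < len(all_leaves):
            out.add(s)
    return out


def rooted_rf(t1: TreeNode, t2: TreeNode) -> int:
    """Rooted Robinson-Foulds distance: |clusters(t1) XOR clusters(t2)|."""
    l1, l2 = leaf_names(t1), leaf_names(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first = {sorted(l1 - l2)}, "
            f"only in second = {sorted(l2 - l1)}"
        )
    return len(rooted_clusters(t1) ^ rooted_clusters(t2))


def _nrf_from_clusters(c1: set, c2: set) -> float:
    max_rf = len(c1) + len(c2)
    if max_rf == 0:
        return 0.0
    return len(c1 ^ c2) / max_rf


def normalized_rf(t1: TreeNode, t2: TreeNode) -> float:
    """Rooted RF normalised to [0, 1] by the trees' own cluster counts.

    0 means complete congruence, 1 complete incongruence (no shared clade).
    For fully binary trees on n leaves the divisor is 2(n - 2). Two star
    trees (no non-trivial clusters at all) score 0: nothing to conflict.
    """
    l1, l2 = leaf_names(t1), leaf_names(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first = {sorted(l1 - l2)}, "
            f"only in second = {sorted(l2 - l1)}"
        )
    return _nrf_from_clusters(rooted_clusters(t1), rooted_clusters(t2))


def random_pair_normalized_rf(
    t1: TreeNode, t2: TreeNode, n_random: int = 1000, seed=None
) -> float:
    """Alternative normalisation: rooted RF over the mean RF of random pairs.

    Divides by the average rooted RF between independent random topologies on
    the same leaves, as some tree-comparison tools do. Can exceed 1.
    """
    rng = _as_rng(seed)
    labels = sorted(leaf_names(t1))
    total = 0.0
    for _ in range(n_random):
        a = _random_cluster_set(labels, rng)
        b = _random_cluster_set(labels, rng)
        total += len(a ^ b)
    mean = total / n_random
    if mean == 0:
        return 0.0
    return rooted_rf(t1, t2) / mean


# ---------------------------------------------------------------------------
# Random topologies and the null
# ---------------------------------------------------------------------------

def _coalesce(labels, rng):
    """Random sequential coalescence; yields (merge pairs as index choices)."""
    items = list(labels)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append((a, b))
    return items[0]


def _random_cluster_set(labels, rng) -> set:
    """Cluster set of a random coalescent topology, without building a tree."""
    n = len(labels)
    sets = [frozenset([x]) for x in labels]
    clusters = set()
    while len(sets) > 1:
        i, j = sorted(rng.choice(len(sets), size=2, replace=False))
        b = sets.pop(j)
        a = sets.pop(i)
        u = a | b
        if 1 < len(u) < n:
            clusters.add(u)
        sets.append(u)
    return clusters


def _nested_to_tree(x) -> TreeNode:
    if isinstance(x, tuple):
        return TreeNode(children=[_nested_to_tree(x[0]), _nested_to_tree(x[1])])
    return TreeNode(name=x)


def random_topology(labels, seed) -> TreeNode:
    """Uniform-coalescent random rooted binary topology over `labels`.

    Each step merges a uniformly chosen pair of the remaining lineages;
    deterministic given the seed. No branch lengths are assigned.
    """
    labels = sorted(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    rng = _as_rng(seed)
    return _nested_to_tree(_coalesce(labels, rng))


def shuffled_labels_topology(tree: TreeNode, seed) -> TreeNode:
    """Copy of `tree` with its leaf labels randomly permuted."""
    rng = _as_rng(seed)
    new = tree.copy()
    tips = list(new.tips())
    names = [t.name for t in tips]
    perm = rng.permutation(len(names))
    for t, k in zip(tips, perm):
        t.name = names[k]
    return new


# ---------------------------------------------------------------------------
# Phylosymbiosis test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhylosymbiosisResult:
    """Observed normalised rooted-RF score against a randomised-topology null.

    ``p_value`` is the probability of a random topology being at least as
    congruent with the host tree as the observed dendrogram. With the add-one
    correction p = (1 + #{null <= observed}) / (1 + n_random), so p > 0
    always; ``p_value_plain`` is the uncorrected #{null <= observed}/n_random.
    """

    observed_nrf: float
    n_random: int
    null_scores: np.ndarray = field(repr=False)
    p_value: float = 0.0
    p_value_plain: float = 0.0


def phylosymbiosis_test(
    dendrogram: TreeNode,
    host_tree: TreeNode,
    n_random: int,
    seed,
    null: str = "coalescent",
) -> PhylosymbiosisResult:
    """Test topological congruence of a dendrogram with the host phylogeny.

    The observed statistic is the normalised rooted Robinson-Foulds score
    between the dendrogram and the host tree. The null distribution is the
    same score for `n_random` randomised topologies over the same leaves --
    either fresh uniform-coalescent topologies (``null='coalescent'``) or
    leaf-label shuffles of the observed dendrogram (``null='label_shuffle'``).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if null not in ("coalescent", "label_shuffle"):
        raise ValueError(f"unknown null kind {null!r}")
    l1, l2 = leaf_names(dendrogram), leaf_names(host_tree)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in dendrogram = {sorted(l1 - l2)}, "
            f"only in host tree = {sorted(l2 - l1)}"
        )
    rng = _as_rng(seed)
    host_clusters = rooted_clusters(host_tree)
    dend_clusters = rooted_clusters(dendrogram)
    observed = _nrf_from_clusters(dend_clusters, host_clusters)
    labels = sorted(l1)
    null_scores = np.empty(n_random)
    for i in range(n_random):
        if null == "coalescent":
            c = _random_cluster_set(labels, rng)
        else:
            perm = rng.permutation(len(labels))
            mapping = {labels[k]: labels[perm[k]] for k in range(len(labels))}
            c = {frozenset(mapping[x] for x in s) for s in dend_clusters}
        null_scores[i] = _nrf_from_clusters(c, host_clusters)
    k = int(np.sum(null_scores <= observed + 1e-12))
    return PhylosymbiosisResult(
        observed_nrf=observed,
        n_random=n_random,
        null_scores=null_scores,
        p_value=(1 + k) / (1 + n_random),
        p_value_plain=k / n_random,
    )
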