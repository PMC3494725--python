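"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the code paths under test: patristic
distances by explicit root-path walking, MAST by exhaustive subset search
over restricted split sets, quality measures by a second scripted
evaluation, AUC by all-pairs Mann-Whitney counting.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from coevoppi import GeneTree, simulate_species_tree


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def random_topology(n_leaves: int, labels: list[str], seed: int) -> GeneTree:
    """Random binary tree with the given leaf labels (random lengths)."""
    rng = np.random.default_rng(seed)
    st = simulate_species_tree(max(n_leaves, 10), seed=int(rng.integers(2**31)))
    keep = sorted(st.leaf_labels())[:n_leaves]
    t = st.tree.extract_tree_with_taxa_labels(labels=set(keep))
    perm = rng.permutation(n_leaves)
    for i, lf in enumerate(t.leaf_node_iter()):
        lf.taxon.label = labels[perm[i]]
    for e in t.preorder_edge_iter():
        if e.head_node is not t.seed_node:
            e.length = float(rng.uniform(0.1, 2.0))
    return GeneTree(f"rand{seed}", t)


def patristic_path_walk(gtree: GeneTree) -> tuple[list[str], np.ndarray]:
    """Leaf-pair distances by climbing both root paths to the LCA."""
    parent = {}
    length = {}
    leaves = {}
    for nd in gtree.tree.preorder_node_iter():
        if nd.parent_node is not None:
            parent[id(nd)] = nd.parent_node
            length[id(nd)] = nd.edge.length or 0.0
        if nd.is_leaf():
            leaves[nd.taxon.label] = nd

    def root_path(nd):
        path = [nd]
        while id(nd) in parent:
            nd = parent[id(nd)]
            path.append(nd)
        return path

    labels = sorted(leaves)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pi = root_path(leaves[labels[i]])
        pj = root_path(leaves[labels[j]])
        anc_j = {id(x) for x in pj}
        dist = 0.0
        nd = leaves[labels[i]]
        while id(nd) not in anc_j:
            dist += length[id(nd)]
            nd = parent[id(nd)]
        lca = nd
        nd = leaves[labels[j]]
        while id(nd) != id(lca):
            dist += length[id(nd)]
            nd = parent[id(nd)]
        d[i, j] = d[j, i] = dist
    return labels, d


def _nontrivial_splits(gtree: GeneTree) -> list[frozenset]:
    """All splits (as leaf-label sets of one side) of the unrooted tree."""
    all_leaves = frozenset(gtree.leaf_labels())
    out = []
    for nd in gtree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        out.append(below)
    return out


def restricted_splits(full_splits, all_leaves, subset) -> frozenset:
    """Nontrivial splits of the tree restricted to `subset`."""
    s = frozenset(subset)
    out = set()
    for below in full_splits:
        x = below & s
        if 1 < len(x) < len(s) - 1:
            out.add(frozenset([x, s - x]))
    return frozenset(out)


def mast_exhaustive(tree_a: GeneTree, tree_b: GeneTree) -> int:
    """Largest common leaf subset on which the unrooted restricted
    topologies are identical (identical split sets)."""
    common = sorted(tree_a.leaf_set() & tree_b.leaf_set())
    sa = _nontrivial_splits(tree_a)
    sb = _nontrivial_splits(tree_b)
    la, lb = tree_a.leaf_set(), tree_b.leaf_set()
    for size in range(len(common), 3, -1):
        for sub in itertools.combinations(common, size):
            if restricted_splits(sa, la, sub) == restricted_splits(sb, lb, sub):
                return size
    return min(len(common), 3)


# ---------------------------------------------------------------------------
# quality measures: a second, independent scripted evaluation
# ---------------------------------------------------------------------------


def quality_oracle(a: int, b: int, c: int, d: int) -> dict[str, float | None]:
    N = a + b + c + d
    nA, nB = a + b, a + c
    pA, pB, pAB = nA / N, nB / N, a / N
    nan = None

    def safe(num, den):
        return num / den if den != 0 else nan

    out = {}
    out["confidence"] = safe(a, nA)
    out["recall"] = safe(a, nB)
    out["lift"] = safe(a * N, nA * nB)
    out["dice"] = safe(2 * a, nA + nB)
    m = nA * nB * (N - nA) * (N - nB)
    out["pearson"] = (a * d - b * c) / math.sqrt(m) if m > 0 else nan
    out["GI"] = (
        math.log(a * N / (nA * nB), 2) if a > 0 and nA > 0 and nB > 0 else nan
    )
    pe = (nA * nB + (N - nA) * (N - nB)) / N**2
    out["IQC"] = ((a + d) / N - pe) / (1 - pe) if pe != 1 else nan
    for tag, (x, y, nX, nY, pX, pY, pXY) in {
        "1": (a, b, nA, nB, pA, pB, pAB),
        "2": (a, c, nB, nA, pB, pA, pAB),
    }.items():
        conf = safe(x, nX)
        out[f"confidenceCentered{tag}"] = nan if conf is None else conf - pY
        out[f"leastContradiction{tag}"] = safe(x - y, nY)
        out[f"loevinger{tag}"] = (
            nan if conf is None or pY == 1 else (conf - pY) / (1 - pY)
        )
        out[f"tec{tag}"] = 1 - y / x if x > 0 else nan
        out[f"LAP{tag}"] = (x + 1) / (nX + 2)
        out[f"GAN{tag}"] = safe(x - y, nX)
        zden = max(pXY * (1 - pY), pY * (pX - pXY))
        out[f"Zhang{tag}"] = (pXY - pX * pY) / zden if zden > 0 else nan
        out[f"Pearl{tag}"] = nan if conf is None else pX * abs(conf - pY)
        out[f"jaccard{tag}"] = safe(a, nA + nB - a)
    return out


# ---------------------------------------------------------------------------
# AUC by brute-force Mann-Whitney counting
# ---------------------------------------------------------------------------


def auc_brute(scores, labels) -> float:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
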