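"""Tree-comparison features: mirror correlations and MAST-based congruence.

Seven features are computed per protein pair (A, B) given their gene trees
and a reference species tree (Tree of Life, ToL):

* ``mirror``      - Pearson correlation between the patristic distance
                    matrices of the two gene trees over their common species
                    (the classic mirrortree statistic).
* ``mirror_A/B``  - the same statistic between each gene tree and the ToL.
* ``tol_mirror``  - mirror computed after subtracting a rescaled ToL distance
                    matrix from each gene-tree matrix, removing the background
                    similarity that is due to shared speciation history alone.
* ``icong``       - congruence index: observed maximum-agreement-subtree
                    (MAST) size divided by its mean under a label-permutation
                    null; an associated chance p-value is also computed.
* ``icong_A/B``   - the same index between each gene tree and the ToL.

Trees are compared as unrooted; MAST ignores branch lengths.  Every
correlation-type feature requires at least 7 common species (the congruence
index is not designed below that size) and signals ``NotComputable``
otherwise, which the feature-table assembly converts into a missing mask.

MAST is exact: the unrooted MAST of two trees on a common leaf set equals
``max over common leaves x of 1 + rooted-MAST(T1 rooted at x minus x,
T2 rooted at x minus x)``, and the rooted MAST is computed by the standard
subtree dynamic programme.  Fully binary pairs go through a numba kernel;
multifurcating inputs take a general (matching-based) Python route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from numba import njit
from scipy.optimize import linear_sum_assignment

from .datamodel import (
    DistanceMatrix,
    GeneTree,
    NotComputable,
    TREE_FEATURE_NAMES,
    ValidationError,
)

logger = logging.getLogger("coevoppi")

__all__ = [
    "TolModel",
    "CongruenceResult",
    "patristic_matrix",
    "mirror",
    "tol_correct",
    "tol_mirror",
    "mast_size",
    "icong",
    "tree_feature_block",
    "MIN_COMMON_SPECIES",
]

#: Minimum common-species count below which tree features are undefined.
MIN_COMMON_SPECIES = 7

#: Default number of label permutations for the congruence null.
DEFAULT_PERMUTATIONS = 999


# ---------------------------------------------------------------------------
# Patristic distances and mirror correlations
# ---------------------------------------------------------------------------


def patristic_matrix(gtree: GeneTree) -> DistanceMatrix:
    """Pairwise leaf-to-leaf distance matrix: sum of branch lengths on the
    unique path between each pair of leaves.  Labels are sorted."""
    leaves = sorted(gtree.leaf_labels())
    if len(leaves) < 2:
        raise ValidationError(
            f"tree {gtree.protein_id!r} has {len(leaves)} leaf; need >= 2"
        )
    pdm = gtree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in gtree.tree.taxon_namespace}
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[leaves[i]], taxa[leaves[j]])
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(leaves), d)


def _common_labels(mat_a: DistanceMatrix, mat_b: DistanceMatrix) -> list[str]:
    return sorted(set(mat_a.labels) & set(mat_b.labels))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise NotComputable("zero variance in distance vector")
    return float(np.corrcoef(x, y)[0, 1])


def mirror(
    mat_a: DistanceMatrix,
    mat_b: DistanceMatrix,
    min_common: int = MIN_COMMON_SPECIES,
) -> float:
    """Mirrortree statistic: Pearson correlation over the strictly-upper
    triangles of the two matrices aligned on their common label set."""
    common = _common_labels(mat_a, mat_b)
    if len(common) < min_common:
        raise NotComputable(
            f"{len(common)} common species < required {min_common}"
        )
    return _pearson(mat_a.restrict(common).upper(), mat_b.restrict(common).upper())


@dataclass(frozen=True)
class TolModel:
    """Species-tree distance model used for background correction."""

    tol_matrix: DistanceMatrix
    scaling_rule: str = "mean-ratio"

    @classmethod
    def from_tree(cls, tol_tree: GeneTree) -> "TolModel":
        return cls(tol_matrix=patristic_matrix(tol_tree))


def tol_correct(
    mat: DistanceMatrix, tol: TolModel | DistanceMatrix
) -> DistanceMatrix:
    """Residual matrix d - s*t after rescaling the species-tree distances.

    s is the ratio of the mean upper-triangle entries of the protein matrix
    to that of the species matrix restricted to the same labels, i.e. a
    single clock-rescaling factor; residuals may be negative.
    """
    tol_mat = tol.tol_matrix if isinstance(tol, TolModel) else tol
    if mat.n < 2:
        raise ValidationError("matrix needs >= 2 labels for correction")
    t = tol_mat.restrict(mat.labels)
    mean_t = float(np.mean(t.upper()))
    if mean_t == 0.0:
        raise ValidationError("species-tree mean distance is zero")
    s = float(np.mean(mat.upper())) / mean_t
    return DistanceMatrix(mat.labels, mat.d - s * t.d, signed=True)


def tol_mirror(
    mat_a: DistanceMatrix,
    mat_b: DistanceMatrix,
    tol: TolModel | DistanceMatrix,
    min_common: int = MIN_COMMON_SPECIES,
) -> float:
    """Mirror correlation of the two speciation-corrected residual matrices.

    The correction is computed on the restriction to the common label set so
    each protein gets its own rescaling factor there.
    """
    common = _common_labels(mat_a, mat_b)
    if len(common) < min_common:
        raise NotComputable(
            f"{len(common)} common species < required {min_common}"
        )
    ra = tol_correct(mat_a.restrict(common), tol)
    rb = tol_correct(mat_b.restrict(common), tol)
    return _pearson(ra.upper(), rb.upper())


# ---------------------------------------------------------------------------
# MAST machinery
# ---------------------------------------------------------------------------


class _NotBinary(Exception):
    pass


def _unrooted_adjacency(tree: dendropy.Tree) -> tuple[list[list[int]], dict[int, str]]:
    """Adjacency list of the tree seen as an unrooted graph, with every
    degree-2 node (e.g. a rooted seed node) suppressed.  Returns (adj,
    leaf_label_by_node)."""
    nodes = list(tree.preorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    adj: list[set[int]] = [set() for _ in nodes]
    for nd in nodes:
        for ch in nd.child_nodes():
            adj[idx[id(nd)]].add(idx[id(ch)])
            adj[idx[id(ch)]].add(idx[id(nd)])
    # suppress degree-2 nodes
    for i in range(len(nodes)):
        if len(adj[i]) == 2:
            a, b = sorted(adj[i])
            adj[a].discard(i)
            adj[b].discard(i)
            adj[a].add(b)
            adj[b].add(a)
            adj[i] = set()
    leaf_label = {
        idx[id(nd)]: nd.taxon.label
        for nd in nodes
        if nd.is_leaf() and nd.taxon is not None
    }
    return [sorted(s) for s in adj], leaf_label


class _TreeEnc:
    """Per-tree MAST encodings: for every leaf (as root) the rooted, binary
    child arrays in postorder.  Leaf identity is a *slot* index so that leaf
    labels can be permuted cheaply without rebuilding the structure."""

    def __init__(self, tree: dendropy.Tree, label_to_id: dict[str, int]):
        adj, leaf_label = _unrooted_adjacency(tree)
        self.k = len(leaf_label)
        leaf_nodes = sorted(leaf_label)  # node indices of leaves, fixed order
        self.slot_of_node = {nd: s for s, nd in enumerate(leaf_nodes)}
        #: labels0[slot] = integer label currently carried by that leaf slot
        self.labels0 = np.array(
            [label_to_id[leaf_label[nd]] for nd in leaf_nodes], dtype=np.int64
        )
        self.binary = True
        self._encs: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for root_leaf in leaf_nodes:
            try:
                self._encs.append(self._encode(adj, root_leaf))
            except _NotBinary:
                self.binary = False
                self._encs = []
                break
        self._adj = adj
        self._leaf_nodes = leaf_nodes

    def _encode(self, adj, root_leaf):
        if self.k == 1:
            raise ValidationError("cannot root a single-leaf tree")
        start = adj[root_leaf][0]
        c1, c2, slot = [], [], []
        # iterative postorder from `start`, excluding root_leaf
        def children(u, parent):
            return [v for v in adj[u] if v != parent and v != root_leaf]

        order: list[int] = []
        stack = [(start, root_leaf, False)]
        pos: dict[tuple[int, int], int] = {}
        while stack:
            u, p, done = stack.pop()
            if done:
                ch = children(u, p)
                if ch:
                    if len(ch) != 2:
                        raise _NotBinary()
                    c1.append(pos[(ch[0], u)])
                    c2.append(pos[(ch[1], u)])
                    slot.append(-1)
                else:
                    c1.append(-1)
                    c2.append(-1)
                    slot.append(self.slot_of_node[u])
                pos[(u, p)] = len(order)
                order.append(u)
            else:
                stack.append((u, p, True))
                for v in children(u, p):
                    stack.append((v, u, False))
        return (
            np.array(c1, dtype=np.int64),
            np.array(c2, dtype=np.int64),
            np.array(slot, dtype=np.int64),
        )

    def packed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(c1, c2, slot, ncount) stacked over root slots, -1-padded."""
        m = max(len(e[0]) for e in self._encs)
        k = self.k
        c1 = np.full((k, m), -1, dtype=np.int64)
        c2 = np.full((k, m), -1, dtype=np.int64)
        sl = np.full((k, m), -1, dtype=np.int64)
        nc = np.zeros(k, dtype=np.int64)
        for r, (a, b, s) in enumerate(self._encs):
            nc[r] = len(a)
            c1[r, : len(a)] = a
            c2[r, : len(b)] = b
            sl[r, : len(s)] = s
        return c1, c2, sl, nc

    # ---- general (multifurcation-capable) rooted structures ----
    def rooted_children(self, root_slot: int):
        """(children lists in postorder, labels array with -1 internal) for
        the tree rooted at the given leaf slot, that leaf removed."""
        adj = self._adj
        root_leaf = self._leaf_nodes[root_slot]
        start = adj[root_leaf][0]
        children_of: list[list[int]] = []
        slots: list[int] = []
        pos: dict[tuple[int, int], int] = {}
        order = 0
        stack = [(start, root_leaf, False)]
        while stack:
            u, p, done = stack.pop()
            ch = [v for v in adj[u] if v != p and v != root_leaf]
            if done:
                children_of.append([pos[(v, u)] for v in ch])
                slots.append(self.slot_of_node[u] if not ch else -1)
                pos[(u, p)] = order
                order += 1
            else:
                stack.append((u, p, True))
                for v in ch:
                    stack.append((v, u, False))
        return children_of, np.array(slots, dtype=np.int64)


@njit(cache=False)
def _umast_binary(c1a, c2a, sla, nca, c1b, c2b, slb, ncb,
                  lab_a, lab_b, inv_a, inv_b, k):  # pragma: no cover - numba
    """Exact unrooted MAST over packed rooted encodings of two binary trees
    on the same k labels.  lab_*: slot -> label; inv_*: label -> slot."""
    best = 1
    for x in range(k):
        ra = inv_a[x]
        rb = inv_b[x]
        m1 = nca[ra]
        m2 = ncb[rb]
        M = np.zeros((m1, m2), dtype=np.int64)
        for u in range(m1):
            ua = c1a[ra, u]
            ub = c2a[ra, u]
            lu = -1 if sla[ra, u] < 0 else lab_a[sla[ra, u]]
            for v in range(m2):
                va = c1b[rb, v]
                vb = c2b[rb, v]
                if ua < 0 and va < 0:
                    lv = lab_b[slb[rb, v]]
                    M[u, v] = 1 if lu == lv else 0
                elif ua < 0:
                    x1 = M[u, va]
                    x2 = M[u, vb]
                    M[u, v] = x1 if x1 > x2 else x2
                elif va < 0:
                    x1 = M[ua, v]
                    x2 = M[ub, v]
                    M[u, v] = x1 if x1 > x2 else x2
                else:
                    m_ = M[ua, va] + M[ub, vb]
                    t = M[ua, vb] + M[ub, va]
                    if t > m_:
                        m_ = t
                    for w in (M[u, va], M[u, vb], M[ua, v], M[ub, v]):
                        if w > m_:
                            m_ = w
                    M[u, v] = m_
        val = 1 + M[m1 - 1, m2 - 1]
        if val > best:
            best = val
        if best == k:
            break
    return best


def _rmast_general(ch_a, lab_node_a, ch_b, lab_node_b) -> int:
    """Rooted MAST for possibly multifurcating trees (postorder children
    lists; per-node labels, -1 internal).  Matching step uses the Hungarian
    algorithm."""
    m1, m2 = len(ch_a), len(ch_b)
    M = np.zeros((m1, m2), dtype=np.int64)
    for u in range(m1):
        cu = ch_a[u]
        for v in range(m2):
            cv = ch_b[v]
            if not cu and not cv:
                M[u, v] = 1 if lab_node_a[u] == lab_node_b[v] else 0
            elif not cu:
                M[u, v] = max(M[u, w] for w in cv)
            elif not cv:
                M[u, v] = max(M[w, v] for w in cu)
            else:
                best = max(max(M[u, w] for w in cv), max(M[w, v] for w in cu))
                cost = M[np.ix_(cu, cv)]
                ri, ci = linear_sum_assignment(cost, maximize=True)
                best = max(best, int(cost[ri, ci].sum()))
                M[u, v] = best
    return int(M[m1 - 1, m2 - 1])


def _umast_general(enc_a: _TreeEnc, enc_b: _TreeEnc,
                   lab_a: np.ndarray, lab_b: np.ndarray) -> int:
    k = enc_a.k
    inv_a = np.empty(k, dtype=np.int64)
    inv_a[lab_a] = np.arange(k)
    inv_b = np.empty(k, dtype=np.int64)
    inv_b[lab_b] = np.arange(k)
    best = 1
    for x in range(k):
        ch_a, slots_a = enc_a.rooted_children(int(inv_a[x]))
        ch_b, slots_b = enc_b.rooted_children(int(inv_b[x]))
        la = np.where(slots_a >= 0, lab_a[slots_a], -1)
        lb = np.where(slots_b >= 0, lab_b[slots_b], -2)
        val = 1 + _rmast_general(ch_a, la, ch_b, lb)
        best = max(best, val)
        if best == k:
            break
    return best


class _MastPair:
    """Both trees restricted to their common leaves, ready for repeated MAST
    evaluation under leaf-label permutations of tree B."""

    def __init__(self, tree_a: GeneTree, tree_b: GeneTree):
        common = sorted(tree_a.leaf_set() & tree_b.leaf_set())
        self.n_common = len(common)
        if self.n_common < 3:
            self.enc_a = self.enc_b = None
            return
        self.label_to_id = {l: i for i, l in enumerate(common)}
        ra = tree_a.tree.extract_tree_with_taxa_labels(labels=set(common))
        rb = tree_b.tree.extract_tree_with_taxa_labels(labels=set(common))
        self.enc_a = _TreeEnc(ra, self.label_to_id)
        self.enc_b = _TreeEnc(rb, self.label_to_id)
        self.binary = self.enc_a.binary and self.enc_b.binary
        if self.binary:
            self._packed_a = self.enc_a.packed()
            self._packed_b = self.enc_b.packed()

    def mast(self, lab_b: np.ndarray | None = None) -> int:
        """MAST size; lab_b optionally replaces tree B's slot->label map."""
        if self.n_common < 3:
            return self.n_common
        k = self.n_common
        lab_a = self.enc_a.labels0
        if lab_b is None:
            lab_b = self.enc_b.labels0
        if self.binary:
            inv_a = np.empty(k, dtype=np.int64)
            inv_a[lab_a] = np.arange(k)
            inv_b = np.empty(k, dtype=np.int64)
            inv_b[lab_b] = np.arange(k)
            c1a, c2a, sla, nca = self._packed_a
            c1b, c2b, slb, ncb = self._packed_b
            return int(
                _umast_binary(c1a, c2a, sla, nca, c1b, c2b, slb, ncb,
                              lab_a, lab_b, inv_a, inv_b, k)
            )
        return _umast_general(self.enc_a, self.enc_b, lab_a, lab_b)


def mast_size(
    tree_a: GeneTree,
    tree_b: GeneTree,
    min_common: int = MIN_COMMON_SPECIES,
) -> int:
    """Size of the maximum agreement subtree of the two trees, compared as
    unrooted topologies (branch lengths ignored)."""
    pair = _MastPair(tree_a, tree_b)
    if pair.n_common < min_common:
        raise NotComputable(
            f"{pair.n_common} common leaves < required {min_common}"
        )
    return pair.mast()


@dataclass(frozen=True)
class CongruenceResult:
    """Observed MAST with its permutation-null summary."""

    mast_size: int
    icong: float
    p_value: float
    n_common: int
    n_permutations: int

    def __post_init__(self) -> None:
        if self.mast_size > self.n_common:
            raise ValidationError("MAST cannot exceed common leaf count")
        if self.icong <= 0:
            raise ValidationError("congruence index must be positive")


def icong(
    tree_a: GeneTree,
    tree_b: GeneTree,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
    min_common: int = MIN_COMMON_SPECIES,
    return_null: bool = False,
):
    """Congruence index of two trees.

    The null distribution is built by shuffling the leaf labels of tree B
    (both topologies fixed) and recomputing MAST; the index is the observed
    MAST divided by the null mean, and the chance probability uses the
    add-one permutation estimator.  With ``return_null=True`` the sampled
    null MAST sizes are returned alongside the result (useful for
    calibration checks).
    """
    if n_permutations < 100:
        raise ValidationError("need >= 100 permutations for a stable null")
    pair = _MastPair(tree_a, tree_b)
    if pair.n_common < min_common:
        raise NotComputable(
            f"{pair.n_common} common leaves < required {min_common}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    observed = pair.mast()
    lab_b0 = pair.enc_b.labels0
    null = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        null[i] = pair.mast(lab_b0[rng.permutation(pair.n_common)])
    p_value = (1 + int(np.sum(null >= observed))) / (n_permutations + 1)
    result = CongruenceResult(
        mast_size=observed,
        icong=observed / float(null.mean()),
        p_value=p_value,
        n_common=pair.n_common,
        n_permutations=n_permutations,
    )
    return (result, null) if return_null else result


# ---------------------------------------------------------------------------
# Feature block
# ---------------------------------------------------------------------------


def tree_feature_block(
    tree_a: GeneTree,
    tree_b: GeneTree,
    tol_tree: GeneTree,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
    tol_model: TolModel | None = None,
) -> dict[str, float | None]:
    """The 7 tree features for one pair; slots that cannot be computed are
    returned as ``None`` (missing-masked), the others are still computed.

    The congruence feature slots carry the index value; the associated
    p-values are logged at DEBUG level.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if tol_model is None:
        tol_model = TolModel.from_tree(tol_tree)
    out: dict[str, float | None] = {name: None for name in TREE_FEATURE_NAMES}

    mats: dict[str, DistanceMatrix] = {}
    for key, gt in (("A", tree_a), ("B", tree_b)):
        try:
            mats[key] = patristic_matrix(gt)
        except (ValidationError, NotComputable) as e:
            logger.debug("patristic matrix %s failed: %s", key, e)

    def attempt(name, fn):
        try:
            out[name] = fn()
        except NotComputable as e:
            logger.debug("feature %s not computable: %s", name, e)

    if "A" in mats and "B" in mats:
        attempt("mirror", lambda: mirror(mats["A"], mats["B"]))
        attempt("tol_mirror", lambda: tol_mirror(mats["A"], mats["B"], tol_model))
    if "A" in mats:
        attempt("mirror_A", lambda: mirror(mats["A"], tol_model.tol_matrix))
    if "B" in mats:
        attempt("mirror_B", lambda: mirror(mats["B"], tol_model.tol_matrix))

    for name, t1, t2 in (
        ("icong", tree_a, tree_b),
        ("icong_A", tree_a, tol_tree),
        ("icong_B", tree_b, tol_tree),
    ):
        try:
            res = icong(t1, t2, n_permutations=n_permutations, seed=rng)
        except NotComputable as e:
            logger.debug("feature %s not computable: %s", name, e)
            continue
        logger.debug(
            "%s: mast=%d/%d index=%.4f p=%.4g",
            name, res.mast_size, res.n_common, res.icong, res.p_value,
        )
        out[name] = res.icong
    return out
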