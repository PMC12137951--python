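"""Genotype p-distances, neighbour joining, SNP bootstrap, outgroup rooting.

The pairwise distance between two diploid genotypes is allele-multiset
mismatch: per jointly-called site, distance = 1 - (shared alleles)/2, which
for biallelic sites reduces to |dosage_i - dosage_j| / 2; the pair distance
is the mean over joint sites.  Neighbour joining uses the Studier-Keppler
Q-criterion with deterministic lowest-index tie-breaking; negative branch
lengths are clamped to zero with the deficit moved to the sibling edge
(raw lengths available).  Bootstrap resamples SNP columns with replacement
and reports, per internal edge of the original tree, the percentage of
replicate trees containing the same leaf bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .io_formats import VariantDataset


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair joint-site counts."""

    labels: list[str]
    matrix: np.ndarray
    joint_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{v:.6f}" for v in self.matrix[i])
                fh.write(f"{lab}  {row}\n")


def _pair_arrays(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Per-site |dosage diff| (NaN->0) and validity mask for every pair."""
    n = dosage.shape[1]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    diffs = np.empty((dosage.shape[0], len(pairs)))
    valid = np.empty((dosage.shape[0], len(pairs)))
    for k, (i, j) in enumerate(pairs):
        d = np.abs(dosage[:, i] - dosage[:, j])
        v = ~np.isnan(d)
        diffs[:, k] = np.where(v, d, 0.0)
        valid[:, k] = v
    return diffs, valid, pairs


def p_distance(
    dataset: VariantDataset, samples: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise genotype p-distance over biallelic SNP sites.

    Pairs with zero jointly-called sites get NaN (tree construction will
    refuse them).
    """
    sub = dataset if samples is None else dataset.take_samples(list(samples))
    snp = sub.is_biallelic & ~sub.is_indel
    sub = sub.take_sites(snp)
    dosage = sub.dosage()
    diffs, valid, pairs = _pair_arrays(dosage)
    sums = diffs.sum(axis=0)
    counts = valid.sum(axis=0)
    n = sub.n_samples
    mat = np.zeros((n, n))
    joint = np.zeros((n, n), dtype=int)
    for k, (i, j) in enumerate(pairs):
        d = sums[k] / counts[k] / 2.0 if counts[k] > 0 else np.nan
        mat[i, j] = mat[j, i] = d
        joint[i, j] = joint[j, i] = int(counts[k])
    return DistanceMatrix(list(sub.samples), mat, joint)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou-Nei neighbour joining with the Studier-Keppler Q-criterion.

    Ties in Q are broken toward the lowest (i, j) index pair, so the result
    is deterministic.  Returns an unrooted tree (trifurcating root).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    if not np.isfinite(dm.matrix).all():
        raise ValueError("distance matrix contains undefined entries")

    D = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    active = list(range(n))

    def set_length(node: TreeNode, length: float) -> None:
        node.length = float(length)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic arg-min: smallest flat index wins ties
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if clamp_negative:
            if li < 0.0:
                lj += li
                li = 0.0
            if lj < 0.0:
                li += lj
                lj = 0.0
            li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        set_length(child_i, li)
        set_length(child_j, lj)
        parent = TreeNode(children=[child_i, child_j])

        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0])
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.vstack([D, new_row[None, :]])
        new_col = np.append(new_row, 0.0)
        D = np.hstack([D, new_col[:, None]])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # join the last three around the root
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    if clamp_negative:
        li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    for idx, ln in zip((i, j, k), (li, lj, lk)):
        set_length(nodes[idx], ln)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return root


# ---------------------------------------------------------------------------
# Bipartitions, bootstrap, rooting
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each canonicalised to the side that
    excludes the alphabetically first taxon."""
    anchor = min(taxa)
    bps: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if len(side) < 2 or len(taxa) - len(side) < 2:
            continue
        if anchor in side:
            side = taxa - side
        bps.add(side)
    return bps


def bootstrap_support(
    dataset: VariantDataset,
    samples: Sequence[str] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    clamp_negative: bool = True,
    max_retries: int = 100,
) -> TreeNode:
    """NJ tree with SNP-column bootstrap supports on internal edges.

    Columns (sites) are resampled with replacement to the original count;
    each internal edge of the tree from the full data gets the percentage of
    replicates whose tree contains the same leaf bipartition.  A replicate
    leaving some pair with no jointly-called site is redrawn (capped).
    Supports are stored as ``node.support`` and as internal node names.
    """
    sub = dataset if samples is None else dataset.take_samples(list(samples))
    if sub.n_samples < 4:
        raise ValueError("bootstrap needs >= 4 taxa")
    snp = sub.is_biallelic & ~sub.is_indel
    sub = sub.take_sites(snp)
    dm = p_distance(sub)
    tree = neighbor_joining(dm, clamp_negative=clamp_negative)
    taxa = frozenset(dm.labels)

    dosage = sub.dosage()
    diffs, valid, pairs = _pair_arrays(dosage)
    n_sites = dosage.shape[0]
    n = sub.n_samples
    rng = np.random.default_rng(seed)

    counts: dict[frozenset[str], int] = {bp: 0 for bp in _bipartitions(tree, taxa)}
    for _ in range(n_reps):
        for _attempt in range(max_retries):
            idx = rng.integers(0, n_sites, size=n_sites)
            w = np.bincount(idx, minlength=n_sites).astype(float)
            denom = w @ valid
            if (denom > 0).all():
                break
        else:
            raise RuntimeError("could not draw a replicate with all pairs defined")
        dist = (w @ diffs) / denom / 2.0
        mat = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            mat[i, j] = mat[j, i] = dist[k]
        rep_tree = neighbor_joining(
            DistanceMatrix(dm.labels, mat, dm.joint_sites), clamp_negative=clamp_negative
        )
        rep_bps = _bipartitions(rep_tree, taxa)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if min(taxa) in side:
            side = taxa - side
        if side in counts:
            support = 100.0 * counts[side] / n_reps
            node.support = support
            node.name = str(int(round(support)))
    return tree


def root_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root on the edge subtending the outgroup leaf, splitting it equally.

    Operates on a copy; internal-node labels (supports) move with their
    subtrees.  Idempotent on an already outgroup-rooted tree.
    """
    work = tree.copy()
    try:
        leaf = next(t for t in work.tips() if t.name == outgroup)
    except StopIteration:
        raise KeyError(f"outgroup {outgroup!r} not in tree") from None

    parent = leaf.parent
    if (
        parent is work
        and len(work.children) == 2
        and leaf in work.children
    ):
        return work  # already rooted on the outgroup edge

    half = (leaf.length or 0.0) / 2.0
    # detach the outgroup, reroot the remainder at its former parent, then
    # join both under a new root
    parent.remove(leaf)
    work = _suppress_unifurcations(work, keep=parent)
    rest = _reroot_at(work, parent)
    leaf.length = half
    rest.length = half
    return TreeNode(children=[leaf, rest])


def _suppress_unifurcations(tree: TreeNode, keep: TreeNode) -> TreeNode:
    """Remove internal nodes left with a single child, merging branch lengths;
    ``keep`` survives even if unary (it becomes the rerooting point)."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.traverse(include_self=False)):
            if node.children and len(node.children) == 1 and node is not keep:
                child = node.children[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                grand = node.parent
                grand.remove(node)
                node.remove(child)
                grand.append(child)
                changed = True
    if len(tree.children) == 1 and tree is not keep:
        child = tree.children[0]
        tree.remove(child)
        child.length = (child.length or 0.0) + (tree.length or 0.0)
        return child
    return tree


def _reroot_at(tree: TreeNode, node: TreeNode) -> TreeNode:
    """Re-hang the tree so ``node`` becomes the root (branch lengths kept)."""
    if node is tree:
        return tree
    path = [node]
    cur = node
    while cur.parent is not None:
        cur = cur.parent
        path.append(cur)
    # reverse parent-child relationships along the path root -> node
    for child, parent in zip(path[:-1], path[1:]):
        parent.remove(child)
    for child, parent in zip(path[:-1], path[1:]):
        child.append(parent)
        parent.length = child.length
    node.length = None
    node.parent = None
    return _cleanup_unary(node)


def _cleanup_unary(tree: TreeNode) -> TreeNode:
    for node in list(tree.traverse(include_self=False)):
        if node.children and len(node.children) == 1:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            grand = node.parent
            grand.remove(node)
            node.remove(child)
            grand.append(child)
    return tree
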