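"""BioNJ distance-tree construction, column-resampling bootstrap and
newick output.

BioNJ is the neighbor-joining variant that tracks an estimate of the
variance of each pairwise distance and uses it to weight the matrix
reduction when two nodes are agglomerated; pair selection and branch
lengths follow the classical NJ formulas.  On additive matrices the
reduction is exact for any weighting, so the generating tree (and all its
path lengths) is recovered exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distances import DistanceMatrix, SaturationError, build_matrix
from .seqio import SequenceRecord, SequenceSet

logger = logging.getLogger(__name__)

_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.\-|]+$")


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; ``length`` is the edge to the parent."""

    label: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary trifurcating root."""

    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.root.leaves()]  # type: ignore[misc]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each encoded canonically as the side
        not containing the lexicographically smallest leaf label."""
        all_leaves = frozenset(self.leaf_labels)
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])  # type: ignore[list-item]
            side = frozenset().union(*(walk(ch) for ch in node.children))
            if node is not self.root and 1 < len(side) < len(all_leaves) - 1:
                canon = side if anchor not in side else all_leaves - side
                out.add(canon)
            return side

        walk(self.root)
        return out

    def distance(self, a: str, b: str) -> float:
        """Sum of branch lengths along the path between two leaves."""

        def path_to(node: TreeNode, target: str) -> list[TreeNode] | None:
            if node.is_leaf:
                return [node] if node.label == target else None
            for ch in node.children:
                sub = path_to(ch, target)
                if sub is not None:
                    return [node] + sub
            return None

        pa, pb = path_to(self.root, a), path_to(self.root, b)
        if pa is None or pb is None:
            raise KeyError(f"leaf not found: {a if pa is None else b}")
        k = 0
        while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
            k += 1
        return sum(n.length for n in pa[k:]) + sum(n.length for n in pb[k:])

    def newick(self) -> str:
        return _to_newick(self.root) + ";"


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _to_newick(node: TreeNode) -> str:
    if node.is_leaf:
        return f"{_quote(node.label or '')}:{node.length:.10g}"
    inner = ",".join(_to_newick(ch) for ch in node.children)
    sup = "" if node.support is None else f"{node.support:.10g}"
    length = f":{node.length:.10g}" if node.length != 0.0 else ""
    return f"({inner}){sup}{length}"


def write_newick(
    tree: PhyloTree, path: str | Path, outgroup: str | None = None
) -> Path:
    """Write the tree as newick; optionally root on an outgroup leaf by
    splitting its pendant edge with a new bifurcating root."""
    path = Path(path)
    t = reroot(tree, outgroup) if outgroup is not None else tree
    path.write_text(t.newick() + "\n")
    return path


def reroot(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Return a copy rooted on the pendant edge of ``outgroup``."""
    import copy

    root = copy.deepcopy(tree.root)
    # Re-hang the tree so the outgroup leaf's parent chain flips.
    parent_of: dict[int, TreeNode] = {}

    def index(node: TreeNode) -> None:
        for ch in node.children:
            parent_of[id(ch)] = node
            index(ch)

    index(root)
    target = next((lf for lf in root.leaves() if lf.label == outgroup), None)
    if target is None:
        raise KeyError(f"outgroup {outgroup!r} is not a leaf label")
    # Flip edges from the outgroup's parent up to the old root.
    chain: list[TreeNode] = []
    node = parent_of[id(target)]
    while node is not None:
        chain.append(node)
        node = parent_of.get(id(node))
    orig_length = {id(nd): nd.length for nd in chain}
    orig_support = {id(nd): nd.support for nd in chain}
    for child, par in zip(chain, chain[1:]):
        par.children.remove(child)
        child.children.append(par)
        par.length = orig_length[id(child)]
        par.support = orig_support[id(child)]
    pivot = chain[0]
    pivot.children.remove(target)
    half = target.length / 2.0
    new_root = TreeNode(children=[target, pivot])
    target.length = half
    pivot.length = half
    pivot.support = None
    return PhyloTree(root=new_root)


def bionj(m: DistanceMatrix) -> PhyloTree:
    """Build an unrooted BioNJ tree from a symmetric distance matrix.

    Ties in the selection criterion break toward the lexicographically
    smallest pair of subtree representative labels, making output
    deterministic.  Negative branch lengths are kept as computed (logged),
    preserving exact path-length fit on additive inputs.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("BioNJ requires at least 3 taxa")
    D = np.array(m.distances, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    V = D.copy()  # initial variance estimates proportional to distances
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in m.labels]
    reps: list[str] = list(m.labels)  # representative (min leaf) per subtree
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        S = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best: tuple[float, str, str] | None = None
        best_pair: tuple[int, int] | None = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * D[i, j] - S[i] - S[j]
                lo, hi = sorted((reps[i], reps[j]))
                key = (q, lo, hi)
                if best is None or key < best:
                    best, best_pair = key, (i, j)
        i, j = best_pair  # type: ignore[misc]
        bi = 0.5 * D[i, j] + (S[i] - S[j]) / (2.0 * (r - 2))
        bj = D[i, j] - bi
        if bi < 0 or bj < 0:
            logger.info(
                "negative branch length at join (%s, %s): %.4g / %.4g",
                reps[i], reps[j], bi, bj,
            )
        # variance-weighted reduction
        if V[i, j] > 0 and r > 3:
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in active if k not in (i, j)) / (
                2.0 * (r - 2) * V[i, j]
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        u = len(nodes)
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = bi, bj
        nodes.append(TreeNode(children=[ni, nj]))
        reps.append(min(reps[i], reps[j]))
        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = lam * (D[i, k] - bi) + (1.0 - lam) * (D[j, k] - bj)
            V[u, k] = V[k, u] = lam * V[i, k] + (1.0 - lam) * V[j, k] - lam * (1.0 - lam) * V[i, j]
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = length
    order = sorted((a, b, c), key=lambda k: reps[k])
    root = TreeNode(children=[nodes[k] for k in order])
    return PhyloTree(root=root)


@dataclass
class BootstrapResult:
    """Full-data tree annotated with bipartition supports (percent)."""

    tree: PhyloTree
    n_replicates: int
    n_skipped: int  # replicates dropped for saturated distances


def bootstrap(
    seqs: SequenceSet,
    metric: str = "k2p",
    n_reps: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """Column-resampling bootstrap: each replicate resamples alignment
    columns with replacement, rebuilds the matrix and the BioNJ tree;
    support of each internal edge of the full-data tree is the percent of
    replicate trees containing the same bipartition."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seqs.require_aligned()
    L = seqs.alignment_length
    full = bionj(build_matrix(seqs, metric=metric))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in full.bipartitions()}
    rng = np.random.default_rng(seed)
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = SequenceSet(
            [
                SequenceRecord(
                    id=r.id,
                    residues="".join(r.residues[c] for c in cols),
                    species=r.species,
                )
                for r in seqs
            ]
        )
        try:
            rep = bionj(build_matrix(resampled, metric=metric))
        except SaturationError:
            skipped += 1
            continue
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    valid = n_reps - skipped
    if skipped:
        logger.warning("bootstrap: %d of %d replicates skipped (saturation)", skipped, n_reps)
    if valid > 0:
        all_leaves = frozenset(full.leaf_labels)
        anchor = min(all_leaves)

        def annotate(node: TreeNode, tree_root: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])  # type: ignore[list-item]
            side = frozenset().union(*(annotate(ch, tree_root) for ch in node.children))
            if node is not tree_root and 1 < len(side) < len(all_leaves) - 1:
                canon = side if anchor not in side else all_leaves - side
                node.support = 100.0 * counts[canon] / valid
            return side

        annotate(full.root, full.root)
    return BootstrapResult(tree=full, n_replicates=n_reps, n_skipped=skipped)
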