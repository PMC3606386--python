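"""Distance-based phylogenetic placement of a putative transferred gene.

A Poisson-corrected protein distance feeds Saitou-Nei neighbor joining;
bipartition bootstrap over alignment columns attaches supports; the origin
call asks whether the focal sequence nests, with support, inside the
bacterial or the eukaryotic part of the tree.  This deliberately trades the
heavier Bayesian machinery for the one decision-relevant output - clade
nesting - in a fast, exactly reproducible form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


def _norm_alignment(alignment) -> list[tuple[str, str]]:
    out = []
    for rec in alignment:
        if isinstance(rec, tuple):
            out.append(rec)
        else:
            out.append((rec.id, rec.seq))
    lengths = {len(s) for _, s in out}
    if len(lengths) > 1:
        raise ValueError("aligned sequences must have equal lengths")
    return out


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (self.d < 0).any() or not np.isfinite(self.d).all():
            raise ValueError("distances must be finite and non-negative")


@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # list of (TreeNode, branch_length)

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset([self.name])
        out = frozenset()
        for child, _ in self.children:
            out |= child.leaves()
        return out


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root node) with optional bipartition supports."""

    root: TreeNode
    supports: dict = field(default_factory=dict)  # canonical bipartition -> [0,1]

    @property
    def labels(self) -> frozenset:
        return self.root.leaves()

    def _canonical(self, side: frozenset) -> frozenset:
        ref = min(self.labels)
        return self.labels - side if ref in side else side

    def bipartitions(self) -> set:
        """Canonical non-trivial bipartitions (the side without the reference
        leaf), one per internal edge."""
        all_leaves = self.labels
        out = set()

        def walk(node):
            for child, _ in node.children:
                side = child.leaves()
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(self._canonical(side))
                walk(child)

        walk(self.root)
        return out

    def newick(self) -> str:
        def fmt(node, blen):
            if not node.children:
                return f"{node.name}:{blen:.6f}"
            inner = ",".join(fmt(c, b) for c, b in node.children)
            side = node.leaves()
            key = self._canonical(side)
            label = ""
            if key in self.supports:
                label = f"{self.supports[key]:.2f}"
            return f"({inner}){label}:{blen:.6f}"

        inner = ",".join(fmt(c, b) for c, b in self.root.children)
        return f"({inner});"


def protein_distance(alignment) -> DistanceMatrix:
    """Poisson-corrected distance d = -ln(1 - p), p the mismatch fraction
    over shared non-gap columns (pairwise deletion)."""
    aln = _norm_alignment(alignment)
    if len(aln) < 3:
        raise ValueError("need at least 3 sequences")
    labels = [lab for lab, _ in aln]
    arrs = [np.frombuffer(seq.encode(), dtype=np.uint8) for _, seq in aln]
    gap = ord("-")
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (arrs[i] != gap) & (arrs[j] != gap)
            total = int(shared.sum())
            if total == 0:
                raise ValueError(f"no shared columns between {labels[i]} and {labels[j]}")
            p = float((arrs[i][shared] != arrs[j][shared]).sum()) / total
            if p >= 1.0:
                raise ValueError(f"saturated pair {labels[i]}/{labels[j]} (p = 1)")
            d[i, j] = d[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(labels=labels, d=d)


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; ties on the Q criterion are broken by the
    lexicographically smallest pair of cluster representative labels; negative
    branch lengths are clamped to zero with the deficit moved to the sister."""
    labels = list(matrix.labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    nodes = [TreeNode(name=lab) for lab in labels]
    reps = list(labels)  # representative (min leaf) label per active cluster
    D = matrix.d.astype(float).copy()
    active = list(range(len(labels)))

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * D[i, j] - R[i] - R[j]
                key = tuple(sorted((reps[i], reps[j])))
                if best is None or (q, key) < best[:2]:
                    best = (q, key, i, j)
        _, _, i, j = best
        vi = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        vj = D[i, j] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        new = TreeNode(children=[(nodes[i], vi), (nodes[j], vj)])
        # distances from the new cluster
        newD = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            newD[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newD
        D[:-1, -1] = newD
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode(children=[(nodes[a], max(va, 0.0)),
                              (nodes[b], max(vb, 0.0)),
                              (nodes[c], max(vc, 0.0))])
    return PhyloTree(root=root)


def bootstrap_supports(alignment, n_reps: int, seed: int) -> PhyloTree:
    """NJ tree from the full alignment with bipartition supports from
    ``n_reps`` column resamples (fraction of replicate trees containing
    each full-tree bipartition)."""
    aln = _norm_alignment(alignment)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(protein_distance(aln))
    target = tree.bipartitions()
    tally = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    length = len(aln[0][1])
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [(lab, "".join(seq[c] for c in cols)) for lab, seq in aln]
        rep_bps = nj_tree(protein_distance(resampled)).bipartitions()
        for bp in target:
            if bp in rep_bps:
                tally[bp] += 1
    tree.supports = {bp: tally[bp] / n_reps for bp in target}
    return tree


def classify_origin(tree: PhyloTree, focal: str, kingdom_labels: dict,
                    support_threshold: float = 0.8):
    """Classify the focal leaf as bacterial_nested / eukaryotic_nested /
    ambiguous from the smallest well-supported bipartition grouping it with
    other leaves.  Returns (call, supporting side frozenset or None)."""
    all_leaves = tree.labels
    if focal not in all_leaves:
        raise ValueError(f"focal label {focal!r} not in tree")
    candidates = []
    for bp, support in tree.supports.items():
        if support < support_threshold:
            continue
        side = bp if focal in bp else all_leaves - bp
        others = side - {focal}
        if others:
            candidates.append((len(side), sorted(side), side, others))
    if not candidates:
        return "ambiguous", None
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, side, others = candidates[0]
    kinds = {kingdom_labels[lab] for lab in others}
    if kinds == {"bacterial"}:
        return "bacterial_nested", side
    if kinds == {"eukaryotic"}:
        return "eukaryotic_nested", side
    return "ambiguous", side
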