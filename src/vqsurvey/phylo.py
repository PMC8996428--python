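"""Distance-based protein phylogenetics: p-distance, neighbor joining,
bootstrap support and reference-guided subgroup assignment.

The tree builder is the classic Saitou-Nei neighbor-joining algorithm on a
pairwise-deletion p-distance matrix (a Poisson correction is available as a
flag). Negative branch-length estimates are clamped to zero and counted.
Bootstrap support resamples alignment columns with replacement, rebuilds the
tree, and reports the percentage of replicates containing each internal
bipartition of the original tree.

Multiple sequence alignment itself is out of scope: the functions accept an
aligned FASTA from any aligner. A minimal center-star aligner is included for
building small test fixtures only; it is no substitute for a real aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "DistanceMatrix",
    "PhyloNode",
    "PhyloTree",
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "assign_subgroups",
    "center_star_align",
]


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")


def p_distance(
    aligned: Mapping[str, str],
    correction: str | None = None,
    on_empty: str = "error",
) -> DistanceMatrix:
    """Pairwise-deletion p-distance over an aligned set of sequences.

    d(i,j) = mismatches / compared columns, skipping columns with a gap in
    either row. ``correction="poisson"`` applies d = -ln(1 - p). A pair with
    zero comparable columns raises, or yields 0 with ``on_empty="zero"``.
    """
    taxa = list(aligned)
    seqs = [aligned[t].upper() for t in taxa]
    length = {len(s) for s in seqs}
    if len(length) > 1:
        raise ValueError("aligned rows differ in length")
    arr = np.frombuffer(
        "".join(seqs).encode(), dtype="S1"
    ).reshape(len(taxa), -1)
    ok = arr != b"-"
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                if on_empty == "zero":
                    p = 0.0
                else:
                    raise ValueError(
                        f"no comparable columns between {taxa[i]} and {taxa[j]}"
                    )
            else:
                p = float((arr[i][both] != arr[j][both]).sum()) / m
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError("Poisson correction undefined at p = 1")
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa, d)


@dataclass
class PhyloNode:
    name: str | None = None  # leaf name; None for internal nodes
    children: list[tuple["PhyloNode", float]] = field(default_factory=list)
    support: float | None = None  # bootstrap % for the edge above this node

    def leaves(self) -> list[str]:
        if self.name is not None:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        if self.name is not None:
            return self.name
        inner = ",".join(
            f"{c.newick()}:{ln:.6f}" for c, ln in self.children
        )
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}"


@dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating root."""

    root: PhyloNode
    taxa: list[str]
    negative_clamped: int = 0
    degenerate: bool = False

    def newick(self) -> str:
        return self.root.newick() + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized as the side that does not
        contain the lexicographically smallest taxon."""
        ref = min(self.taxa)
        full = set(self.taxa)
        splits: set[frozenset[str]] = set()

        def walk(node: PhyloNode) -> None:
            for child, _ in node.children:
                side = set(child.leaves())
                if 2 <= len(side) <= len(full) - 2:
                    if ref in side:
                        side = full - side
                    splits.add(frozenset(side))
                walk(child)

        walk(self.root)
        return splits


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic Saitou-Nei NJ; ties broken by the lexicographically smallest
    (representative, representative) name pair; negative branch lengths are
    clamped to zero and counted."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[PhyloNode] = [PhyloNode(name=t) for t in dm.taxa]
    reps: list[str] = list(dm.taxa)  # min leaf name per cluster, for ties
    d = dm.d.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_key = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best_key is None or key < best_key:
                    best, best_key = (i, j), key
        i, j = best
        bi = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = d[i, j] - bi
        new = PhyloNode(
            children=[(nodes[i], clamp(bi)), (nodes[j], clamp(bj))]
        )
        new_rep = min(reps[i], reps[j])
        du = np.array(
            [(d[i, k] + d[j, k] - d[i, j]) / 2.0 for k in range(m)]
        )
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], du[keep]])
        d = np.hstack([d, np.append(du[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [new_rep]

    (a, b, c) = range(3)
    va = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    vb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    vc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    root = PhyloNode(
        children=[
            (nodes[a], clamp(va)),
            (nodes[b], clamp(vb)),
            (nodes[c], clamp(vc)),
        ]
    )
    return PhyloTree(
        root=root,
        taxa=list(dm.taxa),
        negative_clamped=clamped,
        degenerate=bool(np.all(dm.d == 0.0)),
    )


def bootstrap_support(
    aligned: Mapping[str, str],
    replicates: int = 1000,
    seed: int | None = None,
    correction: str | None = None,
) -> PhyloTree:
    """NJ tree with per-edge bootstrap support (% of column-resampled
    replicates containing each original bipartition)."""
    tree = neighbor_joining(p_distance(aligned, correction=correction))
    if tree.degenerate:
        return tree
    taxa = list(aligned)
    length = len(next(iter(aligned.values())))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    done = 0
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        res = {
            t: "".join(aligned[t][c] for c in cols) for t in taxa
        }
        try:
            rep_tree = neighbor_joining(
                p_distance(res, correction=correction, on_empty="zero")
            )
        except ValueError:
            continue
        done += 1
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    full = set(taxa)
    ref = min(taxa)

    def attach(node: PhyloNode) -> None:
        for child, _ in node.children:
            side = set(child.leaves())
            if 2 <= len(side) <= len(full) - 2:
                canon = frozenset(full - side if ref in side else side)
                if done:
                    child.support = 100.0 * counts[canon] / done
            attach(child)

    attach(tree.root)
    return tree


def assign_subgroups(
    tree: PhyloTree, labeled_leaves: Mapping[str, str]
) -> dict[str, str]:
    """Label each unlabeled leaf from the smallest surrounding clade that
    contains at least one reference leaf; conflicting labels -> UNASSIGNED.

    Clades are the two sides of every edge of the unrooted tree.
    """
    sides: list[set[str]] = []
    full = set(tree.taxa)

    def walk(node: PhyloNode) -> None:
        for child, _ in node.children:
            side = set(child.leaves())
            sides.append(side)
            sides.append(full - side)
            walk(child)

    walk(tree.root)
    out: dict[str, str] = {}
    for leaf in tree.taxa:
        if leaf in labeled_leaves:
            continue
        candidates = [
            s
            for s in sides
            if leaf in s and any(x in labeled_leaves for x in s)
        ]
        if not candidates:
            out[leaf] = "UNASSIGNED"
            continue
        smallest = min(candidates, key=lambda s: (len(s), tuple(sorted(s))))
        labels = {
            labeled_leaves[x] for x in smallest if x in labeled_leaves
        }
        out[leaf] = labels.pop() if len(labels) == 1 else "UNASSIGNED"
    return out


_protein_aligner = Align.PairwiseAligner()
_protein_aligner.mode = "global"
_protein_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_protein_aligner.open_gap_score = -10.0
_protein_aligner.extend_gap_score = -0.5


def center_star_align(seqs: Mapping[str, str]) -> dict[str, str]:
    """Naive center-star multiple alignment (fixture building only).

    Every sequence is pairwise-aligned to the longest one and the pairwise
    gap patterns are merged relative to the center.
    """
    names = list(seqs)
    if len(names) == 1:
        return dict(seqs)
    center = max(names, key=lambda t: (len(seqs[t]), t))
    center_seq = seqs[center]
    # per-center-position insertions (gap runs in the center) and row maps
    rows: dict[str, tuple[list[str], list[str]]] = {}
    max_ins = [0] * (len(center_seq) + 1)
    for name in names:
        if name == center:
            continue
        aln = _protein_aligner.align(center_seq, seqs[name])[0]
        ic, iq = aln.indices
        cells: list[list[str]] = [[] for _ in range(len(center_seq) + 1)]
        pos = 0
        per_pos: list[str] = [""] * len(center_seq)
        for xc, xq in zip(ic, iq):
            ch = seqs[name][xq] if xq >= 0 else "-"
            if xc >= 0:
                per_pos[xc] = ch
                pos = xc + 1
            else:
                cells[pos].append(ch)
        ins = ["".join(c) for c in cells]
        for k, s in enumerate(ins):
            max_ins[k] = max(max_ins[k], len(s))
        rows[name] = (per_pos, ins)

    def build(per_pos: list[str], ins: list[str]) -> str:
        out = []
        for k in range(len(center_seq) + 1):
            block = ins[k] if k < len(ins) else ""
            out.append(block.ljust(max_ins[k], "-"))
            if k < len(center_seq):
                out.append(per_pos[k] or "-")
        return "".join(out)

    result = {
        center: build(list(center_seq), [""] * (len(center_seq) + 1))
    }
    for name, (per_pos, ins) in rows.items():
        result[name] = build(per_pos, ins)
    return {t: result[t] for t in names}
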