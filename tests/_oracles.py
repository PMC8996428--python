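"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written as plainly as possible, from the definition of the
quantity rather than from the implementation's structure.
"""

from __future__ import annotations

import math
import re
from itertools import permutations

from Bio.Seq import Seq

# --- VQ motif: plain regular-expression scan --------------------------------

_H = "AVLIMFWYC"
_VQ_RE = re.compile(rf"(?=(F[A-Z]{{3}}V[QH][A-Z][{_H}][A-Z]{{2}}))")


def regex_scan_vq(protein: str) -> list[tuple[int, str, bool]]:
    """(offset, decamer, canonical) for every motif window."""
    out = []
    for m in _VQ_RE.finditer(protein.upper()):
        w = m.group(1)
        out.append((m.start(), w, w[8:10] == "TG"))
    return out


# --- NG86: from-the-definition site and pathway counting --------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _syn_sites_of_codon(codon: str) -> float:
    total = 0.0
    for pos in range(3):
        syn = 0
        possible = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in _STOPS:
                continue
            possible += 1
            if _aa(mut) == _aa(codon):
                syn += 1
        if possible:
            total += syn / possible
    return total


def oracle_ng86(cds_a: str, cds_b: str):
    """(ka, ks) by explicit pathway enumeration; None where the Jukes-Cantor
    correction is undefined (p >= 3/4)."""
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    codons = [
        (cds_a[i : i + 3], cds_b[i : i + 3]) for i in range(0, len(cds_a), 3)
    ]
    s_sites = (
        sum(_syn_sites_of_codon(a) for a, _ in codons)
        + sum(_syn_sites_of_codon(b) for _, b in codons)
    ) / 2.0
    n_sites = 3 * len(codons) - s_sites
    sd = nd = 0.0
    for a, b in codons:
        positions = [p for p in range(3) if a[p] != b[p]]
        if not positions:
            continue
        path_counts = []
        blocked_counts = []
        for order in permutations(positions):
            cur = a
            s = n = 0
            hit_stop = False
            for p in order:
                nxt = cur[:p] + b[p] + cur[p + 1 :]
                if nxt in _STOPS:
                    hit_stop = True
                if _aa(cur) == _aa(nxt):
                    s += 1
                else:
                    n += 1
                cur = nxt
            (blocked_counts if hit_stop else path_counts).append((s, n))
        chosen = path_counts or blocked_counts
        sd += sum(c[0] for c in chosen) / len(chosen)
        nd += sum(c[1] for c in chosen) / len(chosen)

    def jc(p: float):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    return jc(pn), jc(ps)


# --- SSR: scan every (start, unit length) and extend -------------------------


def _primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def brute_force_ssrs(
    seq: str, thresholds=(10, 6, 5, 5, 5, 5)
) -> list[tuple[str, int, int, int]]:
    """(motif, count, start, end) records, 1-based, same reporting policy as
    the scanner: left-aligned maximal primitive repeats, smallest unit wins
    on overlap."""
    seq = seq.upper()
    n = len(seq)
    cands: list[tuple[str, int, int, int]] = []
    for k in range(1, 7):
        thr = thresholds[k - 1]
        for p in range(n - k * thr + 1):
            unit = seq[p : p + k]
            if any(c not in "ACGT" for c in unit) or not _primitive(unit):
                continue
            # left-aligned: the period must not extend through p-1
            if p > 0 and seq[p - 1] in "ACGT" and seq[p - 1] == seq[p - 1 + k]:
                continue
            count = 1
            while seq[p + count * k : p + (count + 1) * k] == unit:
                count += 1
            if count >= thr:
                cands.append((unit, count, p + 1, p + k * count))
    cands.sort(key=lambda r: (len(r[0]), r[2]))
    kept: list[tuple[str, int, int, int]] = []
    for cand in cands:
        if not any(
            len(r[0]) < len(cand[0])
            and not (cand[3] < r[2] or cand[2] > r[3])
            for r in kept
        ):
            kept.append(cand)
    kept.sort(key=lambda r: r[2])
    return kept


# --- homoeolog ratio: exhaustive rule restatement ----------------------------


def oracle_ratio_category(na: int, nb: int, nd: int) -> str:
    ms = sorted((na, nb, nd))
    if ms == [1, 1, 1]:
        return "TRIAD_1_1_1"
    if ms[0] == 1 and ms[1] == 1 and ms[2] > 1:
        return "DUP_n_1_1"
    if ms == [0, 1, 1]:
        return "LOSS_1_1_0"
    if na + nb + nd == 1:
        return "ORPHAN"
    return "OTHER"


# --- random additive trees for NJ recovery -----------------------------------


def random_additive_tree(rng, n_taxa: int = 8):
    """A random unrooted binary tree with positive branch lengths.

    Returns (taxa, distance matrix as dict-of-dict, bipartitions as a set of
    frozensets canonicalized against the smallest taxon name).
    """
    import networkx as nx

    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    g = nx.Graph()
    g.add_edge(taxa[0], "i0", weight=rng.uniform(0.1, 1.0))
    g.add_edge(taxa[1], "i0", weight=rng.uniform(0.1, 1.0))
    g.add_edge(taxa[2], "i0", weight=rng.uniform(0.1, 1.0))
    next_internal = 1
    for leaf in taxa[3:]:
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        w = g[u][v]["weight"]
        frac = rng.uniform(0.2, 0.8)
        mid = f"i{next_internal}"
        next_internal += 1
        g.remove_edge(u, v)
        g.add_edge(u, mid, weight=w * frac)
        g.add_edge(mid, v, weight=w * (1 - frac))
        g.add_edge(mid, leaf, weight=rng.uniform(0.1, 1.0))
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    ref = min(taxa)
    full = set(taxa)
    splits = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        comp = set(x for x in nx.node_connected_component(h, u) if x in full)
        if 2 <= len(comp) <= n_taxa - 2:
            if ref in comp:
                comp = full - comp
            splits.add(frozenset(comp))
    return taxa, dist, splits
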