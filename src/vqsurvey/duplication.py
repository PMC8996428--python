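"""Duplicated-gene detection, tandem/segmental classification and NG86 Ka/Ks.

A gene pair is called duplicated when a global, protein-guided codon alignment
covers more than 75% of the longer CDS and more than 75% of the aligned
nucleotide columns are identical (both thresholds strict). Pairs on the same
chromosome that are close (few intervening genes, or within a distance cap)
are tandem duplicates; everything else is segmental.

Ka and Ks follow the Nei-Gojobori (1986) counting method: synonymous site
fractions per codon position (changes to stop codons excluded from the
denominator), observed differences partitioned by equal-weight averaging over
all minimal substitution pathways that avoid stop codons, and Jukes-Cantor
correction d = -(3/4) ln(1 - (4/3) p). A proportion p >= 3/4 leaves the
correction undefined and the corresponding rate is returned as None.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from math import log

__all__ = [
    "CodonAlignment",
    "DuplicationPair",
    "align_cds_pair",
    "is_duplicated_pair",
    "classify_duplication",
    "ng86",
    "ng86_counts",
    "selection_call",
    "find_duplicated_pairs",
]

_STANDARD = unambiguous_dna_by_id[1]
_STOPS = frozenset(_STANDARD.stop_codons)
_BASES = "ACGT"


def _codon_table() -> dict[str, str]:
    table = dict(_STANDARD.forward_table)
    for stop in _STOPS:
        table[stop] = "*"
    return table


_AA = _codon_table()


@dataclass
class CodonAlignment:
    """A pair of codon-aligned CDSs (gaps in whole-codon units)."""

    aln_a: str
    aln_b: str

    def __post_init__(self) -> None:
        if len(self.aln_a) != len(self.aln_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.aln_a) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    def aligned_codon_pairs(self) -> list[tuple[str, str]]:
        """Codon pairs at columns where neither sequence is gapped."""
        out = []
        for i in range(0, len(self.aln_a), 3):
            ca, cb = self.aln_a[i : i + 3], self.aln_b[i : i + 3]
            if "-" not in ca and "-" not in cb:
                out.append((ca, cb))
        return out


@dataclass
class DuplicationPair:
    gene_a: str
    gene_b: str
    coverage: float
    identity: float
    kind: str | None = None  # "tandem" | "segmental"
    ka: float | None = None
    ks: float | None = None

    @property
    def ratio(self) -> float | None:
        if self.ka is None or self.ks is None or self.ks == 0:
            return None
        return self.ka / self.ks

    @property
    def selection(self) -> str:
        return selection_call(self.ka, self.ks)


def _strip_stop(cds: str) -> str:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if cds[-3:] in _STOPS:
        cds = cds[:-3]
    aa = str(Seq(cds).translate())
    if "*" in aa:
        raise ValueError("internal stop codon in CDS")
    return cds


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -10.0
_aligner.extend_gap_score = -0.5


def align_cds_pair(
    cds_a: str, cds_b: str
) -> tuple[CodonAlignment, float, float]:
    """Protein-guided global codon alignment plus coverage and identity.

    Needleman-Wunsch on the translated proteins (BLOSUM62, gap open 10,
    extend 0.5), back-translated to codons. Terminal stop codons are stripped
    before alignment. Coverage is aligned (non-gap) codons x3 over the length
    of the longer stripped CDS; identity is identical nucleotides over aligned
    non-gap nucleotide columns.
    """
    a = _strip_stop(cds_a)
    b = _strip_stop(cds_b)
    prot_a = str(Seq(a).translate())
    prot_b = str(Seq(b).translate())
    aln = _aligner.align(prot_a, prot_b)[0]
    ia, ib = aln.indices  # per-column residue index or -1 for a gap
    cod_a, cod_b = [], []
    for xa, xb in zip(ia, ib):
        cod_a.append(a[3 * xa : 3 * xa + 3] if xa >= 0 else "---")
        cod_b.append(b[3 * xb : 3 * xb + 3] if xb >= 0 else "---")
    ca = CodonAlignment("".join(cod_a), "".join(cod_b))
    pairs = ca.aligned_codon_pairs()
    coverage = 3.0 * len(pairs) / max(len(a), len(b))
    n_cols = 3 * len(pairs)
    if n_cols == 0:
        return ca, 0.0, 0.0
    ident = sum(
        x == y for pa, pb in pairs for x, y in zip(pa, pb)
    )
    return ca, coverage, ident / n_cols


def is_duplicated_pair(
    coverage: float, identity: float, cov_min: float = 0.75, id_min: float = 0.75
) -> bool:
    """Strictly-greater-than test on both the coverage and identity criteria."""
    return coverage > cov_min and identity > id_min


def classify_duplication(
    gene_a: str,
    gene_b: str,
    genes: Sequence,
    max_intervening: int = 5,
    max_distance: int = 200_000,
) -> str:
    """Tandem iff same chromosome and close; otherwise segmental.

    "Close" means at most ``max_intervening`` annotated genes lie between the
    two (by midpoint), or the midpoints are within ``max_distance`` bp.
    """
    by_id = {g.gene_id: g for g in genes}
    ga, gb = by_id[gene_a], by_id[gene_b]
    if ga.chromosome != gb.chromosome:
        return "segmental"
    mid_a = (ga.start + ga.end) / 2.0
    mid_b = (gb.start + gb.end) / 2.0
    lo, hi = sorted((mid_a, mid_b))
    if hi - lo <= max_distance:
        return "tandem"
    intervening = sum(
        1
        for g in genes
        if g.chromosome == ga.chromosome
        and g.gene_id not in (gene_a, gene_b)
        and lo < (g.start + g.end) / 2.0 < hi
    )
    return "tandem" if intervening <= max_intervening else "segmental"


def _syn_site_fraction(codon: str, pos: int) -> float:
    """Fraction of possible changes at one codon position that are synonymous.

    Changes producing a stop codon are excluded from the denominator.
    """
    aa = _AA[codon]
    syn = 0
    possible = 0
    for base in _BASES:
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if mutant in _STOPS:
            continue
        possible += 1
        if _AA[mutant] == aa:
            syn += 1
    if possible == 0:
        return 0.0
    return syn / possible


def _codon_sites(codon: str) -> float:
    """Synonymous site count of one codon (sum over its 3 positions)."""
    return sum(_syn_site_fraction(codon, p) for p in range(3))


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged over minimal
    substitution pathways that avoid stop codons."""
    diff_pos = [p for p in range(3) if ca[p] != cb[p]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = ca
        sd = nd = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in _STOPS:
                blocked = True
            if _AA.get(cur, "*") == _AA.get(nxt, "*"):
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not blocked:
            valid.append((sd, nd))
    paths = valid or all_paths  # fall back if every pathway crosses a stop
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_counts(alignment: CodonAlignment) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) site and difference counts for a codon alignment."""
    pairs = alignment.aligned_codon_pairs()
    if not pairs:
        raise ValueError("no aligned codons")
    for ca, cb in pairs:
        if ca in _STOPS or cb in _STOPS:
            raise ValueError("stop codon inside alignment")
    s_a = sum(_codon_sites(ca) for ca, _ in pairs)
    s_b = sum(_codon_sites(cb) for _, cb in pairs)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(pairs) - s_sites
    sd = nd = 0.0
    for ca, cb in pairs:
        d_s, d_n = _pathway_diffs(ca, cb)
        sd += d_s
        nd += d_n
    return s_sites, n_sites, sd, nd


def ng86(alignment: CodonAlignment) -> tuple[float | None, float | None]:
    """Nei-Gojobori (ka, ks); a rate is None where Jukes-Cantor saturates."""
    s_sites, n_sites, sd, nd = ng86_counts(alignment)
    if s_sites == 0 and sd > 0:
        raise ValueError("synonymous differences with zero synonymous sites")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return _jukes_cantor(pn), _jukes_cantor(ps)


def selection_call(ka: float | None, ks: float | None) -> str:
    """positive / neutral / purifying by the Ka/Ks ratio; undefined when
    Ks is zero or either rate is undefined."""
    if ka is None or ks is None or ks == 0:
        return "undefined"
    ratio = ka / ks
    if ratio > 1:
        return "positive"
    if ratio < 1:
        return "purifying"
    return "neutral"


def find_duplicated_pairs(
    cds: Mapping[str, str],
    genes: Sequence,
    cov_min: float = 0.75,
    id_min: float = 0.75,
    max_intervening: int = 5,
    max_distance: int = 200_000,
) -> list[DuplicationPair]:
    """All-vs-all duplicate detection with Ka/Ks for each passing pair.

    Pairs whose length ratio already caps coverage at or below ``cov_min``
    are skipped without aligning (coverage cannot exceed shorter/longer).
    """
    ids = sorted(cds)
    stripped = {gid: _strip_stop(cds[gid]) for gid in ids}
    out: list[DuplicationPair] = []
    for i, ga in enumerate(ids):
        for gb in ids[i + 1 :]:
            la, lb = len(stripped[ga]), len(stripped[gb])
            if min(la, lb) / max(la, lb) <= cov_min:
                continue
            aln, coverage, identity = align_cds_pair(cds[ga], cds[gb])
            if not is_duplicated_pair(coverage, identity, cov_min, id_min):
                continue
            ka, ks = ng86(aln)
            out.append(
                DuplicationPair(
                    gene_a=ga,
                    gene_b=gb,
                    coverage=coverage,
                    identity=identity,
                    kind=classify_duplication(
                        ga, gb, genes, max_intervening, max_distance
                    ),
                    ka=ka,
                    ks=ks,
                )
            )
    return out
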