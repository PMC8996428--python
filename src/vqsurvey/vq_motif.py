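"""Deterministic VQ-domain motif scanning and variant typing.

VQ transcriptional cofactors carry the short conserved motif FxxhVQxhTG
(x: any residue, h: hydrophobic). The scan reports every 10-residue window
whose constrained positions match:

    position  1  2  3  4  5  6  7  8  9  10
              F  x  x  x  V  Q/H x  h  T  G

Windows matching positions 1-8 but ending in something other than TG are
reported as non-canonical; this captures the rare terminal variants such as
VMA while keeping the false-positive rate of the relaxed ending low. The
"core" is the VQ (or VH) dipeptide at positions 5-6 and the "variant" label is
the terminal tripeptide at positions 8-10 (LTG, FTG, ITG, VTG, VMA, ...).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "HYDROPHOBIC",
    "VQHit",
    "scan_vq",
    "scan_proteins",
    "classify_family",
    "FamilyVerdict",
    "assign_family_names",
]

#: Default hydrophobic set for the h positions: the standard hydrophobics,
#: covering every terminal-variant first residue observed in plant VQ families
#: (L, F, I, V) plus A, M, W, Y, C.
HYDROPHOBIC = frozenset("AVLIMFWYC")

_CORES = ("Q", "H")


@dataclass(frozen=True)
class VQHit:
    """A located VQ-motif occurrence."""

    gene_id: str
    offset: int  # 0-based index of the motif's F
    decamer: str
    core: str  # "VQ" or "VH"
    variant: str  # terminal tripeptide, e.g. LTG / VMA
    canonical: bool  # True iff positions 9-10 are TG


def scan_vq(
    protein_seq: str,
    hydrophobic_set: frozenset[str] | set[str] = HYDROPHOBIC,
    gene_id: str = "",
) -> list[VQHit]:
    """All VQ-motif windows in a protein, sorted by offset.

    X is tolerated in the input but never matches a constrained position.
    Overlapping hits are all reported.
    """
    seq = protein_seq.upper()
    hits: list[VQHit] = []
    for i in range(len(seq) - 9):
        w = seq[i : i + 10]
        if (
            w[0] == "F"
            and w[4] == "V"
            and w[5] in _CORES
            and w[7] in hydrophobic_set
        ):
            hits.append(
                VQHit(
                    gene_id=gene_id,
                    offset=i,
                    decamer=w,
                    core="V" + w[5],
                    variant=w[7:10],
                    canonical=w[8:10] == "TG",
                )
            )
    return hits


def scan_proteins(
    proteins: Mapping[str, str],
    hydrophobic_set: frozenset[str] | set[str] = HYDROPHOBIC,
) -> dict[str, list[VQHit]]:
    return {
        gid: scan_vq(seq, hydrophobic_set, gene_id=gid)
        for gid, seq in proteins.items()
    }


@dataclass
class FamilyVerdict:
    gene_id: str
    is_vq: bool
    best_hit: VQHit | None


def classify_family(
    hits_by_gene: Mapping[str, Sequence[VQHit]],
) -> tuple[dict[str, FamilyVerdict], Counter]:
    """Per-gene family membership plus a variant census across the family.

    A gene is a VQ-family member iff it has at least one hit; its best hit is
    the first canonical hit, else the first hit. The census counts hits per
    terminal-variant label over all genes.
    """
    verdicts: dict[str, FamilyVerdict] = {}
    census: Counter = Counter()
    for gid, hits in hits_by_gene.items():
        best = None
        for h in hits:
            if h.canonical:
                best = h
                break
        if best is None and hits:
            best = hits[0]
        verdicts[gid] = FamilyVerdict(gene_id=gid, is_vq=bool(hits), best_hit=best)
        census.update(h.variant for h in hits)
    return verdicts, census


def assign_family_names(genes, groups, prefix: str = "TaVQ") -> dict[str, str]:
    """Name family members by chromosomal location, wheat-style.

    Groups are numbered 1..G ordered by (chromosome group number, minimum
    member start coordinate, subgenome letter); each member is named
    ``<prefix><groupNumber>-<chromosome>``; two or more inparalogs on the same
    chromosome get consecutive suffixes in coordinate order (e.g. 6-2B1,
    6-2B2). Every gene must belong to exactly one group.

    ``genes`` is an iterable of GeneModel; ``groups`` of HomoeologGroup.
    """
    from .homoeolog import parse_subgenome

    by_id = {g.gene_id: g for g in genes}
    seen: dict[str, int] = {}
    for grp in groups:
        for gid in grp.members:
            if gid in seen:
                raise ValueError(f"gene {gid!r} belongs to more than one group")
            if gid not in by_id:
                raise ValueError(f"group member {gid!r} not among the genes")
            seen[gid] = grp.group_id
    missing = set(by_id) - set(seen)
    if missing:
        raise ValueError(f"genes in no group: {sorted(missing)}")

    def sort_key(grp):
        parsed = [parse_subgenome(by_id[gid].chromosome) for gid in grp.members]
        chrom_group = min(p[0] for p in parsed)
        min_start = min(by_id[gid].start for gid in grp.members)
        sub = min(p[1] for p in parsed)
        return (chrom_group, min_start, sub)

    names: dict[str, str] = {}
    for number, grp in enumerate(sorted(groups, key=sort_key), start=1):
        per_chrom: dict[str, list[str]] = {}
        for gid in grp.members:
            per_chrom.setdefault(by_id[gid].chromosome, []).append(gid)
        for chrom, gids in per_chrom.items():
            gids.sort(key=lambda gid: by_id[gid].start)
            if len(gids) == 1:
                names[gids[0]] = f"{prefix}{number}-{chrom}"
            else:
                for i, gid in enumerate(gids, 1):
                    names[gid] = f"{prefix}{number}-{chrom}{i}"
    return names
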