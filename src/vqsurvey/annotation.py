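"""Gene-structure and chromosome-distribution summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import round_half_up
from .seqio import GeneModel

__all__ = ["StructureSummary", "intron_counts", "chromosome_distribution"]


@dataclass
class StructureSummary:
    per_gene: dict[str, int]  # gene id -> intron count (exons - 1)
    n_genes: int
    n_intronless: int
    pct_intronless: float  # 2 decimals, half-up


def intron_counts(genes: Sequence[GeneModel]) -> StructureSummary:
    """Intron counts per gene (computed on exons, transcript convention)."""
    per_gene: dict[str, int] = {}
    for g in genes:
        if not g.exons:
            raise ValueError(f"gene {g.gene_id} has no exons")
        per_gene[g.gene_id] = len(g.exons) - 1
    n = len(per_gene)
    n0 = sum(1 for c in per_gene.values() if c == 0)
    return StructureSummary(
        per_gene=per_gene,
        n_genes=n,
        n_intronless=n0,
        pct_intronless=round_half_up(100.0 * n0 / n, 2) if n else 0.0,
    )


def chromosome_distribution(
    genes: Sequence[GeneModel], chromosomes: Iterable[str] | None = None
) -> dict[str, int]:
    """Gene counts per chromosome, including zero-count chromosomes."""
    counts = {c: 0 for c in chromosomes} if chromosomes is not None else {}
    for g in genes:
        counts[g.chromosome] = counts.get(g.chromosome, 0) + 1
    return counts
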