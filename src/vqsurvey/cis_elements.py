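"""Promoter scanning against a catalog of named cis-element consensus patterns.

Patterns are IUPAC consensus strings (R = A/G, Y = C/T, N = any base, ...).
An N in the *sequence* matches nothing. Both strands are scanned by default;
minus-strand hits are reported at the leftmost plus-strand coordinate of the
matched span. Overlapping matches of the same element are all counted, the
way site-instance reports from promoter-scanning services behave.

The default catalog covers the elements conventionally reported in plant
stress-gene promoter surveys: the WRKY-binding W-box (TTGACC / TTGACT, i.e.
(T)TGAC(C/T)), hormone-response elements (ABRE, CGTCA/TGACG MeJA pair,
TCA-element, gibberellin boxes, auxin elements), stress elements (LTR, MBS,
TC-rich repeats, MYB, MYC, DRE core, ARE, GC-motif) and development elements
(MSA-like, RY-element, CAT-box). Only the W-box consensus is anchored in the
family literature; the rest follow PlantCARE-style definitions and are fully
overridable via a TSV catalog.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import revcomp

__all__ = [
    "IUPAC",
    "ElementCatalog",
    "CisHit",
    "default_catalog",
    "load_catalog",
    "scan_elements",
    "scan_promoters",
    "element_count_matrix",
]

IUPAC: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

CATEGORIES = ("WRKY-binding", "hormone", "stress", "development")

_DEFAULT_ENTRIES: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("W-box", "WRKY-binding", ("TTGACC", "TTGACT")),
    ("ABRE", "hormone", ("ACGTG",)),
    ("TGA-element", "hormone", ("AACGAC",)),
    ("AuxRR-core", "hormone", ("GGTCCAT",)),
    ("CGTCA-motif", "hormone", ("CGTCA",)),
    ("TGACG-motif", "hormone", ("TGACG",)),
    ("TATC-box", "hormone", ("TATCCCA",)),
    ("GARE-motif", "hormone", ("TCTGTTG",)),
    ("P-box", "hormone", ("CCTTTTG",)),
    ("TCA-element", "hormone", ("CCATCTTTTT",)),
    ("LTR", "stress", ("CCGAAA",)),
    ("MBS", "stress", ("CAACTG",)),
    ("TC-rich repeats", "stress", ("ATTCTCTAAC",)),
    ("MYB", "stress", ("CAACCA",)),
    ("MYC", "stress", ("CANNTG",)),
    ("DRE core", "stress", ("RCCGAC",)),
    ("ARE", "stress", ("AAACCA",)),
    ("GC-motif", "stress", ("CCCCCG",)),
    ("MSA-like", "development", ("TCCAACGGT",)),
    ("RY-element", "development", ("CATGCA",)),
    ("CAT-box", "development", ("GCCACT",)),
)


def _compile(consensus: str) -> re.Pattern:
    parts = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"malformed IUPAC consensus {consensus!r}: {ch!r}")
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping matches are all found
    return re.compile(f"(?=({''.join(parts)}))")


@dataclass
class ElementCatalog:
    entries: dict[str, list[str]]  # element name -> consensus strings
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._compiled = {
            name: [_compile(c) for c in strings]
            for name, strings in self.entries.items()
        }

    @property
    def names(self) -> list[str]:
        return list(self.entries)


def default_catalog() -> ElementCatalog:
    return ElementCatalog(
        entries={name: list(cons) for name, _, cons in _DEFAULT_ENTRIES},
        categories={name: cat for name, cat, _ in _DEFAULT_ENTRIES},
    )


def load_catalog(path: str | Path) -> ElementCatalog:
    """Read a catalog TSV with columns: name, category, consensus (comma-split)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    entries: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    for row in df.itertuples(index=False):
        name = str(row.name)
        if name in entries:
            raise ValueError(f"duplicate element name {name!r}")
        entries[name] = [c.strip().upper() for c in str(row.consensus).split(",")]
        categories[name] = str(row.category)
    return ElementCatalog(entries=entries, categories=categories)


@dataclass(frozen=True)
class CisHit:
    promoter_id: str
    element: str
    strand: str  # "+" or "-"
    offset: int  # 1-based leftmost plus-strand coordinate of the match


def scan_elements(
    promoter_seq: str,
    catalog: ElementCatalog,
    both_strands: bool = True,
    promoter_id: str = "",
) -> list[CisHit]:
    """Every catalog match in a promoter, sorted by offset then element name."""
    seq = promoter_seq.upper()
    n = len(seq)
    hits: list[CisHit] = []
    rc = revcomp(seq) if both_strands else ""
    for name, patterns in catalog._compiled.items():
        for pat in patterns:
            for m in pat.finditer(seq):
                hits.append(CisHit(promoter_id, name, "+", m.start() + 1))
            if both_strands:
                for m in pat.finditer(rc):
                    span = len(m.group(1))
                    # revcomp position j (0-based) spans plus-strand
                    # [n - j - span, n - j - 1] (0-based)
                    hits.append(
                        CisHit(promoter_id, name, "-", n - m.start() - span + 1)
                    )
    hits.sort(key=lambda h: (h.offset, h.element, h.strand))
    return hits


def scan_promoters(
    promoters: Mapping[str, str],
    catalog: ElementCatalog,
    both_strands: bool = True,
) -> dict[str, list[CisHit]]:
    return {
        pid: scan_elements(seq, catalog, both_strands, promoter_id=pid)
        for pid, seq in promoters.items()
    }


def element_count_matrix(
    hits: Mapping[str, Sequence[CisHit]] | Iterable[CisHit],
    promoter_ids: Sequence[str],
    catalog: ElementCatalog,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x element count matrix plus per-element gene-coverage fractions."""
    if isinstance(hits, Mapping):
        flat = [h for hs in hits.values() for h in hs]
    else:
        flat = list(hits)
    counts = pd.DataFrame(
        0, index=list(promoter_ids), columns=catalog.names, dtype=int
    )
    for h in flat:
        counts.loc[h.promoter_id, h.element] += 1
    coverage = (counts > 0).sum(axis=0) / len(promoter_ids) if len(
        promoter_ids
    ) else (counts.sum(axis=0) * 0.0)
    return counts, coverage
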