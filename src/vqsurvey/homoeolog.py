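"""Homoeolog-group assembly and retention-ratio classification.

In hexaploid wheat every gene sits on one of 21 chromosomes named
<group 1-7><subgenome A/B/D>. A family group's retention pattern is read off
its per-subgenome member counts (nA, nB, nD):

    TRIAD_1_1_1  (1,1,1)            the fully retained homoeologous triad
    DUP_n_1_1    one count > 1,     homoeolog-specific duplication
                 the other two = 1  (n:1:1 / 1:n:1 / 1:1:n)
    LOSS_1_1_0   one count = 0,     loss of a single homoeolog
                 the other two = 1  (1:1:0 / 1:0:1 / 0:1:1)
    ORPHAN       a single gene      orphans/singletons
    OTHER        anything else      (includes mixed loss+duplication patterns)

Groups are provided (by the synthetic generator, a naming convention, or an
external orthology run); inferring them from sequence similarity is out of
scope here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import percent

__all__ = [
    "CATEGORIES",
    "HomoeologGroup",
    "TriadSummary",
    "parse_subgenome",
    "classify_ratio",
    "group_from_members",
    "summarize_triads",
    "REFERENCE_GENOME_PERCENTS",
]

CATEGORIES = ("TRIAD_1_1_1", "DUP_n_1_1", "LOSS_1_1_0", "OTHER", "ORPHAN")

#: Genome-wide category percentages for all wheat genes (IWGSC 2018), used as
#: the comparison column of the triad summary.
REFERENCE_GENOME_PERCENTS: Mapping[str, float] = {
    "TRIAD_1_1_1": 35.8,
    "DUP_n_1_1": 5.7,
    "LOSS_1_1_0": 13.2,
    "OTHER": 8.0,
    "ORPHAN": 37.1,
}

_CHROM_RE = re.compile(r"^([1-7])([ABD])$")


def parse_subgenome(
    chromosome_name: str, pattern: re.Pattern | str = _CHROM_RE
) -> tuple[int, str]:
    """Split a wheat-style chromosome name into (group 1-7, subgenome letter)."""
    if isinstance(pattern, str):
        pattern = re.compile(pattern)
    m = pattern.match(chromosome_name)
    if not m:
        raise ValueError(f"unparseable chromosome name {chromosome_name!r}")
    return int(m.group(1)), m.group(2)


def classify_ratio(n_a: int, n_b: int, n_d: int) -> str:
    """Category of a (nA, nB, nD) retention pattern (see module docstring)."""
    counts = (n_a, n_b, n_d)
    if any(c < 0 for c in counts):
        raise ValueError("negative member count")
    if sum(counts) == 0:
        raise ValueError("empty homoeolog group")
    if counts == (1, 1, 1):
        return "TRIAD_1_1_1"
    if sorted(counts) == [1, 1] + [max(counts)] and max(counts) > 1:
        return "DUP_n_1_1"
    if sorted(counts) == [0, 1, 1]:
        return "LOSS_1_1_0"
    if sum(counts) == 1:
        return "ORPHAN"
    return "OTHER"


@dataclass
class HomoeologGroup:
    group_id: int
    members: list[str]  # gene ids
    counts: tuple[int, int, int]  # (nA, nB, nD)

    def __post_init__(self) -> None:
        if sum(self.counts) != len(self.members):
            raise ValueError(
                f"group {self.group_id}: counts {self.counts} do not sum to "
                f"{len(self.members)} members"
            )

    @property
    def category(self) -> str:
        return classify_ratio(*self.counts)


def group_from_members(
    group_id: int,
    members: Sequence[tuple[str, str]],
    subgenomes: Sequence[str] = ("A", "B", "D"),
) -> HomoeologGroup:
    """Build a group from (gene_id, chromosome_name) pairs."""
    tally = {s: 0 for s in subgenomes}
    ids = []
    for gid, chrom in members:
        _, sub = parse_subgenome(chrom)
        tally[sub] += 1
        ids.append(gid)
    return HomoeologGroup(group_id, ids, tuple(tally[s] for s in subgenomes))


@dataclass
class TriadSummary:
    n_groups: dict[str, int] = field(default_factory=dict)
    n_genes: dict[str, int] = field(default_factory=dict)
    pct_genes: dict[str, float] = field(default_factory=dict)  # 1 decimal
    reference_pct: Mapping[str, float] = field(default_factory=dict)
    total_groups: int = 0
    total_genes: int = 0


def summarize_triads(
    groups: Iterable[HomoeologGroup],
    reference_percents: Mapping[str, float] = REFERENCE_GENOME_PERCENTS,
) -> TriadSummary:
    """Per-category group/gene counts and gene percentages (1 decimal, half-up).

    Percent denominators are genes, not groups.
    """
    n_groups = {c: 0 for c in CATEGORIES}
    n_genes = {c: 0 for c in CATEGORIES}
    for grp in groups:
        cat = grp.category
        n_groups[cat] += 1
        n_genes[cat] += len(grp.members)
    total_genes = sum(n_genes.values())
    return TriadSummary(
        n_groups=n_groups,
        n_genes=n_genes,
        pct_genes={c: percent(n_genes[c], total_genes) for c in CATEGORIES},
        reference_pct=dict(reference_percents),
        total_groups=sum(n_groups.values()),
        total_genes=total_genes,
    )
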