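"""MISA-equivalent perfect microsatellite detection.

A simple SSR is a maximal perfect tandem repeat of a primitive 1-6 nt unit
whose repeat count reaches the per-unit-length thresholds (MISA defaults:
mono >= 10, di >= 6, tri/tetra/penta/hexa >= 5). A run reportable under
several unit lengths is reported once at the smallest unit (a poly-A run is
mononucleotide, not an AA dinucleotide). N never extends a repeat. Two simple
SSRs separated by at most a small interruption merge into one compound
record; chains merge transitively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._util import percent

__all__ = [
    "DEFAULT_THRESHOLDS",
    "SSRRecord",
    "find_ssrs",
    "merge_compound",
    "ssr_census",
]

DEFAULT_THRESHOLDS = (10, 6, 5, 5, 5, 5)


@dataclass
class SSRRecord:
    """One microsatellite locus; coordinates 1-based inclusive."""

    seq_id: str
    motif: str  # unit for simple SSRs; "(AG)6-(CT)6"-style for compounds
    repeat_count: int
    start: int
    end: int
    ssr_type: str  # p1..p6 or "compound"
    components: list["SSRRecord"] = field(default_factory=list)


def _is_primitive(unit: str) -> bool:
    """True unless the unit is itself a repetition of a shorter unit."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def find_ssrs(
    sequence: str,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    seq_id: str = "",
) -> list[SSRRecord]:
    """All simple SSRs in a nucleotide sequence, sorted by start.

    Candidate repeats of every unit length are collected left-aligned and
    maximal, then deduplicated smallest-unit-first: a candidate overlapping an
    accepted record of a strictly smaller unit is dropped.
    """
    seq = sequence.upper()
    n = len(seq)
    valid = [c in "ACGT" for c in seq]
    candidates: list[SSRRecord] = []
    for k in range(1, 7):
        thr = thresholds[k - 1]
        i = k
        run_start = 0  # start of the current period-k region
        while i <= n:
            matches = (
                i < n and valid[i] and valid[i - k] and seq[i] == seq[i - k]
            )
            if not matches:
                region_len = i - run_start
                count = region_len // k
                unit = seq[run_start : run_start + k]
                if (
                    count >= thr
                    and all(valid[run_start : run_start + k])
                    and _is_primitive(unit)
                ):
                    candidates.append(
                        SSRRecord(
                            seq_id=seq_id,
                            motif=unit,
                            repeat_count=count,
                            start=run_start + 1,
                            end=run_start + k * count,
                            ssr_type=f"p{k}",
                        )
                    )
                run_start = i - k + 1
            i += 1
    candidates.sort(key=lambda r: (len(r.motif), r.start))
    kept: list[SSRRecord] = []
    for cand in candidates:
        clash = any(
            len(r.motif) < len(cand.motif)
            and not (cand.end < r.start or cand.start > r.end)
            for r in kept
        )
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda r: r.start)
    return kept


def merge_compound(
    records: Sequence[SSRRecord], max_interruption: int = 100
) -> list[SSRRecord]:
    """Merge simple SSRs separated by <= max_interruption bp into compounds."""
    out: list[SSRRecord] = []
    chain: list[SSRRecord] = []

    def flush() -> None:
        if not chain:
            return
        if len(chain) == 1:
            out.append(chain[0])
        else:
            out.append(
                SSRRecord(
                    seq_id=chain[0].seq_id,
                    motif="-".join(
                        f"({r.motif}){r.repeat_count}" for r in chain
                    ),
                    repeat_count=sum(r.repeat_count for r in chain),
                    start=chain[0].start,
                    end=chain[-1].end,
                    ssr_type="compound",
                    components=list(chain),
                )
            )
        chain.clear()

    for rec in sorted(records, key=lambda r: r.start):
        if chain and rec.start - chain[-1].end - 1 <= max_interruption:
            chain.append(rec)
        else:
            flush()
            chain.append(rec)
    flush()
    return out


def ssr_census(records: Sequence[SSRRecord], n_genes: int) -> dict:
    """Counts and unit-length class percentages over simple SSRs.

    Compound records contribute their components to the class tally.
    """
    simple: list[SSRRecord] = []
    for r in records:
        simple.extend(r.components if r.ssr_type == "compound" else [r])
    by_class: dict[str, int] = {}
    for r in simple:
        by_class[r.ssr_type] = by_class.get(r.ssr_type, 0) + 1
    total = len(simple)
    return {
        "n_ssrs": total,
        "n_compound": sum(1 for r in records if r.ssr_type == "compound"),
        "n_genes_with_ssr": len({r.seq_id for r in records}),
        "n_genes": n_genes,
        "class_counts": by_class,
        "class_pct": {c: percent(v, total) for c, v in by_class.items()},
    }
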