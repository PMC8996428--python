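"""Physicochemical protein descriptors and the family's categorical calls.

Length, average molecular weight, theoretical pI, Guruprasad instability
index, Ikai aliphatic index and Kyte-Doolittle GRAVY, with the categorical
thresholds conventional in gene-family surveys: basic = pI > 7, unstable =
instability > 40, thermostable = aliphatic index >= 65, hydrophilic =
GRAVY < 0.

MW, GRAVY and the instability index are delegated to Biopython's ProtParam
implementation (which carries the published Kyte-Doolittle and Guruprasad
tables). The pI is solved here by bisection of the Henderson-Hasselbalch net
charge using the EMBOSS pKa set; tools differ slightly in their pKa choices,
so computed pI may differ from other calculators by a few tenths of a unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.SeqUtils import molecular_weight as _bio_mw
from Bio.SeqUtils.ProtParam import ProteinAnalysis

__all__ = [
    "AMINO_ACIDS",
    "EMBOSS_PKA",
    "ProteinProperties",
    "molecular_weight",
    "gravy",
    "aliphatic_index",
    "instability_index",
    "isoelectric_point",
    "net_charge",
    "compute_properties",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: EMBOSS iep default pKa values.
EMBOSS_PKA: Mapping[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}


def _check(seq: str) -> str:
    if not seq:
        raise ValueError("empty protein sequence")
    seq = seq.upper()
    for ch in seq:
        if ch not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {ch!r}")
    return seq


def molecular_weight(protein_seq: str) -> float:
    """Average molecular weight in Da (sum of residue masses + one water)."""
    return _bio_mw(_check(protein_seq), seq_type="protein")


def gravy(protein_seq: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle score per residue."""
    return ProteinAnalysis(_check(protein_seq)).gravy()


def aliphatic_index(protein_seq: str) -> float:
    """Ikai aliphatic index: X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)),
    with X the mole percent of each residue."""
    seq = _check(protein_seq)
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def instability_index(protein_seq: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights."""
    seq = _check(protein_seq)
    if len(seq) < 2:
        raise ValueError("instability index needs at least one dipeptide")
    return ProteinAnalysis(seq).instability_index()


def net_charge(protein_seq: str, ph: float, pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Net charge at a given pH (Henderson-Hasselbalch, linear summation)."""
    seq = _check(protein_seq)
    pos = [pka["Nterm"]] + [pka[aa] for aa in seq if aa in "KRH"]
    neg = [pka["Cterm"]] + [pka[aa] for aa in seq if aa in "DECY"]
    charge = sum(1.0 / (1.0 + 10 ** (ph - p)) for p in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (p - ph)) for p in neg)
    return charge


def isoelectric_point(
    protein_seq: str,
    pka: Mapping[str, float] = EMBOSS_PKA,
    tol: float = 1e-4,
    max_iter: int = 60,
) -> float:
    """pH of zero net charge, by bisection on [0, 14] to |charge| < tol.

    Net charge is strictly decreasing in pH, so bisection always converges.
    """
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        c = net_charge(protein_seq, mid, pka)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass
class ProteinProperties:
    length: int
    mw: float
    pi: float
    instability: float
    aliphatic: float
    gravy: float

    @property
    def is_basic(self) -> bool:
        return self.pi > 7.0

    @property
    def is_unstable(self) -> bool:
        return self.instability > 40.0

    @property
    def is_thermostable(self) -> bool:
        return self.aliphatic >= 65.0

    @property
    def is_hydrophilic(self) -> bool:
        return self.gravy < 0.0


def compute_properties(protein_seq: str) -> ProteinProperties:
    seq = _check(protein_seq)
    return ProteinProperties(
        length=len(seq),
        mw=molecular_weight(seq),
        pi=isoelectric_point(seq),
        instability=instability_index(seq) if len(seq) > 1 else 0.0,
        aliphatic=aliphatic_index(seq),
        gravy=gravy(seq),
    )
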