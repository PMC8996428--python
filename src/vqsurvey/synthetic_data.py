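"""Seeded generator of a toy hexaploid genome with planted, manifest-tracked
features for exercising every stage of the survey pipeline.

The generator emulates the statistical structure the pipeline consumes, not
wheat biology: 21 chromosomes (7 groups x A/B/D subgenomes), a 113-gene
family in 40 homoeologous groups whose retention-ratio census reproduces the
published family table (25 triads, 4 duplication groups carrying 17 genes,
8 single-loss groups, 1 other-ratio group, 2 orphans), one planted VQ motif
per protein with the published variant census, a 103/113 intronless
fraction, duplicated CDS pairs with exact planted synonymous/nonsynonymous
codon changes, MISA-threshold SSRs in 3' UTRs, promoter cis-elements at
known offsets, a zero-inflated log-normal TPM matrix with a controlled
30/40 detection rate, and a ddCt-style qPCR Ct table.

Background sequence is rejection-sampled so that no unplanted VQ motif,
catalog cis-element, or threshold-passing SSR occurs in any scanned
sequence; every planted feature lands in a ground-truth manifest sufficient
to verify pipeline output without re-deriving it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from ._util import revcomp
from .cis_elements import ElementCatalog, default_catalog, scan_elements
from .homoeolog import HomoeologGroup
from .seqio import GeneModel, write_fasta, write_gff3
from .ssr import find_ssrs
from .vq_motif import scan_vq

__all__ = ["GenConfig", "Manifest", "generate"]

_AA_LIST = list("ACDEFGHIKLMNPQRSTVWY")
_STANDARD = unambiguous_dna_by_id[1]
_STOPS = tuple(_STANDARD.stop_codons)
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)
_AA_OF = dict(_STANDARD.forward_table)


@dataclass
class GenConfig:
    """Generation conditions; defaults reproduce the published family survey
    at toy-genome scale."""

    seed: int = 42
    n_chromosome_groups: int = 7
    subgenomes: tuple[str, ...] = ("A", "B", "D")
    chromosome_length: int = 90_000
    n_family_groups: int = 40
    ratio_census: Mapping[str, int] = field(
        default_factory=lambda: {
            "TRIAD_1_1_1": 25,
            "DUP_n_1_1": 4,
            "LOSS_1_1_0": 8,
            "OTHER": 1,
            "ORPHAN": 2,
        }
    )
    dup_group_counts: tuple[tuple[int, int, int], ...] = (
        (3, 1, 1),
        (2, 1, 1),
        (2, 1, 1),
        (2, 1, 1),
    )
    other_group_counts: tuple[tuple[int, int, int], ...] = ((0, 2, 1),)
    #: (core, terminal variant, gene count); census matches the family paper.
    motif_census: tuple[tuple[str, str, int], ...] = (
        ("VQ", "LTG", 86),
        ("VQ", "FTG", 11),
        ("VQ", "VTG", 8),
        ("VQ", "ITG", 3),
        ("VH", "VTG", 4),
        ("VQ", "VMA", 1),
    )
    promoter_len: int = 1500
    utr5_len: int = 100
    utr3_len: int = 200
    n_intron_genes: int = 10
    intron_len_range: tuple[int, int] = (150, 400)
    protein_len_mean: float = 190.0
    protein_len_sd: float = 40.0
    protein_len_range: tuple[int, int] = (80, 300)
    #: (synonymous changes, nonsynonymous changes, tandem|segmental)
    duplication_pairs: tuple[tuple[int, int, str], ...] = (
        (4, 0, "tandem"),
        (8, 1, "tandem"),
        (2, 3, "segmental"),
        (10, 2, "segmental"),
        (0, 2, "segmental"),
        (6, 6, "segmental"),
    )
    ssr_thresholds: tuple[int, ...] = (10, 6, 5, 5, 5, 5)
    #: per unit-length class, how many simple SSRs to plant family-wide
    ssr_class_counts: Mapping[str, int] = field(
        default_factory=lambda: {"p1": 5, "p2": 2, "p3": 21}
    )
    n_ssr_genes: int = 25
    n_two_ssr_genes: int = 3  # genes carrying two SSRs
    n_compound_genes: int = 2  # of those, how many merge into a compound
    compound_gap: int = 30
    simple_gap: int = 120  # two-SSR genes that must stay simple
    #: element name -> number of promoters carrying one planted instance
    cis_plantings: Mapping[str, int] = field(
        default_factory=lambda: {
            "W-box": 55,
            "CGTCA-motif": 100,
            "ABRE": 98,
            "CAT-box": 35,
        }
    )
    tissue_classes: Mapping[str, int] = field(
        default_factory=lambda: {
            "leaf_stem": 4,
            "root": 3,
            "spike": 3,
            "grain": 2,
        }
    )
    n_expressed_groups: int = 30
    tpm_lognormal: tuple[float, float] = (1.0, 0.8)
    tpm_zero_inflation: float = 0.35
    qpcr_n_groups: int = 12
    qpcr_conditions: tuple[str, ...] = (
        "PEG", "NaCl", "HT", "LT", "MeJA", "SA", "ABA",
    )
    qpcr_timepoints: tuple[str, ...] = ("0h", "1h", "6h", "24h")
    qpcr_replicates: int = 3
    ct_noise_sd: float = 0.1
    spacer_range: tuple[int, int] = (200, 500)

    def validate(self) -> None:
        if sum(self.ratio_census.values()) != self.n_family_groups:
            raise ValueError("ratio census does not sum to n_family_groups")
        if len(self.dup_group_counts) != self.ratio_census.get("DUP_n_1_1", 0):
            raise ValueError("dup_group_counts length mismatches census")
        if len(self.other_group_counts) != self.ratio_census.get("OTHER", 0):
            raise ValueError("other_group_counts length mismatches census")
        n_genes = self._n_genes()
        if sum(c for _, _, c in self.motif_census) != n_genes:
            raise ValueError("motif census does not sum to the gene count")
        n_ssrs = sum(self.ssr_class_counts.values())
        expect = self.n_ssr_genes + self.n_two_ssr_genes
        if self.ssr_class_counts and n_ssrs != expect:
            raise ValueError(
                f"{n_ssrs} planted SSRs cannot fill {self.n_ssr_genes} genes "
                f"with {self.n_two_ssr_genes} two-SSR genes"
            )
        if self.n_intron_genes > n_genes:
            raise ValueError("more intron genes than genes")
        for name, k in self.cis_plantings.items():
            if k > n_genes:
                raise ValueError(f"cis planting {name!r} exceeds gene count")

    def _n_genes(self) -> int:
        n = 3 * self.ratio_census.get("TRIAD_1_1_1", 0)
        n += sum(sum(c) for c in self.dup_group_counts)
        n += 2 * self.ratio_census.get("LOSS_1_1_0", 0)
        n += sum(sum(c) for c in self.other_group_counts)
        n += self.ratio_census.get("ORPHAN", 0)
        return n


@dataclass
class Manifest:
    """Ground truth for every planted feature."""

    seed: int
    n_genes: int
    genes: list[dict]  # id, chromosome, strand, group, motif, intron count..
    groups: list[dict]  # group_id, members, counts, category
    dup_pairs: list[dict]  # source, target, kind, syn, nonsyn
    ssrs: dict[str, list[dict]]  # gene -> records in forward gene-span frame
    cis: dict[str, list[dict]]  # gene -> hits in promoter frame
    expressed_groups: list[str]
    qpcr_true: list[dict]  # group, condition, timepoint, log2_rq
    files: dict[str, str]

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"kind": "header", "seed": self.seed,
                                 "n_genes": self.n_genes}) + "\n")
            kinds = {
                "genes": "gene",
                "groups": "group",
                "dup_pairs": "dup_pair",
                "qpcr_true": "qpcr_true",
            }
            for key, kind in kinds.items():
                for rec in getattr(self, key):
                    rec = dict(rec)
                    if "kind" in rec:  # tandem/segmental field of dup pairs
                        rec["pair_kind"] = rec.pop("kind")
                    fh.write(json.dumps({"kind": kind, **rec}) + "\n")
            for gid, recs in self.ssrs.items():
                for rec in recs:
                    fh.write(json.dumps({"kind": "ssr", "gene": gid, **rec}) + "\n")
            for gid, recs in self.cis.items():
                for rec in recs:
                    fh.write(json.dumps({"kind": "cis", "gene": gid, **rec}) + "\n")
            fh.write(json.dumps({"kind": "expressed_groups",
                                 "groups": self.expressed_groups}) + "\n")


# ---------------------------------------------------------------------------
# low-level sequence builders


def _rand_nt(rng: np.random.Generator, length: int) -> list[str]:
    return [("A", "C", "G", "T")[i] for i in rng.integers(0, 4, size=length)]


def _cis_spans(seq: str, catalog: ElementCatalog) -> list[tuple[int, int]]:
    rc = revcomp(seq)
    n = len(seq)
    spans = []
    for pats in catalog._compiled.values():
        for pat in pats:
            for m in pat.finditer(seq):
                spans.append((m.start(), m.start() + len(m.group(1)) - 1))
            for m in pat.finditer(rc):
                length = len(m.group(1))
                s = n - m.start() - length
                spans.append((s, s + length - 1))
    return spans


def _ssr_spans(seq: str, thresholds: Sequence[int]) -> list[tuple[int, int]]:
    return [(r.start - 1, r.end - 1) for r in find_ssrs(seq, thresholds)]


def _clean_nt(
    rng: np.random.Generator,
    length: int,
    span_finders,
    max_rounds: int = 200,
) -> str:
    """Random sequence with every forbidden-pattern span re-randomized until
    none remain (local rejection sampling keeps the composition uniform)."""
    seq = _rand_nt(rng, length)
    for _ in range(max_rounds):
        text = "".join(seq)
        bad: list[tuple[int, int]] = []
        for finder in span_finders:
            bad.extend(finder(text))
        if not bad:
            return text
        for s, e in bad:
            for p in range(max(0, s), min(length, e + 1)):
                seq[p] = ("A", "C", "G", "T")[rng.integers(0, 4)]
    raise RuntimeError("background cleaning did not converge")


def _random_protein(
    rng: np.random.Generator,
    length: int,
    core: str,
    variant: str,
    offset: int,
) -> tuple[str, str]:
    """(protein, decamer) with exactly one VQ motif planted at `offset`."""
    for _ in range(100):
        aa = [
            _AA_LIST[i] for i in rng.integers(0, 20, size=length)
        ]
        aa[0] = "M"
        decamer = (
            "F"
            + "".join(_AA_LIST[i] for i in rng.integers(0, 20, size=3))
            + "V"
            + core[1]
            + _AA_LIST[rng.integers(0, 20)]
            + variant
        )
        aa[offset : offset + 10] = list(decamer)
        protein = "".join(aa)
        hits = scan_vq(protein)
        if len(hits) == 1 and hits[0].offset == offset:
            return protein, decamer
    raise RuntimeError("motif planting did not converge")


def _encode_cds(
    rng: np.random.Generator,
    protein: str,
    thresholds: Sequence[int],
) -> str:
    """Back-translate with random synonymous codons; SSR-free; stop added."""
    for _ in range(100):
        codons = []
        for aa in protein:
            opts = _CODONS_FOR[aa]
            codons.append(opts[rng.integers(0, len(opts))])
        codons.append(_STOPS[rng.integers(0, len(_STOPS))])
        cds = "".join(codons)
        if not find_ssrs(cds, thresholds):
            return cds
    raise RuntimeError("CDS encoding did not converge")


def _mutation_options(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    aa = _AA_OF.get(codon)
    opts = []
    for p in range(3):
        for b in "ACGT":
            if b == codon[p]:
                continue
            mut = codon[:p] + b + codon[p + 1 :]
            if mut in _STOPS:
                continue
            if (_AA_OF[mut] == aa) == synonymous:
                opts.append((p, b))
    return opts


def _mutate_cds(
    rng: np.random.Generator,
    cds: str,
    syn: int,
    nonsyn: int,
    motif_codons: range,
    thresholds: Sequence[int],
) -> str:
    """Apply exactly `syn` synonymous and `nonsyn` nonsynonymous single-
    nucleotide codon changes, away from the start codon, the stop codon and
    the planted motif codons."""
    n_codons = len(cds) // 3
    eligible = [
        i
        for i in range(1, n_codons - 1)
        if i not in motif_codons
    ]
    for _ in range(100):
        codons = [cds[3 * i : 3 * i + 3] for i in range(n_codons)]
        order = list(rng.permutation(eligible))
        used: set[int] = set()
        ok = True
        for want_syn, count in ((True, syn), (False, nonsyn)):
            placed = 0
            for i in order:
                if placed == count:
                    break
                if i in used:
                    continue
                opts = _mutation_options(codons[i], synonymous=want_syn)
                if not opts:
                    continue
                p, b = opts[rng.integers(0, len(opts))]
                codons[i] = codons[i][:p] + b + codons[i][p + 1 :]
                used.add(i)
                placed += 1
            if placed != count:
                ok = False
        mutated = "".join(codons)
        if ok and not find_ssrs(mutated, thresholds):
            return mutated
    raise RuntimeError("planting codon mutations did not converge")


def _expected_cis_for_instance(
    element_seq: str, offset0: int, catalog: ElementCatalog
) -> list[dict]:
    """Catalog hits generated by one planted instance (complement-pair
    elements, palindromic patterns), shifted to promoter coordinates.

    ``offset0`` is the 1-based promoter position of the instance start.
    """
    out = []
    for h in scan_elements(element_seq, catalog):
        out.append(
            {
                "element": h.element,
                "strand": h.strand,
                "offset": offset0 + h.offset - 1,
            }
        )
    return out


# ---------------------------------------------------------------------------


def _plan_groups(cfg: GenConfig, rng: np.random.Generator):
    """(category, (nA,nB,nD)) per group, chromosome-group assignment."""
    def rotate(c: tuple[int, int, int], k: int) -> tuple[int, int, int]:
        k %= 3
        return tuple(c[(i - k) % 3] for i in range(3))

    specs: list[tuple[str, tuple[int, int, int]]] = []
    for _ in range(cfg.ratio_census.get("TRIAD_1_1_1", 0)):
        specs.append(("TRIAD_1_1_1", (1, 1, 1)))
    for k, counts in enumerate(cfg.dup_group_counts):
        specs.append(("DUP_n_1_1", rotate(counts, k)))
    for k in range(cfg.ratio_census.get("LOSS_1_1_0", 0)):
        specs.append(("LOSS_1_1_0", rotate((1, 1, 0), k)))
    for counts in cfg.other_group_counts:
        specs.append(("OTHER", counts))
    for k in range(cfg.ratio_census.get("ORPHAN", 0)):
        specs.append(("ORPHAN", rotate((1, 0, 0), k)))

    order = list(rng.permutation(len(specs)))
    chrom_groups = {}
    for slot, idx in enumerate(order):
        chrom_groups[idx] = 1 + slot % cfg.n_chromosome_groups
    return specs, chrom_groups


def generate(config: GenConfig | None = None, out_dir: str | Path = ".") -> Manifest:
    """Write the synthetic genome bundle + tables and return the manifest.

    Deterministic given ``config.seed``: the same seed yields byte-identical
    output files.
    """
    cfg = config or GenConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = default_catalog()
    up_len = cfg.promoter_len - cfg.utr5_len
    if up_len <= 0:
        raise ValueError("promoter_len must exceed utr5_len")

    # ---- family structure ------------------------------------------------
    specs, chrom_group_of = _plan_groups(cfg, rng)
    chrom_names = [
        f"{g}{s}"
        for g in range(1, cfg.n_chromosome_groups + 1)
        for s in cfg.subgenomes
    ]
    # genes per chromosome, honoring group adjacency for inparalogs
    genes_per_chrom: dict[str, list[dict]] = {c: [] for c in chrom_names}
    for gidx, (category, counts) in enumerate(specs):
        cg = chrom_group_of[gidx]
        for sub, n_copies in zip(cfg.subgenomes, counts):
            chrom = f"{cg}{sub}"
            for copy in range(n_copies):
                genes_per_chrom[chrom].append(
                    {"group_idx": gidx, "category": category, "copy": copy}
                )
    plans: list[dict] = []
    for chrom in chrom_names:
        for entry in genes_per_chrom[chrom]:
            entry["chromosome"] = chrom
            plans.append(entry)
    for i, p in enumerate(plans):
        p["gene_id"] = f"g{i + 1:03d}"
        p["strand"] = "+" if rng.random() < 0.5 else "-"

    by_id = {p["gene_id"]: p for p in plans}
    gene_ids = [p["gene_id"] for p in plans]
    n_genes = len(gene_ids)

    # ---- intron genes ----------------------------------------------------
    for gid in rng.choice(gene_ids, size=cfg.n_intron_genes, replace=False):
        by_id[str(gid)]["has_intron"] = True

    # ---- duplication pairs ----------------------------------------------
    adjacent_inparalogs: list[tuple[str, str]] = []
    for chrom in chrom_names:
        entries = genes_per_chrom[chrom]
        for a, b in zip(entries, entries[1:]):
            if a["group_idx"] == b["group_idx"]:
                adjacent_inparalogs.append((a["gene_id"], b["gene_id"]))
    tandem_specs = [d for d in cfg.duplication_pairs if d[2] == "tandem"]
    segmental_specs = [d for d in cfg.duplication_pairs if d[2] == "segmental"]
    dup_pairs: list[dict] = []
    taken: set[str] = set()
    # disjoint adjacent pairs only: a shared gene would chain two pairs into
    # an unplanted third similarity relation
    usable = []
    for a, b in adjacent_inparalogs:
        if a in taken or b in taken:
            continue
        usable.append((a, b))
        taken.update((a, b))
    taken = set()
    if len(tandem_specs) > len(usable):
        raise ValueError("not enough inparalog pairs for tandem duplications")
    for (syn, nonsyn, kind), (ga, gb) in zip(tandem_specs, usable):
        dup_pairs.append(
            {"source": ga, "target": gb, "kind": kind, "syn": syn, "nonsyn": nonsyn}
        )
        taken.update((ga, gb))
    free = [g for g in gene_ids if g not in taken]
    free_idx = 0
    for syn, nonsyn, kind in segmental_specs:
        ga = free[free_idx]
        gb = next(
            g
            for g in free[free_idx + 1 :]
            if by_id[g]["chromosome"] != by_id[ga]["chromosome"]
            and g not in taken
        )
        free_idx += 1
        while free_idx < len(free) and free[free_idx] in taken | {gb}:
            free_idx += 1
        dup_pairs.append(
            {"source": ga, "target": gb, "kind": kind, "syn": syn, "nonsyn": nonsyn}
        )
        taken.update((ga, gb))
    dup_target_of = {d["target"]: d for d in dup_pairs}

    # ---- motif variants --------------------------------------------------
    pool: list[tuple[str, str]] = []
    for core, variant, count in cfg.motif_census:
        pool.extend([(core, variant)] * count)
    # pair partners share a variant: consume two identical entries per pair
    for d in dup_pairs:
        for core, variant, _ in cfg.motif_census:
            if pool.count((core, variant)) >= 2:
                pool.remove((core, variant))
                pool.remove((core, variant))
                by_id[d["source"]]["motif"] = (core, variant)
                by_id[d["target"]]["motif"] = (core, variant)
                break
    rest = [g for g in gene_ids if "motif" not in by_id[g]]
    shuffled = [pool[i] for i in rng.permutation(len(pool))]
    for gid, motif in zip(rest, shuffled):
        by_id[gid]["motif"] = motif

    # ---- SSR plan --------------------------------------------------------
    ssr_units = {
        "p1": ("A", "T"),
        "p2": ("AG", "CT", "TA"),
        "p3": ("CAG", "AAG", "CGG", "GCA", "TCA"),
        "p4": ("ACAT", "AGGC"),
        "p5": ("AACCT",),
        "p6": ("ACGTAG",),
    }
    ssr_jobs: list[tuple[str, int]] = []  # (motif, count)
    for klass in sorted(cfg.ssr_class_counts):
        units = ssr_units[klass]
        k = int(klass[1])
        thr = cfg.ssr_thresholds[k - 1]
        for i in range(cfg.ssr_class_counts[klass]):
            unit = units[i % len(units)]
            ssr_jobs.append((unit, thr + int(rng.integers(0, 3))))
    ssr_jobs = [ssr_jobs[i] for i in rng.permutation(len(ssr_jobs))]
    ssr_gene_ids = [
        str(g)
        for g in rng.choice(gene_ids, size=cfg.n_ssr_genes, replace=False)
    ] if ssr_jobs else []
    two_ssr = ssr_gene_ids[: cfg.n_two_ssr_genes]
    compound_genes = set(two_ssr[: cfg.n_compound_genes])
    job_iter = iter(ssr_jobs)
    for gid in ssr_gene_ids:
        jobs = [next(job_iter)]
        if gid in two_ssr:
            jobs.append(next(job_iter))
        gap = cfg.compound_gap if gid in compound_genes else cfg.simple_gap
        offset = 5
        plant = []
        for unit, count in jobs:
            span = len(unit) * count
            plant.append({"motif": unit, "count": count, "utr3_offset": offset})
            offset += span + gap
        if offset - gap + 1 > cfg.utr3_len:
            raise ValueError("utr3_len too small for the planted SSRs")
        by_id[gid]["ssr_plant"] = plant

    # ---- cis plan --------------------------------------------------------
    for element, n_promoters in cfg.cis_plantings.items():
        if element not in catalog.entries:
            raise ValueError(f"unknown catalog element {element!r}")
        chosen = rng.choice(gene_ids, size=n_promoters, replace=False)
        for gid in chosen:
            by_id[str(gid)].setdefault("cis_plant", []).append(element)

    # ---- per-gene sequence construction ----------------------------------
    forbid_cis = lambda s: _cis_spans(s, catalog)
    forbid_ssr = lambda s: _ssr_spans(s, cfg.ssr_thresholds)

    order = [g for g in gene_ids if g not in dup_target_of] + [
        g for g in gene_ids if g in dup_target_of
    ]
    built: dict[str, dict] = {}
    for gid in order:
        plan = by_id[gid]
        core, variant = plan["motif"]
        if gid in dup_target_of:
            d = dup_target_of[gid]
            src = built[d["source"]]
            motif_codons = range(src["motif_offset"], src["motif_offset"] + 10)
            cds = _mutate_cds(
                rng, src["cds"], d["syn"], d["nonsyn"], motif_codons,
                cfg.ssr_thresholds,
            )
            protein = str(Seq(cds[:-3]).translate())
            hits = scan_vq(protein)
            if len(hits) != 1 or hits[0].offset != src["motif_offset"]:
                raise RuntimeError("mutation disturbed the planted motif")
            motif_offset = src["motif_offset"]
        else:
            lo, hi = cfg.protein_len_range
            length = int(
                np.clip(
                    round(rng.normal(cfg.protein_len_mean, cfg.protein_len_sd)),
                    lo,
                    hi,
                )
            )
            motif_offset = int(rng.integers(5, length - 14))
            protein, _ = _random_protein(rng, length, core, variant, motif_offset)
            cds = _encode_cds(rng, protein, cfg.ssr_thresholds)
        built[gid] = {
            "cds": cds,
            "protein": protein,
            "motif_offset": motif_offset,
        }

    # promoters, UTRs, introns + verified plantings
    manifest_cis: dict[str, list[dict]] = {}
    manifest_ssr: dict[str, list[dict]] = {}
    for gid in gene_ids:
        plan = by_id[gid]
        rec = built[gid]
        cds = rec["cds"]

        # promoter window: cleaned background + planted elements
        expected_cis: list[dict] = []
        for attempt in range(50):
            upstream = _clean_nt(rng, up_len, [forbid_cis])
            utr5 = _clean_nt(rng, cfg.utr5_len, [forbid_cis, forbid_ssr])
            expected_cis = []
            window = list(upstream)
            used_spans: list[tuple[int, int]] = []
            ok = True
            for element in plan.get("cis_plant", []):
                consensus = catalog.entries[element][0]
                for _ in range(100):
                    pos = int(rng.integers(0, up_len - len(consensus)))
                    span = (pos - 10, pos + len(consensus) + 9)
                    if all(
                        span[1] < s or span[0] > e for s, e in used_spans
                    ):
                        break
                else:
                    ok = False
                    break
                used_spans.append(span)
                window[pos : pos + len(consensus)] = list(consensus)
                expected_cis.extend(
                    _expected_cis_for_instance(consensus, pos + 1, catalog)
                )
            if not ok:
                continue
            promoter = "".join(window) + utr5
            found = [
                {"element": h.element, "strand": h.strand, "offset": h.offset}
                for h in scan_elements(promoter, catalog)
            ]
            key = lambda r: (r["offset"], r["element"], r["strand"])
            if sorted(found, key=key) == sorted(expected_cis, key=key):
                break
        else:
            raise RuntimeError(f"promoter construction failed for {gid}")
        rec["upstream"], rec["utr5"] = promoter[: up_len], utr5
        manifest_cis[gid] = sorted(expected_cis, key=key)

        # intron + 3' UTR with planted SSRs, verified on the final span
        n_codons = len(cds) // 3
        split = 3 * (n_codons // 2)
        has_intron = plan.get("has_intron", False)
        planted = plan.get("ssr_plant", [])
        for attempt in range(50):
            intron = ""
            if has_intron:
                ilen = int(rng.integers(*cfg.intron_len_range))
                intron = "GT" + _clean_nt(rng, ilen - 4, [forbid_ssr]) + "AG"
            utr3 = list(_clean_nt(rng, cfg.utr3_len, [forbid_ssr]))
            for p in planted:
                unit, count, off = p["motif"], p["count"], p["utr3_offset"]
                tract = unit * count
                utr3[off : off + len(tract)] = list(tract)
                # guard bases: block partial-period extension on both sides
                k = len(unit)
                left = unit[k - 1]
                utr3[off - 1] = "C" if left != "C" else "G"
                right = unit[0]
                pos_r = off + len(tract)
                if pos_r < len(utr3):
                    utr3[pos_r] = "C" if right != "C" else "G"
            utr3 = "".join(utr3)
            if has_intron:
                span = rec["utr5"] + cds[:split] + intron + cds[split:] + utr3
            else:
                span = rec["utr5"] + cds + utr3
            forward_span = span if plan["strand"] == "+" else revcomp(span)
            expected_ssr = []
            for p in planted:
                off0 = len(span) - len(utr3) + p["utr3_offset"]  # 0-based
                tract_len = len(p["motif"]) * p["count"]
                if plan["strand"] == "+":
                    start = off0 + 1
                    motif = p["motif"]
                else:
                    start = len(span) - (off0 + tract_len) + 1
                    motif = revcomp(p["motif"])
                expected_ssr.append(
                    {
                        "motif": motif,
                        "count": p["count"],
                        "start": start,
                        "end": start + tract_len - 1,
                    }
                )
            found = [
                {
                    "motif": r.motif,
                    "count": r.repeat_count,
                    "start": r.start,
                    "end": r.end,
                }
                for r in find_ssrs(forward_span, cfg.ssr_thresholds)
            ]
            skey = lambda r: r["start"]
            if sorted(found, key=skey) == sorted(expected_ssr, key=skey):
                break
        else:
            raise RuntimeError(f"gene body construction failed for {gid}")
        rec["intron"], rec["utr3"], rec["split"] = intron, utr3, split
        rec["span"] = span
        manifest_ssr[gid] = sorted(expected_ssr, key=lambda r: r["start"])

    # ---- chromosome assembly --------------------------------------------
    chromosomes: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    manifest_genes: list[dict] = []
    for chrom in chrom_names:
        parts: list[str] = []
        pos = 0  # 0-based length so far
        for entry in genes_per_chrom[chrom]:
            gid = entry["gene_id"]
            plan = by_id[gid]
            rec = built[gid]
            spacer = int(rng.integers(*cfg.spacer_range))
            parts.append("".join(_rand_nt(rng, spacer)))
            pos += spacer
            cassette = rec["upstream"] + rec["span"]
            span_len = len(rec["span"])
            # span-relative (0-based, cassette orientation) feature intervals
            cds = rec["cds"]
            u5, u3 = cfg.utr5_len, len(rec["utr3"])
            if rec["intron"]:
                split, ilen = rec["split"], len(rec["intron"])
                exons_rel = [
                    (0, u5 + split - 1),
                    (u5 + split + ilen, span_len - 1),
                ]
                cds_rel = [
                    (u5, u5 + split - 1),
                    (u5 + split + ilen, u5 + split + ilen + (len(cds) - split) - 1),
                ]
            else:
                exons_rel = [(0, span_len - 1)]
                cds_rel = [(u5, u5 + len(cds) - 1)]
            if plan["strand"] == "+":
                parts.append(cassette)
                gene_start = pos + up_len + 1
                to_chrom = lambda a, b: (gene_start + a, gene_start + b)
            else:
                parts.append(revcomp(cassette))
                gene_start = pos + 1
                base = pos + len(cassette) - up_len  # 1-based end of span
                to_chrom = lambda a, b: (base - b, base - a)
            exons = sorted(to_chrom(a, b) for a, b in exons_rel)
            cds_iv = sorted(to_chrom(a, b) for a, b in cds_rel)
            g_start = min(s for s, _ in exons)
            g_end = max(e for _, e in exons)
            gene_models.append(
                GeneModel(
                    gene_id=gid,
                    chromosome=chrom,
                    strand=plan["strand"],
                    start=g_start,
                    end=g_end,
                    exons=exons,
                    cds_intervals=cds_iv,
                )
            )
            manifest_genes.append(
                {
                    "gene_id": gid,
                    "chromosome": chrom,
                    "strand": plan["strand"],
                    "start": g_start,
                    "end": g_end,
                    "group": f"group{plan['group_idx'] + 1:02d}",
                    "category": plan["category"],
                    "intron_count": 1 if rec["intron"] else 0,
                    "motif_offset": rec["motif_offset"],
                    "core": plan["motif"][0],
                    "variant": plan["motif"][1],
                }
            )
            pos += len(cassette)
        if pos > cfg.chromosome_length:
            raise ValueError(
                f"chromosome {chrom}: {pos} bp of cassettes exceed "
                f"chromosome_length={cfg.chromosome_length}"
            )
        parts.append("".join(_rand_nt(rng, cfg.chromosome_length - pos)))
        chromosomes[chrom] = "".join(parts)

    # ---- homoeolog groups -------------------------------------------------
    group_members: dict[int, list[str]] = {}
    for p in plans:
        group_members.setdefault(p["group_idx"], []).append(p["gene_id"])
    groups: list[HomoeologGroup] = []
    manifest_groups: list[dict] = []
    for gidx, (category, counts) in enumerate(specs):
        members = group_members[gidx]
        groups.append(HomoeologGroup(gidx + 1, members, counts))
        manifest_groups.append(
            {
                "group": f"group{gidx + 1:02d}",
                "members": members,
                "counts": list(counts),
                "category": category,
            }
        )

    # ---- expression -------------------------------------------------------
    tissue_cols: list[str] = []
    col_class: dict[str, str] = {}
    for klass, n_cols in cfg.tissue_classes.items():
        for i in range(1, n_cols + 1):
            col = f"{klass}_{i}"
            tissue_cols.append(col)
            col_class[col] = klass
    group_names = [f"group{g + 1:02d}" for g in range(len(specs))]
    expressed = sorted(
        str(g)
        for g in rng.choice(
            group_names, size=cfg.n_expressed_groups, replace=False
        )
    )
    mu, sigma = cfg.tpm_lognormal
    tpm = pd.DataFrame(0.0, index=gene_ids, columns=tissue_cols)
    for gidx, members in group_members.items():
        gname = f"group{gidx + 1:02d}"
        if gname in expressed:
            hot = tissue_cols[int(rng.integers(0, len(tissue_cols)))]
            for m in members:
                for col in tissue_cols:
                    if col == hot:
                        tpm.loc[m, col] = rng.uniform(1.5, 30.0)
                    elif rng.random() < cfg.tpm_zero_inflation:
                        tpm.loc[m, col] = rng.uniform(0.0, 0.5)
                    else:
                        tpm.loc[m, col] = float(np.exp(rng.normal(mu, sigma)))
        else:
            for m in members:
                for col in tissue_cols:
                    tpm.loc[m, col] = rng.uniform(0.0, 0.8)
    tpm = tpm.round(3)
    group_means = pd.DataFrame(
        {g: tpm.loc[group_members[i]].mean(axis=0)
         for i, g in ((gi, f"group{gi + 1:02d}") for gi in group_members)}
    ).T
    detected = sorted(group_means.index[(group_means >= 1.0).any(axis=1)])

    # ---- qPCR -------------------------------------------------------------
    qpcr_groups = sorted(
        str(g)
        for g in rng.choice(expressed, size=cfg.qpcr_n_groups, replace=False)
    )
    qpcr_true: list[dict] = []
    ct_rows: list[dict] = []
    for gname in qpcr_groups:
        for cond in cfg.qpcr_conditions:
            base_dct = rng.uniform(2.0, 6.0)
            for tp in cfg.qpcr_timepoints:
                log2rq = 0.0 if tp == cfg.qpcr_timepoints[0] else float(
                    rng.uniform(-3.0, 5.0)
                )
                qpcr_true.append(
                    {
                        "group": gname,
                        "condition": cond,
                        "timepoint": tp,
                        "log2_rq": log2rq,
                    }
                )
                for rep in range(1, cfg.qpcr_replicates + 1):
                    ref = rng.uniform(18.0, 20.0)
                    ct_rows.append(
                        {
                            "gene": gname,
                            "condition": cond,
                            "timepoint": tp,
                            "replicate": rep,
                            "ct_target": round(
                                ref
                                + base_dct
                                - log2rq
                                + rng.normal(0.0, cfg.ct_noise_sd),
                                3,
                            ),
                            "ct_reference": round(
                                ref + rng.normal(0.0, cfg.ct_noise_sd), 3
                            ),
                        }
                    )

    # ---- write files ------------------------------------------------------
    files = {
        "genome": str(out / "genome.fasta"),
        "gff3": str(out / "annotation.gff3"),
        "cds": str(out / "cds.fasta"),
        "proteins": str(out / "proteins.fasta"),
        "groups": str(out / "groups.tsv"),
        "tpm": str(out / "tpm.tsv"),
        "tissues": str(out / "tissues.tsv"),
        "qpcr": str(out / "qpcr_ct.tsv"),
        "manifest": str(out / "manifest.jsonl"),
    }
    write_fasta(chromosomes, files["genome"])
    write_gff3(gene_models, files["gff3"])
    write_fasta({g: built[g]["cds"] for g in gene_ids}, files["cds"])
    write_fasta({g: built[g]["protein"] for g in gene_ids}, files["proteins"])
    pd.DataFrame(
        [
            {"group_id": f"group{gidx + 1:02d}", "gene_id": gid}
            for gidx in sorted(group_members)
            for gid in group_members[gidx]
        ]
    ).to_csv(files["groups"], sep="\t", index=False)
    tpm.rename_axis("gene_id").to_csv(
        files["tpm"], sep="\t", float_format="%.3f"
    )
    pd.DataFrame(
        [{"tissue": c, "organ_class": col_class[c]} for c in tissue_cols]
    ).to_csv(files["tissues"], sep="\t", index=False)
    pd.DataFrame(ct_rows).to_csv(files["qpcr"], sep="\t", index=False)

    manifest = Manifest(
        seed=cfg.seed,
        n_genes=n_genes,
        genes=manifest_genes,
        groups=manifest_groups,
        dup_pairs=dup_pairs,
        ssrs=manifest_ssr,
        cis=manifest_cis,
        expressed_groups=detected,
        qpcr_true=qpcr_true,
        files=files,
    )
    manifest.write_jsonl(files["manifest"])
    return manifest
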