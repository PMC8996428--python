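"""Pipeline orchestration: run every survey stage and merge the results into
one per-gene table plus family-level summary blocks.

The pipeline is deterministic for a given input set; every stage writes its
own TSV under the output directory and logs stage name, input/output counts
and elapsed time to stderr.
"""

from __future__ import annotations

import logging
import time
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import annotation as annot
from . import cis_elements as cis
from . import duplication as dup
from . import expression as expr
from . import homoeolog as homo
from . import protparam
from . import seqio
from . import ssr as ssr_mod
from . import vq_motif

__all__ = ["SurveyConfig", "SurveyReport", "run_pipeline"]

log = logging.getLogger("vqsurvey")


@dataclass
class SurveyConfig:
    """Inputs and thresholds of a full survey run (defaults as published)."""

    genome: str
    gff3: str
    groups: str
    cds: str | None = None  # optional cross-check FASTA
    proteins: str | None = None  # optional cross-check FASTA
    tpm: str | None = None
    tissues: str | None = None
    qpcr: str | None = None
    catalog: str | None = None  # cis-element catalog TSV; None = built-in
    out_dir: str = "survey_out"
    promoter_len: int = 1500
    cov_min: float = 0.75
    id_min: float = 0.75
    tandem_max_intervening: int = 5
    tandem_max_distance: int = 200_000
    ssr_thresholds: tuple[int, ...] = (10, 6, 5, 5, 5, 5)
    ssr_max_interruption: int = 100
    tpm_threshold: float = 1.0
    control_timepoint: str = "0h"
    name_prefix: str = "TaVQ"

    @classmethod
    def from_toml(cls, path: str | Path) -> "SurveyConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ssr_thresholds" in data:
            data["ssr_thresholds"] = tuple(data["ssr_thresholds"])
        return cls(**data)


@dataclass
class SurveyReport:
    per_gene: pd.DataFrame
    summaries: dict[str, Any] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def _check_ids(name: str, expected: set[str], got: set[str]) -> None:
    if expected != got:
        extra = sorted(got - expected)
        missing = sorted(expected - got)
        raise ValueError(
            f"id mismatch in {name}: missing={missing[:10]} extra={extra[:10]}"
        )


def _read_groups(path: str) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.group_id), []).append(str(row.gene_id))
    return out


def run_pipeline(config: SurveyConfig) -> SurveyReport:
    """Run every stage and return the consolidated report.

    Raises on missing inputs or id mismatches between files; each stage's
    TSV is written under ``config.out_dir``.
    """
    for attr in ("genome", "gff3", "groups"):
        p = getattr(config, attr)
        if not Path(p).exists():
            raise FileNotFoundError(f"{attr} input not found: {p}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    bundle = _stage("load")(seqio.load_genome)(config.genome, config.gff3)
    gene_ids = [g.gene_id for g in bundle.genes]
    log.info("loaded %d chromosomes, %d genes", len(bundle.chromosomes), len(gene_ids))

    proteins = {g.gene_id: g.protein_seq for g in bundle.genes if g.protein_seq}
    cds = {g.gene_id: g.cds_seq for g in bundle.genes if g.cds_seq}
    if config.proteins:
        ref = seqio.read_fasta(config.proteins)
        _check_ids("protein FASTA vs annotation", set(proteins), set(ref))
        bad = [g for g in sorted(ref) if ref[g] != proteins[g]]
        if bad:
            raise ValueError(f"derived proteins differ from FASTA for: {bad[:10]}")
    if config.cds:
        ref = seqio.read_fasta(config.cds)
        _check_ids("CDS FASTA vs annotation", set(cds), set(ref))

    groups_map = _read_groups(config.groups)
    _check_ids(
        "groups.tsv vs annotation",
        set(gene_ids),
        {g for ms in groups_map.values() for g in ms},
    )

    # --- motifs -----------------------------------------------------------
    hits = _stage("vqscan")(vq_motif.scan_proteins)(proteins)
    verdicts, variant_census = vq_motif.classify_family(hits)
    hits_df = pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "offset": h.offset,
                "decamer": h.decamer,
                "core": h.core,
                "variant": h.variant,
                "canonical": h.canonical,
            }
            for hs in hits.values()
            for h in hs
        ]
    )
    hits_df.to_csv(out_dir / "vq_hits.tsv", sep="\t", index=False)

    # --- properties -------------------------------------------------------
    props = _stage("protparam")(
        lambda: {g: protparam.compute_properties(s) for g, s in proteins.items()}
    )()
    props_df = pd.DataFrame(
        [
            {
                "gene_id": g,
                "length": p.length,
                "mw": round(p.mw, 2),
                "pi": round(p.pi, 2),
                "instability": round(p.instability, 2),
                "aliphatic": round(p.aliphatic, 2),
                "gravy": round(p.gravy, 3),
                "is_basic": p.is_basic,
                "is_unstable": p.is_unstable,
                "is_thermostable": p.is_thermostable,
                "is_hydrophilic": p.is_hydrophilic,
            }
            for g, p in props.items()
        ]
    )
    props_df.to_csv(out_dir / "protparam.tsv", sep="\t", index=False)

    # --- structure & distribution ----------------------------------------
    structure = _stage("structure")(annot.intron_counts)(bundle.genes)
    chrom_dist = annot.chromosome_distribution(
        bundle.genes, bundle.chromosomes.keys()
    )

    # --- homoeolog groups --------------------------------------------------
    chrom_of = {g.gene_id: g.chromosome for g in bundle.genes}
    hgroups = [
        homo.group_from_members(i + 1, [(gid, chrom_of[gid]) for gid in members])
        for i, (_, members) in enumerate(sorted(groups_map.items()))
    ]
    triads = _stage("triads")(homo.summarize_triads)(hgroups)
    names = vq_motif.assign_family_names(
        bundle.genes, hgroups, prefix=config.name_prefix
    )
    group_of = {
        gid: group_id
        for group_id, members in groups_map.items()
        for gid in members
    }
    triads_df = pd.DataFrame(
        {
            "category": list(triads.n_groups),
            "n_groups": [triads.n_groups[c] for c in triads.n_groups],
            "n_genes": [triads.n_genes[c] for c in triads.n_groups],
            "pct_genes": [triads.pct_genes[c] for c in triads.n_groups],
            "reference_pct": [
                triads.reference_pct.get(c) for c in triads.n_groups
            ],
        }
    )
    triads_df.to_csv(out_dir / "triads.tsv", sep="\t", index=False)

    # --- duplication -------------------------------------------------------
    pairs = _stage("duplication")(dup.find_duplicated_pairs)(
        cds,
        bundle.genes,
        cov_min=config.cov_min,
        id_min=config.id_min,
        max_intervening=config.tandem_max_intervening,
        max_distance=config.tandem_max_distance,
    )
    pairs_df = pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "coverage": round(p.coverage, 4),
                "identity": round(p.identity, 4),
                "kind": p.kind,
                "ka": None if p.ka is None else round(p.ka, 6),
                "ks": None if p.ks is None else round(p.ks, 6),
                "ratio": None if p.ratio is None else round(p.ratio, 4),
                "selection": p.selection,
            }
            for p in pairs
        ]
    )
    pairs_df.to_csv(out_dir / "duplications.tsv", sep="\t", index=False)

    # --- SSRs ---------------------------------------------------------------
    def _ssr_stage():
        records = []
        for gid in gene_ids:
            seq = seqio.gene_span_sequence(bundle, gid)
            simple = ssr_mod.find_ssrs(seq, config.ssr_thresholds, seq_id=gid)
            records.extend(
                ssr_mod.merge_compound(simple, config.ssr_max_interruption)
            )
        return records

    ssr_records = _stage("ssr")(_ssr_stage)()
    ssr_simple = [
        c
        for r in ssr_records
        for c in (r.components if r.ssr_type == "compound" else [r])
    ]
    ssr_census = ssr_mod.ssr_census(ssr_records, len(gene_ids))
    pd.DataFrame(
        [
            {
                "gene_id": r.seq_id,
                "ssr_type": r.ssr_type,
                "motif": r.motif,
                "repeat_count": r.repeat_count,
                "start": r.start,
                "end": r.end,
            }
            for r in ssr_records
        ]
    ).to_csv(out_dir / "ssrs.tsv", sep="\t", index=False)

    # --- promoters & cis-elements -------------------------------------------
    catalog = (
        cis.load_catalog(config.catalog) if config.catalog else cis.default_catalog()
    )
    promoters = {
        gid: seqio.extract_promoter(bundle, gid, config.promoter_len)
        for gid in gene_ids
    }
    cis_hits = _stage("cis")(cis.scan_promoters)(promoters, catalog)
    cis_counts, cis_coverage = cis.element_count_matrix(
        cis_hits, gene_ids, catalog
    )
    cis_counts.rename_axis("gene_id").to_csv(out_dir / "cis_counts.tsv", sep="\t")

    # --- expression ----------------------------------------------------------
    tpm_df = flags_anywhere = group_flags = None
    if config.tpm:
        tpm_df = pd.read_csv(config.tpm, sep="\t", index_col=0)
        _check_ids("TPM matrix vs annotation", set(gene_ids), set(tpm_df.index))
        col_classes = None
        if config.tissues:
            tissues = pd.read_csv(config.tissues, sep="\t")
            col_classes = dict(
                zip(tissues["tissue"].astype(str), tissues["organ_class"])
            )
        group_tpm = expr.average_homoeologs(tpm_df, groups_map)
        _, flags_anywhere, _ = expr.expression_flags(
            group_tpm, config.tpm_threshold, col_classes
        )
        group_flags = flags_anywhere
        expr.heatmap_values(group_tpm).round(4).rename_axis("group_id").to_csv(
            out_dir / "tpm_log2.tsv", sep="\t"
        )
    rq_df = None
    if config.qpcr:
        qpcr_table = pd.read_csv(config.qpcr, sep="\t")
        rq_df = _stage("ddct")(expr.ddct)(
            qpcr_table, control_timepoint=config.control_timepoint
        )
        rq_df.to_csv(out_dir / "qpcr_rq.tsv", sep="\t", index=False)

    # --- per-gene table -------------------------------------------------------
    partners: dict[str, list[str]] = {}
    for p in pairs:
        partners.setdefault(p.gene_a, []).append(p.gene_b)
        partners.setdefault(p.gene_b, []).append(p.gene_a)
    ssr_count = {}
    for r in ssr_simple:
        ssr_count[r.seq_id] = ssr_count.get(r.seq_id, 0) + 1
    rows = []
    for g in bundle.genes:
        gid = g.gene_id
        v = verdicts[gid]
        p = props[gid]
        row = {
            "gene_id": gid,
            "name": names[gid],
            "chromosome": g.chromosome,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "is_vq": v.is_vq,
            "motif_variant": v.best_hit.variant if v.best_hit else None,
            "motif_core": v.best_hit.core if v.best_hit else None,
            "length": p.length,
            "mw": round(p.mw, 2),
            "pi": round(p.pi, 2),
            "instability": round(p.instability, 2),
            "aliphatic": round(p.aliphatic, 2),
            "gravy": round(p.gravy, 3),
            "intron_count": structure.per_gene[gid],
            "group_id": group_of[gid],
            "group_category": next(
                hg.category for hg in hgroups
                if gid in hg.members
            ),
            "dup_partners": ",".join(sorted(partners.get(gid, []))),
            "n_ssrs": ssr_count.get(gid, 0),
            "n_wbox": int(cis_counts.loc[gid, "W-box"])
            if "W-box" in cis_counts.columns
            else 0,
        }
        if group_flags is not None:
            row["group_expressed"] = bool(group_flags[group_of[gid]])
        rows.append(row)
    per_gene = pd.DataFrame(rows)
    per_gene.to_csv(out_dir / "survey_report.tsv", sep="\t", index=False)

    summaries: dict[str, Any] = {
        "n_genes": len(gene_ids),
        "triads": triads,
        "variant_census": dict(variant_census),
        "pct_intronless": structure.pct_intronless,
        "chromosome_distribution": chrom_dist,
        "ssr_census": ssr_census,
        "cis_coverage": cis_coverage.to_dict(),
        "n_duplicated_pairs": len(pairs),
    }
    if group_flags is not None:
        summaries["n_groups_expressed"] = int(group_flags.sum())
        summaries["n_groups"] = int(len(group_flags))
    tables = {
        "vq_hits": hits_df,
        "protparam": props_df,
        "triads": triads_df,
        "duplications": pairs_df,
        "cis_counts": cis_counts,
    }
    if rq_df is not None:
        tables["qpcr_rq"] = rq_df
    if tpm_df is not None:
        tables["tpm"] = tpm_df
    log.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return SurveyReport(per_gene=per_gene, summaries=summaries, tables=tables)
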