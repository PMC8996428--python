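# vqsurvey

A genome-wide gene-family survey pipeline for polyploid plant genomes, built
around the VQ motif-containing transcriptional cofactors of hexaploid bread
wheat (*Triticum aestivum*, subgenomes A/B/D). It is aimed at plant
comparative genomicists who run the standard family-characterization
workflow — identify members, describe their proteins and gene structures,
classify homoeolog retention, date duplications, mine microsatellites, scan
promoters, build a tree, and summarize expression — and want every step
reproducible, scriptable and tested instead of stitched together from web
servers.

## What it computes

* **Motif identification and typing.** VQ proteins carry the conserved
  decapeptide `FxxhVQxhTG` (x = any residue, h = hydrophobic). A
  deterministic scanner reports every window matching
  `F,x,x,x,V,[QH],x,h,T,G`, plus relaxed windows whose terminal dipeptide is
  not `TG` (capturing rare variants such as `VMA`), and types each hit by its
  core (`VQ`/`VH`) and terminal tripeptide (`LTG`, `FTG`, `ITG`, `VTG`, ...).
  Members are named by chromosomal location (`TaVQ<group>-<chromosome>`,
  inparalogs suffixed `-2B1`, `-2B2`, ...).
* **Protein descriptors.** Length, average MW, theoretical pI (bisection of
  the Henderson–Hasselbalch net charge, EMBOSS pKa set), Guruprasad
  instability index, Ikai aliphatic index and Kyte–Doolittle GRAVY, with the
  usual categorical calls (basic pI > 7, unstable II > 40, thermostable
  AI ≥ 65, hydrophilic GRAVY < 0).
* **Homoeolog triads.** Each family group's (nA:nB:nD) retention pattern is
  classified as 1:1:1 triad, n:1:1 duplication, 1:1:0 loss, orphan, or other,
  and summarized against genome-wide reference percentages.
* **Duplications and selection.** All-vs-all protein-guided global codon
  alignments (Needleman–Wunsch, BLOSUM62, gap open 10 / extend 0.5); a pair
  is duplicated when alignable coverage > 75 % of the longer CDS *and*
  nucleotide identity > 75 %; tandem vs segmental by chromosome and distance;
  Ka/Ks by the Nei–Gojobori (1986) method — synonymous site fractions per
  codon position, differences averaged over minimal substitution pathways
  avoiding stops, Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p) — with
  Ka/Ks > 1 read as positive, < 1 as purifying selection.
* **SSRs.** MISA-equivalent perfect microsatellites (unit 1–6 nt; thresholds
  10, 6, 5, 5, 5, 5 repeats), smallest-unit reporting, compound SSRs merged
  at ≤ 100 bp interruption.
* **Promoter cis-elements.** 1.5 kb windows upstream of the translation
  start scanned on both strands against an IUPAC consensus catalog (W-box
  `TTGACC/TTGACT`, ABRE, the CGTCA/TGACG MeJA pair, MYB/MYC, DRE, and the
  other elements conventionally reported; fully overridable via TSV).
* **Phylogeny.** Pairwise-deletion p-distance (optional Poisson correction),
  Saitou–Nei neighbor joining, column-resampling bootstrap support, and
  subgroup assignment of unlabeled leaves from labeled reference leaves.
* **Expression.** Homoeolog-averaged TPM, `tpm < 1` treated as unexpressed,
  log2(TPM + 1) heatmap values, and qPCR relative quantification by the
  2^−ΔΔCt method against a per-(gene, condition) control timepoint.

Because the real wheat genome is far too large for a test suite, the package
ships a first-class synthetic-data generator: a seeded toy hexaploid genome
(21 chromosomes) with planted motifs, homoeolog groups matching the published
family census, duplicate pairs carrying exact synonymous/nonsynonymous codon
changes, SSRs, promoter elements and expression tables — all recorded in a
ground-truth manifest that the test suite checks the pipeline against.

## Worked example

```bash
vqsurvey simulate --seed 42 --out demo
vqsurvey report --config demo/survey.toml   # paths + thresholds, TOML
```

The second command prints `113 genes -> demo/out/survey_report.tsv` and
writes one TSV per stage. The per-gene table starts:

```
gene_id  name      chromosome  start  end   strand  is_vq  motif_variant
g001     TaVQ1-1A  1A          1846   2430  +       True   LTG
g002     TaVQ2-1A  1A          4246   5055  +       True   LTG
```

and the homoeolog-retention summary (`demo/out/triads.tsv`) reproduces the
family census the generator planted — 75 of 113 genes (66.4 %) in 1:1:1
triads, against 35.8 % genome-wide:

```
category     n_groups  n_genes  pct_genes  reference_pct
TRIAD_1_1_1  25        75       66.4       35.8
DUP_n_1_1    4         17       15.0       5.7
LOSS_1_1_0   8         16       14.2       13.2
OTHER        1         3        2.7        8.0
ORPHAN       2         2        1.8        37.1
```

`demo/out/duplications.tsv` lists the detected duplicate pairs with their
Ka/Ks and selection call; e.g. a planted segmental pair with 2 synonymous and
3 nonsynonymous changes comes back as

```
gene_a  gene_b  coverage  identity  kind       ka        ks        ratio   selection
g001    g007    1.0       0.9823    segmental  0.013699  0.033525  0.4086  purifying
```

Every stage is also available standalone (`vqsurvey vqscan`, `protparam`,
`structure`, `triads`, `dup`, `ssr`, `cis`, `tree`, `expr`, `extract`); see
`vqsurvey --help`.

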