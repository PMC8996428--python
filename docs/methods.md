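# Methods

This note records the models and conventions behind each stage, the defaults
and why they were chosen, what the synthetic data does and does not emulate,
and the numerical corner cases.

## Coordinates and promoters

All genomic intervals are 1-based inclusive (the GFF3 dialect). A gene's
representative transcript is the mRNA with the longest total CDS; exon-based
intron counts therefore follow the transcript (GSDS-style) convention, not
CDS segments. Promoters are anchored at the **translation start**: for a +
strand gene the window is `[cds_start − L, cds_start − 1]`, for a − strand
gene the reverse complement of `[cds_end + 1, cds_end + L]`, with L = 1500 bp
by default. Windows are truncated (not padded) at chromosome ends, so a
promoter may be shorter than L near a scaffold edge. `N` bases are permitted
anywhere and never match a motif, SSR unit, or cis-element consensus.

## VQ motif scan

The scanner is positional, not probabilistic: a window matches if position 1
is F, 5 is V, 6 is Q or H, and 8 is in the hydrophobic set
{A, V, L, I, M, F, W, Y, C}; a canonical hit additionally ends in TG.
Windows matching the first eight positions but not ending in TG are reported
as non-canonical — this is what recovers terminal variants like VMA without
opening the ending entirely (the stricter 8-position requirement keeps the
false-positive rate of the relaxed class low; on a uniform random protein the
relaxed pattern matches ~1 in 9000 windows). The hydrophobic set is
configurable; the default covers every terminal-variant first residue seen in
plant VQ families (L, F, I, V) plus the remaining standard hydrophobics.
This deterministic scan stands in for a profile-HMM search: it needs no
external binaries or profile downloads and targets the same biological
pattern, at the cost of ignoring position-specific scores outside the
constrained positions.

## Protein descriptors

MW (average masses + one water), GRAVY and the Guruprasad instability index
are delegated to Biopython's ProtParam tables. The aliphatic index is Ikai's
X(Ala) + 2.9·X(Val) + 3.9·(X(Ile)+X(Leu)) on mole percents. The pI solves
net charge = 0 by bisection on pH ∈ [0, 14] to |charge| < 1e-4 (≤ 60
iterations; the charge is strictly decreasing in pH so bisection cannot
fail). The pKa set is the EMBOSS default (N-term 8.6, C-term 3.6, K 10.8,
R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1) because those values are
published and unambiguous; calculators using other sets (e.g. Bjellqvist)
can differ by roughly 0.1–0.3 pH units, and near the pI the charge curve is
shallow, so the 1e-4 charge tolerance corresponds to ~0.01 pH. Categorical
thresholds: basic pI > 7, unstable II > 40, thermostable AI ≥ 65,
hydrophilic GRAVY < 0.

## Homoeolog ratios

Groups are **inputs** (from the generator, a naming convention, or an
external orthology run); the package classifies, it does not infer orthology.
Classification uses only the (nA, nB, nD) counts and is symmetric in the
subgenomes; patterns with both a loss and a duplication (e.g. 0:2:1) fall
into OTHER. Summary percentages use genes (not groups) as the denominator
and round half-up to one decimal, matching how such tables are printed.

## Duplication and Ka/Ks

Candidate pairs are aligned globally at the protein level (BLOSUM62, gap
open 10, extend 0.5) and back-translated to codons, replacing a BLAST-based
local search: the 75 %/75 % coverage–identity rule only needs coverage and
identity, and a deterministic global alignment makes them reproducible.
Terminal stop codons are stripped before alignment; coverage is aligned
codons × 3 over the longer stripped CDS, so identical sequences score
exactly 1.0. Both thresholds are strict (> 0.75). Pairs whose length ratio
alone caps coverage at ≤ 0.75 are skipped without aligning.

Tandem vs segmental: a pair is tandem when on the same chromosome and either
≤ 5 annotated genes lie between the midpoints or the midpoints are ≤ 200 kb
apart. Neither cutoff has a canonical published value; these are common
plant-genomics practice and are exposed as flags.

NG86: per codon, the synonymous site count at each position is the fraction
of the three possible changes that are synonymous, with changes to stop
codons removed from the denominator; S averages the two sequences, N = 3·L −
S. Observed differences are partitioned by equal-weight averaging over all
minimal substitution pathways that avoid stop codons (if every pathway
crosses a stop — possible only for 2–3-step codon pairs — all pathways are
used rather than none). Proportions are Jukes–Cantor corrected; p ≥ 3/4
leaves the rate undefined (None), and a selection call requires both rates
defined and Ks > 0. The implementation is cross-checked against an
independent pathway-enumeration oracle in the test suite.

## SSRs

Perfect repeats only, MISA thresholds (mono ≥ 10, di ≥ 6, tri/tetra/penta/
hexa ≥ 5). Runs are reported left-aligned and maximal with a primitive unit,
trimmed to whole units; a run reportable under several unit lengths is
reported once at the smallest unit, and a candidate overlapping an accepted
smaller-unit record is dropped, so reported records never overlap. One
consequence: when a repeat region carries a partial trailing unit, the
reported span is anchored at the left edge, so reversing a sequence mirrors
each repeat *region* exactly but may shift the reported span by up to one
unit — the reversal test checks regions, not raw spans. Compound SSRs merge
simple records separated by ≤ 100 bp (the MISA default), transitively.

## Cis-elements

Patterns are IUPAC consensus strings compiled to regular expressions with
lookahead so overlapping instances all count; `N` in the *sequence* matches
nothing. Both strands are scanned by default (minus-strand hits are reported
at their leftmost plus-strand coordinate), which makes per-element totals
invariant under reverse complementation; note the CGTCA/TGACG pair are
mutual reverse complements, so one planted instance legitimately yields one
hit of each on opposite strands, and palindromic patterns (MYC `CANNTG`)
count once per strand. Only the W-box consensus (`TTGACC`/`TTGACT`) is
anchored in the family literature; the rest of the default catalog follows
PlantCARE-style definitions and is an implementation choice, overridable via
a TSV catalog.

## Phylogeny

p-distance with pairwise deletion is the default (a Poisson correction flag
exists because distance-tool defaults are ambiguous). NJ is the classic
Saitou–Nei algorithm; ties in the Q criterion are broken by the
lexicographically smallest pair of cluster representatives (the smallest
leaf name in each cluster), making output deterministic and input-order
invariant up to isomorphism. Negative branch-length estimates are clamped to
zero and counted on the tree object. Bootstrap resamples alignment columns
with replacement; support is the percentage of successful replicates
containing each original bipartition; an all-identical alignment is flagged
degenerate rather than bootstrapped. Subgroup assignment gives an unlabeled
leaf the label of the smallest clade (over all edges of the unrooted tree)
containing it and at least one labeled leaf, provided all labels in that
clade agree; otherwise UNASSIGNED. Multiple sequence alignment itself is out
of scope — the functions take an aligned FASTA from any aligner; the
center-star aligner included here exists to build small test fixtures only.

## Expression and qPCR

Homoeolog averaging is the arithmetic mean of member rows per column.
`tpm < 1` is unexpressed, read strictly, so a value of exactly 1 counts as
expressed. Heatmap values are log2(TPM + 1). For qPCR, ΔCt is the mean over
replicates of Ct_target − Ct_reference (mean-of-ΔCt rather than
ΔCt-of-means; with a shared reference per record the two differ only through
replicate pairing), ΔΔCt subtracts the control timepoint of the same gene
and condition (default `0h`), and RQ = 2^−ΔΔCt, so the control's RQ is
exactly 1 and the result is invariant to any constant shift applied to both
Ct columns. Both RQ and log2 RQ are emitted.

## Synthetic data

The generator emulates the *statistical structure* the pipeline consumes,
not wheat biology: uniform base composition, no transposons, UTRs of fixed
length (100 bp 5', 200 bp 3'), at most one intron, and homoeologs that are
unrelated in sequence (only their group membership is shared). Defaults are
the published family's study conditions: 113 genes in 40 groups with census
25 triads / 4 duplication groups (17 genes) / 8 loss groups / one 0:2:1
group / 2 orphans; motif variants LTG 86, FTG 11, VTG 8 (VQ) + 4 (VH),
ITG 3, VMA 1; 103/113 intronless; protein lengths ~N(190, 40) clipped to
[80, 300]; 28 planted SSRs (21 tri, 2 di, 5 mono) in 25 genes with two
compound-forming genes; W-box in 55 of 113 promoters (and CGTCA in 100,
ABRE in 98, CAT-box in 35); 30 of 40 groups expressed somewhere; 12 groups
with 7-condition qPCR profiles and Ct noise sd 0.1. Chromosomes default to
90 kb — ample for the densest chromosome while keeping generation around a
second; note that at this toy scale any same-chromosome pair is within the
200 kb tandem cutoff, so planted segmental pairs are placed on different
chromosomes.

Background sequence is locally rejection-sampled: any window of a scanned
region (promoter, UTR, intron, CDS) matching a catalog element, a VQ motif
(in protein space) or a threshold-passing SSR is re-randomized until clean,
which keeps composition uniform rather than masked. Planted features are
then re-verified by scanning the final assembled sequence; junction
artifacts trigger a rebuild of the background (never of the planted bases).
Duplicate pairs copy a source CDS and apply exactly the configured number of
synonymous and nonsynonymous single-nucleotide codon changes, placed only at
codons where the change class is unambiguous, outside the start, stop and
motif codons. Expression flags recorded in the manifest are computed from
the *written* (3-decimal) TPM matrix so that file round-tripping cannot flip
a flag; expressed groups are guaranteed one tissue with every member ≥ 1.5
TPM, unexpressed groups keep every value ≤ 0.8.

Passing the planted-recovery tests therefore shows the pipeline is exact on
clean, planted signal; it says nothing about degraded annotations, imperfect
repeats, diverged homoeologs or real promoter composition.

## Problem sizes

The default test/validation sizes are: 200 random codon pairs (≤ 60 codons)
for the NG86 oracle, 100 random additive 8-taxon trees for NJ, 10³ random
1 kb sequences for the SSR oracle (300 in the acceptance script), 10⁴ random
30-mers for the motif regex oracle, and one full 113-gene synthetic survey.
These sizes give each check thousands of independent decision points while
keeping the whole suite under a minute of compute.
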