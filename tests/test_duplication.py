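import numpy as np
import pytest

from vqsurvey.duplication import (
    CodonAlignment,
    align_cds_pair,
    classify_duplication,
    is_duplicated_pair,
    ng86,
    selection_call,
)
from vqsurvey.seqio import GeneModel
from _oracles import oracle_ng86

_NON_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _random_cds(rng, n_codons):
    codons = [_NON_STOP[i] for i in rng.integers(0, len(_NON_STOP), n_codons)]
    codons[0] = "ATG"
    return "".join(codons)


def _mutate(rng, cds, n_changes):
    seq = list(cds)
    tries = 0
    changed = 0
    while changed < n_changes and tries < 500:
        tries += 1
        p = int(rng.integers(3, len(seq)))  # keep the start codon
        b = "ACGT"[rng.integers(0, 4)]
        if b == seq[p]:
            continue
        old = seq[p]
        seq[p] = b
        codon = "".join(seq[3 * (p // 3) : 3 * (p // 3) + 3])
        if codon in ("TAA", "TAG", "TGA"):
            seq[p] = old
            continue
        changed += 1
    return "".join(seq)


def test_identical_pair_full_coverage_and_identity():
    cds = "ATGAAACCCGGGTTTTAA"
    aln, cov, ident = align_cds_pair(cds, cds)
    assert cov == 1.0 and ident == 1.0
    ka, ks = ng86(aln)
    assert ka == 0.0 and ks == 0.0


def test_single_mismatch_identity():
    rng = np.random.default_rng(0)
    a = _random_cds(rng, 100)
    b = _mutate(rng, a, 1)
    _, cov, ident = align_cds_pair(a + "TAA", b + "TAA")
    assert cov == 1.0
    assert ident == pytest.approx(299 / 300)


def test_half_shared_prefix_coverage():
    rng = np.random.default_rng(1)
    long = _random_cds(rng, 100)
    short = long[: 50 * 3]
    _, cov, _ = align_cds_pair(long, short)
    assert cov == pytest.approx(0.5, abs=0.02)


@pytest.mark.parametrize(
    "cov,ident,expected",
    [(0.80, 0.80, True), (0.70, 0.99, False), (0.75, 0.99, False), (0.99, 0.75, False)],
)
def test_duplication_thresholds_strict(cov, ident, expected):
    assert is_duplicated_pair(cov, ident) is expected


def _gene(gid, chrom, start, end):
    return GeneModel(gid, chrom, "+", start, end, exons=[(start, end)])


def test_classify_tandem_vs_segmental():
    genes = [
        _gene("a", "1A", 1_000, 2_000),
        _gene("b", "1A", 10_000, 11_000),
        _gene("c", "2B", 1_000, 2_000),
    ]
    assert classify_duplication("a", "b", genes) == "tandem"
    assert classify_duplication("a", "c", genes) == "segmental"


def test_distant_crowded_pair_is_segmental():
    genes = [_gene("a", "1A", 1_000, 2_000), _gene("b", "1A", 10_001_000, 10_002_000)]
    genes += [
        _gene(f"x{i}", "1A", 50_000 * (i + 1), 50_000 * (i + 1) + 1000)
        for i in range(200)
    ]
    assert classify_duplication("a", "b", genes) == "segmental"


def test_ng86_symmetric():
    rng = np.random.default_rng(2)
    a = _random_cds(rng, 40)
    b = _mutate(rng, a, 6)
    aln = CodonAlignment(a, b)
    assert ng86(aln) == pytest.approx(ng86(CodonAlignment(b, a)), abs=1e-12)


def test_ng86_planted_synonymous_only():
    # 30 codons; two third-position synonymous changes (CCx is 4-fold)
    a = ["ATG"] + ["CCA"] * 29
    b = list(a)
    b[5] = "CCG"
    b[20] = "CCT"
    aln = CodonAlignment("".join(a), "".join(b))
    ka, ks = ng86(aln)
    assert ka == 0.0
    oka, oks = oracle_ng86("".join(a), "".join(b))
    assert oka == 0.0
    assert ks == pytest.approx(oks, abs=1e-12)
    assert ks > 0


def test_ng86_planted_nonsynonymous_only():
    a = ["ATG"] + ["CCA"] * 29
    b = list(a)
    b[10] = "GCA"  # Pro -> Ala, first position
    aln = CodonAlignment("".join(a), "".join(b))
    ka, ks = ng86(aln)
    assert ks == 0.0
    assert ka > 0
    assert (ka, ks) == pytest.approx(oracle_ng86("".join(a), "".join(b)), abs=1e-12)


def test_ng86_monotone_in_planted_synonymous_divergence():
    rng = np.random.default_rng(9)
    base = ["ATG"] + ["CCA", "GGA", "TCA", "GTA"] * 15
    last = -1.0
    for k in range(0, 20):
        mutated = list(base)
        # third positions of 4-fold codons are unambiguously synonymous
        for i in range(1, k + 1):
            codon = mutated[i]
            mutated[i] = codon[:2] + {"A": "G", "G": "C", "C": "T", "T": "A"}[codon[2]]
        _, ks = ng86(CodonAlignment("".join(base), "".join(mutated)))
        assert ks >= last - 1e-12
        last = ks


def test_ng86_rejects_stop_in_alignment():
    with pytest.raises(ValueError):
        ng86(CodonAlignment("ATGTAA", "ATGCCC"))


@pytest.mark.parametrize(
    "ka,ks,expected",
    [
        (0.1, 0.5, "purifying"),
        (0.5, 0.5, "neutral"),
        (0.8, 0.5, "positive"),
        (0.2, 0.0, "undefined"),
        (None, 0.5, "undefined"),
    ],
)
def test_selection_call(ka, ks, expected):
    assert selection_call(ka, ks) == expected


def test_planted_pairs_recovered_exactly(manifest, survey):
    """All-vs-all detection at the 75/75 thresholds finds exactly the planted
    duplicate pairs, with the planted tandem/segmental class."""
    df = survey.tables["duplications"]
    found = {tuple(sorted((a, b))) for a, b in zip(df.gene_a, df.gene_b)}
    truth = {
        tuple(sorted((d["source"], d["target"]))) for d in manifest.dup_pairs
    }
    assert found == truth
    kinds = {
        tuple(sorted((r.gene_a, r.gene_b))): r.kind for r in df.itertuples()
    }
    for d in manifest.dup_pairs:
        assert kinds[tuple(sorted((d["source"], d["target"])))] == d["kind"]


def test_planted_pure_changes_give_zero_rates(manifest, survey):
    df = survey.tables["duplications"]
    by_pair = {
        tuple(sorted((r.gene_a, r.gene_b))): r for r in df.itertuples()
    }
    for d in manifest.dup_pairs:
        r = by_pair[tuple(sorted((d["source"], d["target"])))]
        if d["nonsyn"] == 0:
            assert r.ka == 0.0
        if d["syn"] == 0:
            assert r.ks == 0.0
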