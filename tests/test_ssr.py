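import numpy as np
import pytest

from vqsurvey.ssr import find_ssrs, merge_compound, ssr_census
from _oracles import brute_force_ssrs


@pytest.mark.parametrize(
    "unit,count,found",
    [
        ("A", 10, True),
        ("A", 9, False),
        ("AG", 6, True),
        ("AG", 5, False),
        ("AGC", 5, True),
        ("AGC", 4, False),
        ("AGCT", 5, True),
        ("AGCTC", 5, True),
        ("AGCTCG", 5, True),
    ],
)
def test_misa_thresholds_at_boundaries(unit, count, found):
    # aperiodic flanks with guard bases that cannot extend the repeat
    lg = "C" if unit[-1] != "C" else "G"
    rg = "C" if unit[0] != "C" else "G"
    seq = "GATC" + lg + unit * count + rg + "GATC"
    records = find_ssrs(seq)
    if found:
        assert len(records) == 1
        r = records[0]
        assert r.motif == unit
        assert r.repeat_count == count
        assert r.end - r.start + 1 == len(unit) * count
        assert r.ssr_type == f"p{len(unit)}"
    else:
        assert records == []


def test_mononucleotide_run_not_reported_as_dinucleotide():
    records = find_ssrs("G" * 5 + "A" * 12 + "C" * 5)
    assert len(records) == 1
    assert records[0].motif == "A"
    assert records[0].ssr_type == "p1"


def test_n_never_extends_a_repeat():
    assert find_ssrs("A" * 9 + "N" + "A" * 9) == []


def test_compound_merging():
    seq = "C" * 5 + "AG" * 6 + "T" * 10 + "CT" * 6 + "G" * 5
    simple = find_ssrs(seq, thresholds=(11, 6, 5, 5, 5, 5))
    assert len(simple) == 2
    merged = merge_compound(simple, max_interruption=100)
    assert len(merged) == 1
    assert merged[0].ssr_type == "compound"
    assert merged[0].start == simple[0].start
    assert merged[0].end == simple[1].end
    assert len(merged[0].components) == 2


def test_distant_ssrs_stay_simple():
    filler = ("GATCACGTGTCA" * 15)[:150]  # aperiodic for unit lengths <= 6
    seq = "C" * 5 + "AG" * 6 + filler + "CT" * 6 + "G" * 5
    simple = find_ssrs(seq, thresholds=(11, 6, 5, 5, 5, 5))
    assert len(simple) == 2
    merged = merge_compound(simple, max_interruption=100)
    assert [r.ssr_type for r in merged] == ["p2", "p2"]
    assert merge_compound([simple[0]]) == [simple[0]]


def test_census_percentages():
    seq = "TTT".join(
        ["AGC" * 5, "TGA" * 5, "CCG" * 5, "CC" + "AG" * 6 + "TT"]
    )
    records = find_ssrs(seq)
    census = ssr_census(records, n_genes=4)
    assert census["class_counts"] == {"p3": 3, "p2": 1}
    assert census["class_pct"] == {"p3": 75.0, "p2": 25.0}
    assert ssr_census([], 0)["n_ssrs"] == 0


def _random_with_repeats(rng, length=1000):
    """AT-skewed random sequence with a few planted near-threshold repeats."""
    seq = list(
        np.array(list("ACGT"))[
            rng.choice(4, size=length, p=[0.35, 0.15, 0.35, 0.15])
        ]
    )
    units = ["A", "T", "AG", "TA", "CAG", "AAT", "ACGT", "AACCT", "ACGTAG"]
    for _ in range(rng.integers(2, 6)):
        unit = units[rng.integers(0, len(units))]
        thr = (10, 6, 5, 5, 5, 5)[len(unit) - 1]
        count = int(rng.integers(max(1, thr - 2), thr + 3))
        pos = int(rng.integers(0, length - len(unit) * count))
        seq[pos : pos + len(unit) * count] = list(unit * count)
    return "".join(seq)


def test_equivalence_with_brute_force_oracle():
    rng = np.random.default_rng(17)
    for _ in range(200):
        seq = _random_with_repeats(rng)
        got = [
            (r.motif, r.repeat_count, r.start, r.end) for r in find_ssrs(seq)
        ]
        assert got == brute_force_ssrs(seq)


def test_reversal_maps_repeat_regions():
    """Reversing the sequence mirrors each record's repeat tract (motif
    reversed, same count); reported spans agree up to the partial-period
    remainder at tract edges."""
    rng = np.random.default_rng(23)
    for _ in range(50):
        seq = _random_with_repeats(rng, 500)
        fwd = find_ssrs(seq)
        rev = find_ssrs(seq[::-1])
        assert len(fwd) == len(rev)
        n = len(seq)
        for f, r in zip(fwd, reversed(rev)):
            assert f.repeat_count == r.repeat_count
            # unit may be reported as a rotation of the reversed unit
            assert sorted(f.motif) == sorted(r.motif)
            k = len(f.motif)
            mirrored_start = n - r.end + 1
            assert abs(f.start - mirrored_start) < k


def test_records_never_overlap():
    rng = np.random.default_rng(29)
    for _ in range(100):
        records = find_ssrs(_random_with_repeats(rng, 500))
        for a, b in zip(records, records[1:]):
            assert a.end < b.start


def test_planted_ssr_recovery(manifest, bundle):
    from vqsurvey.seqio import gene_span_sequence

    for g in bundle.genes:
        found = [
            {"motif": r.motif, "count": r.repeat_count, "start": r.start, "end": r.end}
            for r in find_ssrs(gene_span_sequence(bundle, g.gene_id))
        ]
        assert found == manifest.ssrs[g.gene_id]
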