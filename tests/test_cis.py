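import numpy as np
import pytest

from vqsurvey._util import revcomp
from vqsurvey.cis_elements import (
    ElementCatalog,
    default_catalog,
    element_count_matrix,
    load_catalog,
    scan_elements,
    scan_promoters,
)


def _wbox_catalog():
    return ElementCatalog(
        entries={"W-box": ["TTGACC", "TTGACT"]},
        categories={"W-box": "WRKY-binding"},
    )


def test_wbox_plus_strand():
    hits = scan_elements("AATTGACCAA", _wbox_catalog())
    assert len(hits) == 1
    h = hits[0]
    assert (h.element, h.strand, h.offset) == ("W-box", "+", 3)


def test_wbox_minus_strand():
    # revcomp(TTGGTCAAAA) = TTTTGACCAA contains TTGACC
    hits = scan_elements("TTGGTCAAAA", _wbox_catalog())
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert hits[0].offset == 3  # leftmost plus-strand base of the match


def test_poly_a_promoter_has_no_hits():
    assert scan_elements("A" * 200, default_catalog()) == []


def test_sequence_n_matches_nothing():
    cat = ElementCatalog(entries={"MYC": ["CANNTG"]}, categories={})
    assert scan_elements("CANNTG", cat) == []
    assert len(scan_elements("CAGGTG", cat, both_strands=False)) == 1


def test_iupac_degenerate_positions():
    cat = ElementCatalog(entries={"DRE": ["RCCGAC"]}, categories={})
    assert scan_elements("ACCGAC", cat, both_strands=False)[0].element == "DRE"
    assert scan_elements("GCCGAC", cat, both_strands=False)
    assert scan_elements("TCCGAC", cat, both_strands=False) == []


def test_malformed_iupac_rejected():
    with pytest.raises(ValueError, match="IUPAC"):
        ElementCatalog(entries={"bad": ["ACGU"]}, categories={})


def test_overlapping_matches_all_counted():
    cat = ElementCatalog(entries={"x": ["AA"]}, categories={})
    hits = scan_elements("AAAA", cat, both_strands=False)
    assert [h.offset for h in hits] == [1, 2, 3]


def test_reverse_complement_symmetry():
    rng = np.random.default_rng(13)
    cat = default_catalog()
    for _ in range(25):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        fwd = scan_elements(seq, cat)
        rev = scan_elements(revcomp(seq), cat)
        count = lambda hits: sorted(
            (h.element for h in hits)
        )
        assert count(fwd) == count(rev)


def test_count_matrix_and_coverage():
    cat = _wbox_catalog()
    hits = scan_promoters(
        {"p1": "TTGACCTTGACC", "p2": "AAAAAAAAAAAA", "p3": "AATTGACTAA"},
        cat,
    )
    counts, coverage = element_count_matrix(hits, ["p1", "p2", "p3"], cat)
    assert counts.loc["p1", "W-box"] == 2
    assert counts.loc["p2", "W-box"] == 0
    assert coverage["W-box"] == pytest.approx(2 / 3)


def test_empty_hits_zero_matrix():
    cat = _wbox_catalog()
    counts, coverage = element_count_matrix({}, ["a", "b"], cat)
    assert (counts.values == 0).all()
    assert coverage["W-box"] == 0.0


def test_catalog_tsv_round_trip(tmp_path):
    p = tmp_path / "catalog.tsv"
    p.write_text(
        "name\tcategory\tconsensus\n"
        "W-box\tWRKY-binding\tTTGACC,TTGACT\n"
        "DRE core\tstress\tRCCGAC\n"
    )
    cat = load_catalog(p)
    assert cat.entries["W-box"] == ["TTGACC", "TTGACT"]
    assert cat.categories["DRE core"] == "stress"
    assert scan_elements("AATTGACTAA", cat)[0].element == "W-box"


def test_planted_elements_recovered_exactly(manifest, bundle):
    """Precision and recall are both 1.0 against the planted manifest: every
    expected hit (including complement-pair shadows) and nothing else."""
    from vqsurvey.seqio import extract_promoter

    cat = default_catalog()
    for g in bundle.genes:
        prom = extract_promoter(bundle, g.gene_id, 1500)
        found = sorted(
            (
                {"element": h.element, "strand": h.strand, "offset": h.offset}
                for h in scan_elements(prom, cat)
            ),
            key=lambda r: (r["offset"], r["element"], r["strand"]),
        )
        assert found == manifest.cis[g.gene_id]


def test_wbox_coverage_on_planted_fixture(manifest, survey):
    cov = survey.summaries["cis_coverage"]["W-box"]
    planted = sum(
        1
        for hits in manifest.cis.values()
        if any(h["element"] == "W-box" for h in hits)
    )
    assert planted == 55
    assert round(100 * cov, 1) == 48.7
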