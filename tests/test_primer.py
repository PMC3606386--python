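"""Degenerate primer design and in-silico PCR."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from lgt_hunter.datamodel import Scaffold, reverse_complement
from lgt_hunter.primer import (Amplicon, DegeneratePrimer, degeneracy_of, expand,
                               find_conserved_blocks, insilico_pcr, iupac_consensus,
                               make_primer, reverse_complement_iupac)

DM1 = "TTTGGRGGNGGNATGCARAAYGG"
DM2 = "CCRTCRTTNGGDATRAACCA"


def test_survey_primer_degeneracies_from_printed_strings():
    assert degeneracy_of(DM1) == 128   # R*N*N*R*Y = 2*4*4*2*2
    assert degeneracy_of(DM2) == 96    # R*R*N*D*R = 2*2*4*3*2
    assert len(expand("ACGR")) == 2


def test_iupac_consensus_closure():
    assert iupac_consensus({"A", "G"}) == "R"
    assert iupac_consensus({"C", "T"}) == "Y"
    assert iupac_consensus({"A"}) == "A"
    assert iupac_consensus({"A", "C", "G", "T"}) == "N"


def test_reverse_complement_of_degenerate_codes():
    assert reverse_complement_iupac("ACGR") == "YCGT"
    assert reverse_complement_iupac(reverse_complement_iupac(DM1)) == DM1


@given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=20),
       st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=20))
@settings(max_examples=50, derandomize=True)
def test_degeneracy_multiplicative(p, q):
    assert degeneracy_of(p + q) == degeneracy_of(p) * degeneracy_of(q)


def test_identical_sequences_give_single_degeneracy1_block():
    rng = random.Random(2)
    seq = "".join(rng.choice("ACGT") for _ in range(60))
    blocks = find_conserved_blocks([("a", seq), ("b", seq)], min_len=18,
                                   max_degeneracy=512)
    assert blocks == [(0, 60)]
    primer = make_primer(blocks[0], [("a", seq), ("b", seq)])
    assert primer.iupac_seq == seq and primer.degeneracy == 1


def test_mismatch_column_becomes_iupac_code():
    a = "A" * 30
    b = "A" * 15 + "G" + "A" * 14
    blocks = find_conserved_blocks([("a", a), ("b", b)], min_len=18,
                                   max_degeneracy=512)
    primer = make_primer(blocks[0], [("a", a), ("b", b)])
    assert "R" in primer.iupac_seq


def test_gap_column_splits_blocks():
    a = "ACGTACGTACGTACGTACGTA" + "-" + "CGTACGTACGTACGTACGTAC"
    b = a
    blocks = find_conserved_blocks([("a", a), ("b", b)], min_len=18,
                                   max_degeneracy=512)
    assert all(not (lo <= 21 < hi) for lo, hi in blocks)
    assert len(blocks) == 2


def test_degeneracy_budget_limits_blocks():
    a = "ACGT" * 10
    b = "TGCA" * 10  # every column degenerate
    assert find_conserved_blocks([("a", a), ("b", b)], min_len=10,
                                 max_degeneracy=8) == []


def test_planted_sites_give_exact_product_length():
    rng = random.Random(6)
    fwd = DegeneratePrimer(name="f", iupac_seq="ACGTACGTACGTACGTAR")
    rev = DegeneratePrimer(name="r", iupac_seq="TTGCAATTGGCCAATTGG")
    rev_site = reverse_complement(rev.iupac_seq.replace("R", "A"))  # no codes here
    tmpl = ("".join(rng.choice("ACGT") for _ in range(100))
            + "ACGTACGTACGTACGTAA"  # matches fwd (R covers A)
            + "".join(rng.choice("ACGT") for _ in range(482 - 18))
            + rev_site
            + "".join(rng.choice("ACGT") for _ in range(100)))
    products = insilico_pcr(fwd, rev, Scaffold(id="t", seq=tmpl), max_mismatch=0)
    assert [a.product_length for a in products] == [500]
    a = products[0]
    assert a.fwd_site == (100, 118)
    assert a.rev_site == (582, 600)
    assert a.rev_site[1] - a.fwd_site[0] == 500


def test_template_without_sites_gives_no_product():
    rng = random.Random(7)
    tmpl = Scaffold(id="t", seq="".join(rng.choice("ACGT") for _ in range(500)))
    fwd = DegeneratePrimer(name="f", iupac_seq="AAAAAAAAAAAAAAAAAA")
    rev = DegeneratePrimer(name="r", iupac_seq="CCCCCCCCCCCCCCCCCC")
    assert insilico_pcr(fwd, rev, tmpl) == []


def test_degenerate_base_counts_as_match():
    fwd = DegeneratePrimer(name="f", iupac_seq="ACGTACGTACGTACGRR")
    rev = DegeneratePrimer(name="r", iupac_seq="AATTCCGGAATTCCGG")
    tmpl = Scaffold(id="t", seq="ACGTACGTACGTACGGA" + "T" * 50
                    + reverse_complement("AATTCCGGAATTCCGG"))
    products = insilico_pcr(fwd, rev, tmpl, max_mismatch=0)
    assert len(products) == 1 and products[0].fwd_mismatches == 0


def _brute_force_pcr(fwd, rev, template, max_mismatch, anchor):
    """Oracle: union over all fully expanded non-degenerate primer variants."""
    found = set()
    for fv in expand(fwd.iupac_seq):
        for rv in expand(rev.iupac_seq):
            for a in insilico_pcr(DegeneratePrimer(name="f", iupac_seq=fv),
                                  DegeneratePrimer(name="r", iupac_seq=rv),
                                  template, max_mismatch=max_mismatch,
                                  anchor_3prime=anchor):
                found.add((a.fwd_site, a.rev_site, a.product_length))
    return found


def test_expansion_equivalence_for_small_degeneracy():
    rng = random.Random(9)
    fwd = DegeneratePrimer(name="f", iupac_seq="ACGTACRTACGTWCGTA")
    rev = DegeneratePrimer(name="r", iupac_seq="GGATCCYGGATKCAGG")
    assert fwd.degeneracy * rev.degeneracy <= 256
    tmpl = ("".join(rng.choice("ACGT") for _ in range(80))
            + "ACGTACATACGTTCGTA" + "".join(rng.choice("ACGT") for _ in range(200))
            + reverse_complement("GGATCCCGGATGCAGG")
            + "".join(rng.choice("ACGT") for _ in range(80)))
    scf = Scaffold(id="t", seq=tmpl)
    mine = {(a.fwd_site, a.rev_site, a.product_length)
            for a in insilico_pcr(fwd, rev, scf, max_mismatch=0)}
    # with 0 mismatches allowed, degenerate matching == union of variants
    assert mine == _brute_force_pcr(fwd, rev, scf, 0, 3)
    assert mine  # the planted sites were found


def test_strand_duality():
    rng = random.Random(10)
    fwd = DegeneratePrimer(name="f", iupac_seq="ACGTACGTACGTACGTAR")
    rev = DegeneratePrimer(name="r", iupac_seq="TTGCAATTGGCCAATTGG")
    tmpl = ("".join(rng.choice("ACGT") for _ in range(60))
            + "ACGTACGTACGTACGTAG" + "".join(rng.choice("ACGT") for _ in range(150))
            + reverse_complement("TTGCAATTGGCCAATTGG")
            + "".join(rng.choice("ACGT") for _ in range(60)))
    scf = Scaffold(id="t", seq=tmpl)
    flipped = Scaffold(id="t", seq=reverse_complement(tmpl))
    # on the flipped template the primer pair swaps roles
    fwd2 = DegeneratePrimer(name="f2", iupac_seq=rev.iupac_seq)
    rev2 = DegeneratePrimer(name="r2", iupac_seq=fwd.iupac_seq)
    p1 = insilico_pcr(fwd, rev, scf, max_mismatch=0)
    p2 = insilico_pcr(fwd2, rev2, flipped, max_mismatch=0)
    assert [a.product_length for a in p1] == [a.product_length for a in p2]
    n = len(tmpl)
    assert all(a1.fwd_site == (n - a2.rev_site[1], n - a2.rev_site[0])
               for a1, a2 in zip(p1, p2))


def test_primer_length_and_degeneracy_admit_the_survey_pair():
    # both printed survey primers pass the default admissibility bounds
    for seq in (DM1, DM2):
        p = DegeneratePrimer(name="p", iupac_seq=seq)
        assert 18 <= len(p.iupac_seq) <= 27
        assert p.degeneracy <= 512
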