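"""RBH orthology, identity Z-scores, microsynteny, neighbor distances."""

import math

import pytest

from lgt_hunter.datamodel import Assembly, GeneModel, ProteinRecord, Scaffold
from lgt_hunter.orthology import (OrthologPair, identity_zscore, microsynteny,
                                  neighbor_distance, reciprocal_best_hits)
from lgt_hunter.simulate import simulate_ortholog_panel


@pytest.fixture(scope="module")
def panel():
    """50 diverged ortholog pairs + 5 paralog confounders (seed 11)."""
    return simulate_ortholog_panel(n_species=2, tree_depth=0.12, n_genes=50,
                                   gene_length=120, seed=11, n_paralogs=5)


def test_identical_proteomes_give_self_pairs(prot_scheme):
    prot = [ProteinRecord(id=f"g{i}", seq="MKVLLDEFGHIKWQRSTYNPACDE" * 3)
            for i in range(3)]
    # identical sequences tie; the tie rule (lexicographic subject) pairs g0-g0
    pairs = reciprocal_best_hits(prot[:1], prot[:1], prot_scheme)
    assert [(p.gene_a, p.gene_b) for p in pairs] == [("g0", "g0")]
    assert pairs[0].pct_identity == 100.0


def test_rbh_recovers_true_pairs_despite_paralogs(panel, prot_scheme):
    proteomes, _, truth = panel
    pairs = reciprocal_best_hits(proteomes["sp1"], proteomes["sp2"], prot_scheme)
    found = {(p.gene_a, p.gene_b) for p in pairs}
    assert found == set(truth.true_ortholog_pairs)
    # each gene appears in at most one pair
    genes = [g for p in pairs for g in (p.gene_a, p.gene_b)]
    assert len(genes) == len(set(genes))


def test_rbh_symmetry(panel, prot_scheme):
    proteomes, _, _ = panel
    ab = reciprocal_best_hits(proteomes["sp1"][:10], proteomes["sp2"][:10], prot_scheme)
    ba = reciprocal_best_hits(proteomes["sp2"][:10], proteomes["sp1"][:10], prot_scheme)
    assert {(p.gene_a, p.gene_b) for p in ab} == {(p.gene_b, p.gene_a) for p in ba}


def test_reciprocity_required(prot_scheme):
    # a's best is b, but b prefers c (an identical twin of itself): no pair
    base = "MKVLLDEFGHIKWQRSTYNPACDEMKVLLDEFGHIKWQRSTYNP"
    a = ProteinRecord(id="a", seq=base[:30])
    b = ProteinRecord(id="b", seq=base)
    c = ProteinRecord(id="c", seq=base)
    pairs = reciprocal_best_hits([a, c], [b], prot_scheme)
    # b's best among {a, c} is c (full-length identity); a gets no pair
    assert all(p.gene_a != "a" for p in pairs)


def _bg(values):
    return [OrthologPair(gene_a=f"x{i}", gene_b=f"y{i}", pct_identity=v,
                         evalue_ab=0.0, evalue_ba=0.0)
            for i, v in enumerate(values)]


def test_zscore_reproduces_printed_moments():
    # a background with mean 70.7 and sd 15.64 puts a 58.5%-identity pair
    # at z = -0.78 (the inversion of the printed triple)
    focal = OrthologPair(gene_a="f", gene_b="g", pct_identity=58.5,
                         evalue_ab=0.0, evalue_ba=0.0)
    z, mean, sd = identity_zscore(focal, _bg([70.7 - 15.64, 70.7, 70.7 + 15.64]))
    assert mean == pytest.approx(70.7)
    assert sd == pytest.approx(15.64)
    assert z == pytest.approx(-0.78, abs=5e-3)


def test_zscore_two_point_background_hand_computed():
    focal = OrthologPair(gene_a="f", gene_b="g", pct_identity=70.0,
                         evalue_ab=0.0, evalue_ba=0.0)
    z, mean, sd = identity_zscore(focal, _bg([60.0, 80.0]))
    assert z == 0.0
    assert sd == pytest.approx(math.sqrt(200.0), abs=1e-9)  # 14.142


def test_zscore_focal_excluded_and_shift_invariant():
    focal = OrthologPair(gene_a="x0", gene_b="y0", pct_identity=50.0,
                         evalue_ab=0.0, evalue_ba=0.0)
    bg = _bg([50.0, 60.0, 70.0])  # x0/y0 collides with the focal ids
    z1, mean, _ = identity_zscore(focal, bg)
    assert mean == pytest.approx(65.0)  # the focal's twin was dropped
    shifted = _bg([v + 7.5 for v in (55.0, 60.0, 70.0)])
    focal2 = OrthologPair(gene_a="f", gene_b="g", pct_identity=57.5,
                          evalue_ab=0.0, evalue_ba=0.0)
    z_a, *_ = identity_zscore(
        OrthologPair(gene_a="f", gene_b="g", pct_identity=50.0,
                     evalue_ab=0.0, evalue_ba=0.0), _bg([55.0, 60.0, 70.0]))
    z_b, *_ = identity_zscore(focal2, shifted)
    assert z_a == pytest.approx(z_b)


def test_zscore_degenerate_background_errors():
    focal = OrthologPair(gene_a="f", gene_b="g", pct_identity=50.0,
                         evalue_ab=0.0, evalue_ba=0.0)
    with pytest.raises(ValueError, match="zero standard deviation"):
        identity_zscore(focal, _bg([70.0, 70.0, 70.0]))
    with pytest.raises(ValueError, match="at least 2"):
        identity_zscore(focal, _bg([70.0]))


def _toy_assemblies(order_b=None, n=7):
    """Two single-scaffold assemblies with n genes each; assembly B gene order
    optionally permuted."""
    order_b = order_b or list(range(n))
    asm_a, asm_b = Assembly(), Assembly()
    asm_a.add_scaffold(Scaffold(id="A", seq="A" * (n * 200 + 200)))
    asm_b.add_scaffold(Scaffold(id="B", seq="A" * (n * 200 + 200)))
    for i in range(n):
        asm_a.add_gene(GeneModel(gene_id=f"a{i}", scaffold_id="A",
                                 start=100 + 200 * i, end=200 + 200 * i, strand="+"))
    for pos, i in enumerate(order_b):
        asm_b.add_gene(GeneModel(gene_id=f"b{i}", scaffold_id="B",
                                 start=100 + 200 * pos, end=200 + 200 * pos, strand="+"))
    omap = {f"a{i}": f"b{i}" for i in range(n)}
    focal = OrthologPair(gene_a="a3", gene_b="b3", pct_identity=60.0,
                         evalue_ab=0.0, evalue_ba=0.0)
    return asm_a, asm_b, omap, focal


def test_microsynteny_identical_order():
    asm_a, asm_b, omap, focal = _toy_assemblies()
    rep = microsynteny(focal, asm_a, asm_b, omap, window=3)
    assert rep.shared_flank_fraction == 1.0
    assert rep.order_conserved


def test_microsynteny_reversal_is_order_conserved():
    asm_a, asm_b, omap, focal = _toy_assemblies(order_b=list(range(6, -1, -1)))
    rep = microsynteny(focal, asm_a, asm_b, omap, window=3)
    assert rep.shared_flank_fraction == 1.0
    assert rep.order_conserved  # whole-window reversal allowed


def test_microsynteny_shuffle_breaks_order():
    asm_a, asm_b, omap, focal = _toy_assemblies(order_b=[2, 5, 0, 3, 6, 1, 4])
    rep = microsynteny(focal, asm_a, asm_b, omap, window=3)
    assert not rep.order_conserved


def test_microsynteny_clips_at_scaffold_end():
    asm_a, asm_b, omap, _ = _toy_assemblies()
    focal = OrthologPair(gene_a="a0", gene_b="b0", pct_identity=60.0,
                         evalue_ab=0.0, evalue_ba=0.0)
    rep = microsynteny(focal, asm_a, asm_b, omap, window=3)
    assert rep.shared_flank_fraction == 1.0  # denominator clipped to 3


def test_microsynteny_missing_focal_errors():
    asm_a, asm_b, omap, _ = _toy_assemblies()
    ghost = OrthologPair(gene_a="nope", gene_b="b3", pct_identity=60.0,
                         evalue_ab=0.0, evalue_ba=0.0)
    with pytest.raises(ValueError, match="absent"):
        microsynteny(ghost, asm_a, asm_b, omap, window=3)


def _gene(gid, start, end):
    return GeneModel(gene_id=gid, scaffold_id="s", start=start, end=end, strand="+")


def _asm_with(*genes):
    asm = Assembly()
    asm.add_scaffold(Scaffold(id="s", seq="A" * 1000))
    for g in genes:
        asm.add_gene(g)
    return asm


def test_neighbor_distance_85bp_arrangement():
    g1, g2 = _gene("g1", 0, 100), _gene("g2", 185, 300)
    asm = _asm_with(g1, g2)
    assert neighbor_distance(g1, asm) == ("g2", 85)


def test_neighbor_distance_overlap_is_zero():
    g1, g2 = _gene("g1", 0, 100), _gene("g2", 50, 200)
    asm = _asm_with(g1, g2)
    assert neighbor_distance(g1, asm) == ("g2", 0)


def test_neighbor_distance_picks_nearer_flank():
    g1, g2, g3 = _gene("g1", 0, 100), _gene("g2", 150, 250), _gene("g3", 400, 500)
    asm = _asm_with(g1, g2, g3)
    assert neighbor_distance(g2, asm) == ("g1", 50)


def test_neighbor_distance_single_gene_returns_none():
    g1 = _gene("g1", 0, 100)
    asm = _asm_with(g1)
    assert neighbor_distance(g1, asm) is None
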