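"""The differential-homology screen and its filter chain."""

import random

import pytest

from lgt_hunter.datamodel import Assembly, Scaffold
from lgt_hunter.screen import (EXCLUDED_ANIMAL, EXCLUDED_SCAFFOLD_LENGTH, RETAINED,
                               LgtCandidate, ScreenParams, animal_filter,
                               find_bacterial_regions, scaffold_length_filter,
                               screen)


def _rand(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="module")
def simple_assembly(dna_scheme):
    """10 kb scaffold with a verbatim 2 kb bacterial gene at [4000, 6000)."""
    rng = random.Random(17)
    bact_gene = _rand(rng, 2000)
    host = _rand(rng, 4000) + bact_gene + _rand(rng, 4000)
    asm = Assembly()
    asm.add_scaffold(Scaffold(id="scf", seq=host))
    bacterial_db = [Scaffold(id="bact", seq=_rand(rng, 1000) + bact_gene + _rand(rng, 1000))]
    return asm, bacterial_db


def test_verbatim_implant_found_and_spans_insert(simple_assembly, dna_scheme):
    asm, bact = simple_assembly
    cands = find_bacterial_regions(asm, bact, dna_scheme, ScreenParams())
    assert len(cands) == 1
    c = cands[0]
    assert c.region[0] <= 4000 and c.region[1] >= 6000
    assert c.bacterial_best.evalue < 1e-5
    assert c.audit and c.audit[0].startswith("bacterial_region")


def test_nearby_hsps_merge_into_one_region(dna_scheme):
    rng = random.Random(23)
    frag_a, frag_b = _rand(rng, 400), _rand(rng, 400)
    host = _rand(rng, 2000) + frag_a + _rand(rng, 100) + frag_b + _rand(rng, 2000)
    asm = Assembly()
    asm.add_scaffold(Scaffold(id="scf", seq=host))
    bact = [Scaffold(id="b", seq=frag_a + _rand(rng, 3000) + frag_b)]
    cands = find_bacterial_regions(asm, bact, dna_scheme,
                                   ScreenParams(hsp_merge_gap=1000))
    assert len(cands) == 1
    cands2 = find_bacterial_regions(asm, bact, dna_scheme,
                                    ScreenParams(hsp_merge_gap=50))
    assert len(cands2) == 2


def test_random_scaffold_yields_no_candidates(dna_scheme):
    rng = random.Random(31)
    asm = Assembly()
    asm.add_scaffold(Scaffold(id="scf", seq=_rand(rng, 8000)))
    bact = [Scaffold(id="b", seq=_rand(rng, 8000))]
    assert find_bacterial_regions(asm, bact, dna_scheme, ScreenParams()) == []


def test_animal_filter_excludes_better_animal_hit(dna_scheme):
    # short fragment so E-values stay representable (no underflow to 0)
    rng = random.Random(41)
    frag = _rand(rng, 300)
    asm = Assembly()
    asm.add_scaffold(Scaffold(id="scf", seq=_rand(rng, 5000) + frag + _rand(rng, 5000)))
    bact = [Scaffold(id="b", seq=frag)]
    (cand,) = find_bacterial_regions(asm, bact, dna_scheme, ScreenParams())
    assert cand.bacterial_best.evalue > 0
    region_seq = asm.scaffolds["scf"].seq[cand.region[0]:cand.region[1]]
    # verbatim animal copy with a much smaller query (the region) -> smaller E
    animal_db = [Scaffold(id="anim", seq=region_seq)]
    out = animal_filter(cand, animal_db, dna_scheme, ScreenParams(), asm)
    assert out.status == EXCLUDED_ANIMAL
    assert out.animal_best_evalue < out.bacterial_best.evalue
    assert out.audit[-1].startswith("animal_filter")


def test_animal_filter_retains_without_animal_hit(simple_assembly, dna_scheme):
    asm, bact = simple_assembly
    (cand,) = find_bacterial_regions(asm, bact, dna_scheme, ScreenParams())
    rng = random.Random(37)
    out = animal_filter(cand, [Scaffold(id="anim", seq=_rand(rng, 4000))],
                        dna_scheme, ScreenParams(), asm)
    assert out.status == RETAINED
    assert out.animal_best_evalue is None or \
        out.animal_best_evalue >= out.bacterial_best.evalue


def test_animal_filter_equal_evalue_retains(simple_assembly, dna_scheme):
    # strict "less than": an exactly equal animal E-value does not exclude
    import dataclasses

    from lgt_hunter.homology import SearchParams, best_hit

    asm, bact = simple_assembly
    (cand,) = find_bacterial_regions(asm, bact, dna_scheme, ScreenParams())
    region_seq = asm.scaffolds["scf"].seq[cand.region[0]:cand.region[1]]
    animal_db = [Scaffold(id="anim", seq=region_seq)]
    pre = best_hit(Scaffold(id="region", seq=region_seq), animal_db, dna_scheme,
                   SearchParams())
    tied = dataclasses.replace(cand.bacterial_best, evalue=pre.evalue)
    equal = LgtCandidate(scaffold_id=cand.scaffold_id, region=cand.region,
                         bacterial_best=tied, audit=list(cand.audit))
    out = animal_filter(equal, animal_db, dna_scheme, ScreenParams(), asm)
    assert out.animal_best_evalue == out.bacterial_best.evalue
    assert out.status == RETAINED


@pytest.mark.parametrize("length,expected", [(4999, EXCLUDED_SCAFFOLD_LENGTH),
                                             (5000, RETAINED),
                                             (100_000, RETAINED)])
def test_scaffold_length_rule_is_strict(dna_scheme, length, expected):
    rng = random.Random(length)
    frag = _rand(rng, 600)
    seq = frag + _rand(rng, length - 600)
    asm = Assembly()
    asm.add_scaffold(Scaffold(id="scf", seq=seq))
    bact = [Scaffold(id="b", seq=frag)]
    (cand,) = find_bacterial_regions(asm, bact, dna_scheme, ScreenParams())
    out = scaffold_length_filter(cand, asm, ScreenParams())
    assert out.status == expected
    assert out.audit[-1].startswith("scaffold_length_filter")


def test_scaffold_length_filter_unknown_scaffold_errors(dna_scheme, simple_assembly):
    asm, bact = simple_assembly
    (cand,) = find_bacterial_regions(asm, bact, dna_scheme, ScreenParams())
    bad = LgtCandidate(scaffold_id="nope", region=cand.region,
                       bacterial_best=cand.bacterial_best, audit=["x"])
    with pytest.raises(ValueError, match="unknown scaffold"):
        scaffold_length_filter(bad, Assembly(), ScreenParams())


def test_screen_seed7_three_fates(acceptance_screen):
    """The standard fixture exercises retained / excluded_animal /
    excluded_scaffold_length simultaneously, matching ground truth."""
    candidates, truth = acceptance_screen
    by_status = {}
    for c in candidates:
        by_status.setdefault(c.status, []).append(c)
    (retained,) = by_status[RETAINED]
    sid, (lo, hi), _ = truth.implanted_regions[0]
    assert retained.scaffold_id == sid
    assert retained.region[0] < hi and lo < retained.region[1]
    assert {c.scaffold_id for c in by_status[EXCLUDED_SCAFFOLD_LENGTH]} == \
        set(truth.contaminant_scaffold_ids)
    decoy_scaffolds = {g.rsplit("_", 1)[0] for g in truth.decoy_gene_ids}
    assert {c.scaffold_id for c in by_status[EXCLUDED_ANIMAL]} == decoy_scaffolds


def test_screen_audit_lists_each_filter_once_in_order(acceptance_screen):
    candidates, _ = acceptance_screen
    for c in candidates:
        stages = [a.split(":")[0] for a in c.audit]
        assert stages == ["bacterial_region", "animal_filter", "scaffold_length_filter"]


def test_screen_empty_animal_db_keeps_bacterial_candidates(simple_assembly, dna_scheme):
    asm, bact = simple_assembly
    cands = screen(asm, bact, [], dna_scheme)
    assert len(cands) == 1 and cands[0].status == RETAINED


def test_tight_cutoff_dominates_the_screen(dna_scheme):
    # a diverged 400 bp hit has E far above 1e-80 but far below 1e-5:
    # tightening the cutoff to 1e-80 must empty the candidate list
    rng = random.Random(43)
    frag = _rand(rng, 400)
    diverged = "".join(rng.choice([b for b in "ACGT" if b != c])
                       if rng.random() < 0.25 else c for c in frag)
    asm = Assembly()
    asm.add_scaffold(Scaffold(id="scf", seq=_rand(rng, 4000) + diverged + _rand(rng, 4000)))
    bact = [Scaffold(id="b", seq=frag)]
    loose = screen(asm, bact, [], dna_scheme, ScreenParams())
    assert len(loose) == 1 and 0 < loose[0].bacterial_best.evalue < 1e-5
    assert screen(asm, bact, [], dna_scheme,
                  ScreenParams(bacterial_evalue_cutoff=1e-80)) == []


def test_relaxing_cutoff_never_drops_retained(simple_assembly, dna_scheme):
    asm, bact = simple_assembly
    strict = screen(asm, bact, [], dna_scheme,
                    ScreenParams(bacterial_evalue_cutoff=1e-20))
    relaxed = screen(asm, bact, [], dna_scheme,
                     ScreenParams(bacterial_evalue_cutoff=1e-3))
    strict_ids = {(c.scaffold_id, c.region) for c in strict if c.status == RETAINED}
    relaxed_ids = {(c.scaffold_id, c.region) for c in relaxed if c.status == RETAINED}
    assert strict_ids <= relaxed_ids
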