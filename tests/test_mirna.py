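"""Hairpin structure parsing, duplex extraction and curation verdicts."""

import numpy as np
import pytest

from cressomics import mirna
from cressomics.mirna import (
    HairpinCandidate,
    evaluate_candidate,
    extract_duplex,
    parse_structure,
    render_structure,
    terminal_loops,
)


def test_parse_structure_simple_hairpin():
    table = parse_structure("((((....))))")
    assert (table >= 0).sum() == 8  # 4 pairs
    assert terminal_loops(table) == 1
    assert table[0] == 11 and table[11] == 0


def test_parse_structure_two_stems():
    table = parse_structure("((..))((..))")
    assert terminal_loops(table) == 2


def test_parse_structure_symmetry():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(2, 15))
        structure = "(" * n + "." * 4 + ")" * n
        table = parse_structure(structure)
        for i, j in enumerate(table):
            if j >= 0:
                assert table[j] == i


@pytest.mark.parametrize("bad", ["(((", "())", "((x))"])
def test_parse_structure_rejects_invalid(bad):
    with pytest.raises(ValueError):
        parse_structure(bad)


def test_parse_render_round_trip():
    structures = ["((((....))))", "((..))((..))", "..(((...)))..", "." * 5]
    for s in structures:
        assert render_structure(parse_structure(s)) == s


def perfect_hairpin(arm=40, loop=10):
    return "(" * arm + "." * loop + ")" * arm


def test_extract_duplex_perfect_pairing():
    # 22-nt mature on the 5' arm of a perfectly paired stem
    structure = perfect_hairpin(40, 10)
    n = len(structure)
    cand = HairpinCandidate("h", "A" * n, structure, [], (5, 27))
    d = extract_duplex(cand)
    qmin, qmax = n - 1 - 26, n - 1 - 5
    assert d.star == (qmin + 2, qmax + 3)
    assert d.star[1] - d.star[0] == 22
    assert d.mismatches == 0 and d.bulge_nt == 0 and d.internal_loops == 0
    assert d.overhang_mature_3p == 2 and d.overhang_star_3p == 2


def test_extract_duplex_three_prime_arm_mature():
    structure = perfect_hairpin(40, 10)
    n = len(structure)
    cand = HairpinCandidate("h", "A" * n, structure, [], (60, 82))
    d = extract_duplex(cand)
    assert d.overhang_mature_3p == 2 and d.overhang_star_3p == 2
    assert d.star[1] - d.star[0] == 22


def test_extract_duplex_counts_single_mismatch():
    # one 1:1 unpaired opposition inside the duplex
    structure = "((((((((((." + "((((((((((" + "...." + "))))))))))" + "." + "))))))))))"
    cand = HairpinCandidate("h", "A" * len(structure), structure, [], (0, 21))
    d = extract_duplex(cand)
    assert d.mismatches == 1
    assert d.bulge_nt == 0


def test_extract_duplex_counts_asymmetric_bulge():
    # two unpaired mature nts opposite zero on the star strand
    structure = "((((((((((.." + "((((((((((" + "...." + "))))))))))" + "))))))))))"
    cand = HairpinCandidate("h", "A" * len(structure), structure, [], (0, 22))
    d = extract_duplex(cand)
    assert d.bulge_nt == 2
    assert d.mismatches == 0
    # bulge nucleotides count toward the mismatched-base total in the verdict
    v = evaluate_candidate(cand)
    assert v.measured["mismatch_count"] == 2


def test_extract_duplex_mature_spanning_loop_flagged():
    structure = perfect_hairpin(20, 6)
    cand = HairpinCandidate("h", "A" * len(structure), structure, [], (10, 32))
    d = extract_duplex(cand)
    assert d.spans_loop
    v = evaluate_candidate(cand)
    assert not v.criteria["single_stem"]


def test_evaluate_no_reads_fails_duplex_criterion():
    structure = perfect_hairpin(40, 10)
    cand = HairpinCandidate("h", "A" * len(structure), structure, [], (5, 27))
    v = evaluate_candidate(cand)
    assert not v.criteria["duplex_read_fraction"]
    assert any("no reads" in r for r in v.reasons)


def test_candidate_validation():
    with pytest.raises(ValueError):
        HairpinCandidate("h", "ACGU", "(((", [], None)
    with pytest.raises(ValueError):
        HairpinCandidate("h", "ACGU", "....", [(0, 10, 1)], None)


def test_single_fault_fixtures_fail_exactly_their_criterion(hairpin_set):
    candidates, expected = hairpin_set
    by_id = {c.id: c for c in candidates}
    for _, row in expected.iterrows():
        verdict = evaluate_candidate(by_id[row["id"]])
        assert verdict.passed == row["expect_pass"], row["id"]
        failing = [k for k, ok in verdict.criteria.items() if not ok]
        if row["expect_pass"]:
            assert failing == []
        else:
            assert failing == [row["failing_criterion"]], row["id"]


def test_boundary_hairpin_length_and_duplex_fraction(hairpin_set):
    candidates, _ = hairpin_set
    by_id = {c.id: c for c in candidates}
    assert len(by_id["pass_len300"].sequence) == 300
    assert len(by_id["fail_length"].sequence) == 301
    v300 = evaluate_candidate(by_id["pass_len300"])
    v301 = evaluate_candidate(by_id["fail_length"])
    assert v300.criteria["hairpin_length"] and not v301.criteria["hairpin_length"]
    v75 = evaluate_candidate(by_id["pass_duplex75"])
    v74 = evaluate_candidate(by_id["fail_duplex_fraction"])
    assert v75.measured["duplex_read_fraction"] == pytest.approx(0.75)
    assert v74.measured["duplex_read_fraction"] == pytest.approx(0.74)
    assert v75.criteria["duplex_read_fraction"]
    assert not v74.criteria["duplex_read_fraction"]


def test_verdict_invariant_under_read_order_and_count_scaling(hairpin_set):
    candidates, _ = hairpin_set
    for cand in candidates:
        base = evaluate_candidate(cand)
        reordered = HairpinCandidate(
            cand.id, cand.sequence, cand.structure, cand.reads[::-1], cand.mature
        )
        scaled = HairpinCandidate(
            cand.id,
            cand.sequence,
            cand.structure,
            [(s, e, 7 * c) for s, e, c in cand.reads],
            cand.mature,
        )
        for variant in (reordered, scaled):
            v = evaluate_candidate(variant)
            assert v.passed == base.passed
            assert v.criteria == base.criteria


def test_fixture_structures_are_balanced(hairpin_set):
    candidates, _ = hairpin_set
    for cand in candidates:
        assert cand.structure.count("(") == cand.structure.count(")")
        parse_structure(cand.structure)  # does not raise
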