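"""Hairpin folding, dot-bracket parsing and the 11-criteria engine."""
from __future__ import annotations

import functools

import pytest

from mircms._util import can_pair, random_seq, revcomp, stream_rng
from mircms.hairpin_filter import (
    HairpinCriteria,
    HairpinParseError,
    evaluate_criteria,
    extract_hairpin,
    fold_simple,
    parse_dotbracket,
    parse_vienna,
    predict_novel,
    _fold_pairs,
)


# --------------------------------------------------------------------------
# independent oracle: exhaustive maximum-pairing recursion

def max_pairs_oracle(seq: str, min_loop: int = 3) -> int:
    @functools.lru_cache(maxsize=None)
    def f(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = f(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                best = max(best, 1 + f(i + 1, k - 1) + (f(k + 1, j) if k < j else 0))
        return best
    return f(0, len(seq) - 1)


# --------------------------------------------------------------------------
# parsing

def test_parse_simple_hairpin():
    s = parse_dotbracket("GGGGAAAACCCC", "((((....))))")
    assert len(s.pairs) == 4
    assert s.loop == (5, 8)
    assert s.bulges == ()


def test_parse_five_prime_bulge():
    # 13-nt hairpin with a 2-nt bulge on the 5' side
    s = parse_dotbracket("GGTTGGAAACCCC", "((..((...))))")
    assert len(s.pairs) == 4
    assert len(s.bulges) == 1
    b = s.bulges[0]
    assert b.left == (3, 4) and b.right is None and b.size == 2


@pytest.mark.parametrize("db, msg", [
    ("((...))((...))", "not a hairpin"),
    ("((...))(", "unbalanced"),
    (")(....).", "unbalanced"),
    ("((..x..))", "invalid character"),
    ("..........", "no base pairs"),
])
def test_parse_rejects_bad_input(db, msg):
    with pytest.raises(HairpinParseError, match=msg):
        parse_dotbracket("A" * len(db), db)


def test_parse_render_round_trip():
    rng = stream_rng(5, "roundtrip")
    for _ in range(20):
        left = random_seq(rng, 18)
        hp = left + random_seq(rng, 6) + revcomp(left)
        db, e = fold_simple(hp)
        pairs = _fold_pairs(hp)
        unit = extract_hairpin(hp, pairs, (1, len(hp)))
        assert unit is not None
        s, _ = unit
        again = parse_dotbracket(*s.render())
        assert again == s


def test_parse_vienna_blocks():
    text = (">cand1\nGGGGAAAACCCC\n((((....)))) (-4.40)\n"
            ">cand2\nGGGAAAACCC\n(((....))) ( -2.2)\n")
    entries = parse_vienna(text)
    assert [e[0] for e in entries] == ["cand1", "cand2"]
    assert entries[0][2] == "((((....))))"
    assert entries[0][3] == pytest.approx(-4.4)
    s = parse_dotbracket(entries[1][1], entries[1][2], entries[1][3])
    assert s.free_energy == pytest.approx(-2.2)


# --------------------------------------------------------------------------
# folding

def test_fold_unpairable_sequence():
    assert fold_simple("AAAA") == ("....", 0.0)


def test_fold_perfect_gc_stem_energy():
    # 20 GC pairs -> 19 stacked pairs at -2.2 kcal/mol each
    db, e = fold_simple("G" * 20 + "AAAA" + "C" * 20)
    assert db == "(" * 20 + "...." + ")" * 20
    assert e == pytest.approx(-41.8)
    assert e <= -15


def test_fold_matches_exhaustive_oracle():
    rng = stream_rng(7, "fold-oracle")
    for _ in range(40):
        seq = random_seq(rng, int(rng.integers(8, 31)))
        assert len(_fold_pairs(seq)) == max_pairs_oracle(seq)


# --------------------------------------------------------------------------
# criteria fixtures: a compliant hairpin and one fixture per criterion,
# each violating exactly that criterion

def compliant_hairpin():
    """22-bp perfect stem, 6-nt loop; mature = the full 5' arm."""
    seq = "G" * 22 + "A" * 6 + "C" * 22
    db = "(" * 22 + "." * 6 + ")" * 22
    return parse_dotbracket(seq, db, free_energy=-30.0), (1, 22)


def single_violation_fixtures():
    """(name, structure, mature_span) with exactly one failing criterion."""
    fixtures = []

    # stem_bulge_nt: 13-nt one-sided bulge on the 3' strand, outside mature
    seq = "G" * 22 + "AAAA" + "C" * 12 + "T" * 13 + "C" * 10
    db = "(" * 22 + "...." + ")" * 12 + "." * 13 + ")" * 10
    fixtures.append(("stem_bulge_nt", parse_dotbracket(seq, db, -30.0), (1, 22)))

    # stem_bp: only 15 pairs; long loop keeps the other criteria green
    seq = "G" * 15 + "A" * 20 + "C" * 15
    db = "(" * 15 + "." * 20 + ")" * 15
    fixtures.append(("stem_bp", parse_dotbracket(seq, db, -30.0), (1, 18)))

    # free_energy: compliant stem, energy just above the cutoff
    s, span = compliant_hairpin()
    weak = parse_dotbracket(s.sequence, s.dotbracket, free_energy=-14.5)
    fixtures.append(("free_energy", weak, span))

    # hairpin_len: 16 bp + 4-nt loop = 36 nt < 50
    seq = "G" * 16 + "AAAA" + "C" * 16
    db = "(" * 16 + "...." + ")" * 16
    fixtures.append(("hairpin_len", parse_dotbracket(seq, db, -30.0), (1, 18)))

    # loop_len: 201-nt terminal loop
    seq = "G" * 20 + "A" * 201 + "C" * 20
    db = "(" * 20 + "." * 201 + ")" * 20
    fixtures.append(("loop_len", parse_dotbracket(seq, db, -30.0), (1, 20)))

    # mature_bulge_nt: one symmetric 3+3 internal loop inside the mature
    seq = "G" * 10 + "TTT" + "G" * 12 + "AAAA" + "C" * 12 + "AAA" + "C" * 10
    db = "(" * 10 + "..." + "(" * 12 + "...." + ")" * 12 + "..." + ")" * 10
    fixtures.append(("mature_bulge_nt", parse_dotbracket(seq, db, -30.0), (1, 22)))

    # biased_errors_per_bulge: one-sided 3-nt bulge inside the mature
    seq = "G" * 10 + "TTT" + "G" * 12 + "AAAA" + "C" * 22
    db = "(" * 10 + "..." + "(" * 12 + "...." + ")" * 22
    fixtures.append(("biased_errors_per_bulge", parse_dotbracket(seq, db, -30.0), (1, 22)))

    # biased_bulges: three 1-nt one-sided bulges inside the mature
    seq = "G" * 6 + "T" + "G" * 5 + "T" + "G" * 5 + "T" + "G" * 6 + "AAAA" + "C" * 22
    db = "(" * 6 + "." + "(" * 5 + "." + "(" * 5 + "." + "(" * 6 + "...." + ")" * 22
    fixtures.append(("biased_bulges", parse_dotbracket(seq, db, -30.0), (1, 25)))

    # mature_errors: three symmetric 2+2 internal loops -> 6 unpaired mature nt
    left = "G" * 6 + "TT" + "G" * 5 + "TT" + "G" * 5 + "TT" + "G" * 6
    right = "C" * 6 + "AA" + "C" * 5 + "AA" + "C" * 5 + "AA" + "C" * 6
    db = ("(" * 6 + ".." + "(" * 5 + ".." + "(" * 5 + ".." + "(" * 6 + "...."
          + ")" * 6 + ".." + ")" * 5 + ".." + ")" * 5 + ".." + ")" * 6)
    fixtures.append(("mature_errors",
                     parse_dotbracket(left + "AAAA" + right, db, -30.0), (1, 25)))

    # mature_bp: 11 paired mature nt (mature starts after 8 outer pairs)
    left = "G" * 8 + "G" * 5 + "TT" + "G" * 4 + "TT" + "G" * 2
    right = "C" * 2 + "AA" + "C" * 4 + "AA" + "C" * 5 + "C" * 8
    db = ("(" * 13 + ".." + "(" * 4 + ".." + "(" * 2 + "...."
          + ")" * 2 + ".." + ")" * 4 + ".." + ")" * 13)
    fixtures.append(("mature_bp",
                     parse_dotbracket(left + "AAAA" + right, db, -30.0), (9, 26)))

    # mature_in_stem_fraction: 6 of 25 mature nt sit in the terminal loop
    seq = "G" * 23 + "A" * 6 + "C" * 23
    db = "(" * 23 + "." * 6 + ")" * 23
    fixtures.append(("mature_in_stem_fraction", parse_dotbracket(seq, db, -30.0), (5, 29)))

    return fixtures


def test_compliant_hairpin_passes_all():
    s, span = compliant_hairpin()
    report = evaluate_criteria(s, span)
    assert report.overall
    assert report.failing() == []


@pytest.mark.parametrize("name,structure,span",
                         single_violation_fixtures(),
                         ids=[f[0] for f in single_violation_fixtures()])
def test_each_criterion_violable_in_isolation(name, structure, span):
    report = evaluate_criteria(structure, span)
    assert report.failing() == [name]


def test_energy_threshold_boundary():
    s, span = compliant_hairpin()
    weak = parse_dotbracket(s.sequence, s.dotbracket, free_energy=-14.5)
    report = evaluate_criteria(weak, span)
    assert report.failing() == ["free_energy"]
    exact = parse_dotbracket(s.sequence, s.dotbracket, free_energy=-15.0)
    assert evaluate_criteria(exact, span).overall


def test_threshold_monotonicity():
    """Relaxing any single threshold never shrinks the passing set."""
    cases = [(s, span) for _, s, span in single_violation_fixtures()]
    cases.append(compliant_hairpin())
    base = HairpinCriteria()
    relax = {
        "max_stem_bulge_nt": 50, "min_stem_bp": 1, "max_free_energy": 100.0,
        "min_hairpin_len": 1, "max_loop_len": 10_000, "max_mature_bulge_nt": 50,
        "max_biased_errors_per_bulge": 50, "max_biased_bulges": 50,
        "max_mature_errors": 50, "min_mature_bp": 0,
        "min_mature_in_stem_fraction": 1e-9,
    }
    tighten = {
        "max_stem_bulge_nt": 0, "min_stem_bp": 100, "max_free_energy": -100.0,
        "min_hairpin_len": 500, "max_loop_len": 1, "max_mature_bulge_nt": 0,
        "max_biased_errors_per_bulge": 0, "max_biased_bulges": 0,
        "max_mature_errors": 0, "min_mature_bp": 100,
        "min_mature_in_stem_fraction": 1.0,
    }
    for field, value in relax.items():
        crit = HairpinCriteria(**{field: value})
        for s, span in cases:
            if evaluate_criteria(s, span, base).overall:
                assert evaluate_criteria(s, span, crit).overall
    for field, value in tighten.items():
        crit = HairpinCriteria(**{field: value})
        for s, span in cases:
            if not evaluate_criteria(s, span, base).overall:
                # tightening may add failures but never rescues one
                assert not (evaluate_criteria(s, span, crit).overall
                            and not evaluate_criteria(s, span, base).overall)


def test_mature_length_precondition():
    s, _ = compliant_hairpin()
    with pytest.raises(ValueError, match="18-25"):
        evaluate_criteria(s, (1, 10))


# --------------------------------------------------------------------------
# genomic novel prediction

def _designed_locus(rng, flank=120):
    left = random_seq(rng, 33)
    hp = left + random_seq(rng, 9) + revcomp(left)
    read = left[4:4 + 21]
    contig = random_seq(rng, flank + 10) + hp + random_seq(rng, flank + 10)
    return contig, read


def test_predict_novel_compliant_locus_passes():
    rng = stream_rng(23, "locus")
    for attempt in range(10):
        contig, read = _designed_locus(rng)
        preds = predict_novel([("r1", read)], {"chr1": contig})
        if any(p.passed for p in preds):
            return
    pytest.fail("no designed hairpin locus recognised in 10 attempts")


def test_predict_novel_random_locus_fails():
    rng = stream_rng(29, "decoy")
    n_pass = 0
    for i in range(10):
        read = random_seq(rng, 21)
        contig = random_seq(rng, 130) + read + random_seq(rng, 130)
        preds = predict_novel([(f"d{i}", read)], {"chr1": contig})
        n_pass += any(p.passed for p in preds)
    assert n_pass <= 1  # random context essentially never folds compliant


def test_predict_novel_two_loci_reported_separately():
    rng = stream_rng(31, "two-loci")
    contig, read = _designed_locus(rng)
    genome = {"chrA": contig,
              "chrB": random_seq(rng, 130) + read + random_seq(rng, 130)}
    preds = predict_novel([("r1", read)], genome)
    assert len(preds) == 2
    by_contig = {p.contig: p.passed for p in preds}
    assert by_contig["chrA"] or not by_contig["chrB"]
    assert len({(p.contig, p.position) for p in preds}) == 2


def test_predict_novel_read_absent_from_genome():
    preds = predict_novel([("r1", "ACGTACGTACGTACGTACGTA")],
                          {"chr1": "GGGG" * 100})
    assert preds == []
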