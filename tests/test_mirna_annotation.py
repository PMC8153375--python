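"""Catalog mapping, isomiR naming, evidence groups and conservation tiers."""
from __future__ import annotations

import pytest

from mircms._util import stream_rng
from mircms.mirna_annotation import (
    MappingPolicy,
    MiRNAAnnotation,
    VariantError,
    annotate_reads,
    apply_variant,
    assign_group,
    classify_conservation,
    family_summary,
    map_to_catalog,
    name_variant,
    parse_variant_name,
)
from mircms.synthetic_data import (
    SimConfig,
    build_genome,
    make_catalog,
    simulate_srna_reads,
    _make_isomir,
)

MIR156B = "TGACAGAAGAGAGAGAGCACA"          # reference mature
MIR156B_VARIANT = "TTGACAGAAGAGAGAGAGCAC"  # shifted observed sequence


class FakeMature:
    def __init__(self, name, precursor_seq, start, end, family="miR156", arm="5p"):
        self.name = name
        self.family = family
        self.arm = arm
        self.precursor_seq = precursor_seq
        self.start = start
        self.end = end

    @property
    def sequence(self):
        return self.precursor_seq[self.start - 1:self.end]


@pytest.fixture
def mir156b_precursor():
    pre = "GGCT" + MIR156B + "GTGCTCTCTCTCTTCTGTCAGG"
    return FakeMature("gma-miR156b", pre, 5, 25)


# --------------------------------------------------------------------------
# catalog placement

def test_exact_mature_is_single_best_hit(mir156b_precursor):
    hits = map_to_catalog(MIR156B, [mir156b_precursor])
    assert hits and hits[0].mismatches == 0
    assert (hits[0].shift5, hits[0].shift3) == (0, 0)


def test_shifted_variant_hit(mir156b_precursor):
    """The printed shifted sequence maps with a +1 5' and -1 3' shift."""
    hits = map_to_catalog(MIR156B_VARIANT, [mir156b_precursor])
    assert hits
    best = hits[0]
    assert (best.shift5, best.shift3, best.mismatches) == (1, -1, 0)


def test_two_mismatches_rejected(mir156b_precursor):
    seq = list(MIR156B)
    seq[5] = "A" if seq[5] != "A" else "C"
    seq[10] = "A" if seq[10] != "A" else "C"
    assert map_to_catalog("".join(seq), [mir156b_precursor],
                          MappingPolicy(max_internal_mismatch=1)) == []


def test_empty_catalog_gives_no_hits():
    assert map_to_catalog(MIR156B, []) == []


def test_zero_policy_equals_exact_substring_oracle(small_catalog):
    policy = MappingPolicy(0, 0, 0)
    matures = small_catalog.matures("gma")
    rng = stream_rng(3, "zero-policy")
    probes = [m.sequence for m in matures[:4]]
    probes += ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(10)]
    for seq in probes:
        hits = map_to_catalog(seq, matures, policy)
        oracle = [m for m in matures if m.sequence == seq]
        assert {h.mature.name for h in hits} == {m.name for m in oracle}


# --------------------------------------------------------------------------
# variant naming

def test_variant_name_matches_printed_example(mir156b_precursor):
    name = name_variant(MIR156B_VARIANT, MIR156B, mir156b_precursor.precursor_seq)
    assert name == "L+1R-1"
    back = apply_variant(MIR156B, mir156b_precursor.precursor_seq, name)
    assert back == MIR156B_VARIANT


def test_identical_sequence_empty_name(mir156b_precursor):
    assert name_variant(MIR156B, MIR156B, mir156b_precursor.precursor_seq) == ""


def test_double_substitution_grammar():
    ref = "ACGTACGTACGTACGTACGT"
    pre = "AAAA" + ref + "TTTT"
    obs = list(ref)
    obs[0], obs[17] = "T", "A"  # ref bases A and C
    obs = "".join(obs)
    assert name_variant(obs, ref, pre) == "2ss1AT18CA"
    assert apply_variant(ref, pre, "2ss1AT18CA") == obs


def test_parse_variant_name_components():
    assert parse_variant_name("L+1R-1") == (1, -1, [])
    assert parse_variant_name("2ss1AT18CA") == (0, 0, [(1, "A", "T"), (18, "C", "A")])
    assert parse_variant_name("") == (0, 0, [])
    with pytest.raises(VariantError):
        parse_variant_name("X+1")
    with pytest.raises(VariantError):
        parse_variant_name("3ss1AT")  # count mismatch


def test_unanchored_variant_raises(mir156b_precursor):
    with pytest.raises(VariantError, match="unanchored"):
        name_variant("G" * 21, MIR156B, mir156b_precursor.precursor_seq)


def test_roundtrip_over_generated_isomirs(small_catalog):
    """Name -> apply reconstructs every generated isomiR."""
    rng = stream_rng(33, "isomir-roundtrip")
    n_done = 0
    while n_done < 1000:
        fam = small_catalog.families[n_done % len(small_catalog.families)]
        iso = _make_isomir(rng, fam)
        if iso is None:
            continue
        name = name_variant(iso, fam.mature_seq, fam.precursor_seq,
                            mature_start=fam.mature_span[0])
        back = apply_variant(fam.mature_seq, fam.precursor_seq, name,
                             mature_start=fam.mature_span[0])
        assert back == iso
        n_done += 1


# --------------------------------------------------------------------------
# evidence groups

@pytest.mark.parametrize("flags,expected", [
    # mature, precursor, other-species, genome, opposite, hairpin
    ((True, True, False, True, False, False), "gp1a"),
    ((True, True, False, False, False, False), "gp1b"),
    ((False, False, True, True, False, False), "gp2a"),
    ((False, True, False, True, True, False), "gp2b"),
    ((False, True, False, True, False, False), "gp3"),
    ((False, False, False, True, False, True), "gp4"),
])
def test_group_decision_tree(flags, expected):
    assert assign_group(*flags) == expected


def test_group_inconsistent_flags():
    with pytest.raises(ValueError, match="inconsistent"):
        assign_group(True, False, False, True, False, False)
    with pytest.raises(ValueError, match="inconsistent"):
        assign_group(False, False, False, True, True, False)


def test_group_no_evidence():
    with pytest.raises(ValueError, match="no evidence"):
        assign_group(False, False, False, False, False, False)


# --------------------------------------------------------------------------
# conservation

@pytest.mark.parametrize("n,expected", [
    (1, "non-conserved"), (2, "low"), (4, "low"), (5, "moderate"),
    (9, "moderate"), (10, "moderate"), (11, "high"), (12, "high"),
])
def test_conservation_tiers_total_over_membership_sizes(n, expected):
    membership = [f"sp{i:02d}" for i in range(n)]
    assert classify_conservation("miR999", membership) == expected


def test_conserved_list_overrides_membership():
    assert classify_conservation("miR166", ["gma", "ath"],
                                 conserved_families={"miR166"}) == "conserved"


def test_conservation_errors():
    with pytest.raises(ValueError):
        classify_conservation("miR1", [])
    with pytest.raises(ValueError):
        classify_conservation("miR1", [f"s{i}" for i in range(48)])


# --------------------------------------------------------------------------
# summaries and end-to-end annotation

def test_family_summary_sorted():
    anns = [MiRNAAnnotation("A" * 21, f"m{i}", fam, "5p", "gp1a", "", "high")
            for i, fam in enumerate(["miR166"] * 3 + ["miR156"])]
    tab = family_summary(anns)
    assert list(tab.itertuples(index=False, name=None)) == [("miR166", 3), ("miR156", 1)]
    assert family_summary([]).empty


def test_annotate_reads_recovers_truth_groups(small_config):
    cat = make_catalog(small_config)
    genome, truth = build_genome(cat, small_config)
    cfg = SimConfig(seed=41, n_families=small_config.n_families,
                    variant_rate=0.3, star_fraction=0.1, ncrna_fraction=0.0,
                    random_fraction=0.0, libraries=(("A", 1500),))
    reads, truth2 = simulate_srna_reads(cat, cfg)
    from mircms.srna_preprocess import preprocess_libraries
    unique, _ = preprocess_libraries(reads, cfg.adapter)
    annotations, unmapped = annotate_reads(unique, cat, genome)
    by_seq = {a.sequence: a for a in annotations}
    groups = {a.group for a in annotations}
    # every mature sequence is annotated gp1a with an empty variant name
    for fam in cat.families:
        if fam.mature_seq in by_seq:
            a = by_seq[fam.mature_seq]
            assert a.group == "gp1a"
            assert a.variant_name == ""
            assert a.family == fam.family
    # star-arm reads fall in the opposite-arm group
    star_hits = [by_seq[f.star_seq] for f in cat.families if f.star_seq in by_seq]
    assert star_hits and all(a.group == "gp2b" for a in star_hits)
    # each annotated read has exactly one group label
    assert groups <= {"gp1a", "gp1b", "gp2a", "gp2b", "gp3", "gp4"}
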