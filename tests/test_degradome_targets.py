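"""Degradome tag handling, duplex scoring and category classification."""
from __future__ import annotations

import functools

import numpy as np
import pytest

from mircms._util import random_seq, revcomp, stream_rng
from mircms.degradome_targets import (
    DuplexScoring,
    TPlot,
    categorize,
    compare_sets,
    find_cleavage_targets,
    map_tags,
    preprocess_degradome,
    score_duplex,
    TargetInteraction,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


# --------------------------------------------------------------------------
# oracles

def score_oracle(mirna: str, site: str, scoring: DuplexScoring = DuplexScoring()) -> float:
    """Exhaustive minimum over all gapped antiparallel alignments."""
    m, t = mirna, site[::-1]

    def pen(a, b):
        if (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
            return 0.0
        if (a, b) in {("G", "T"), ("T", "G")}:
            return scoring.wobble
        return scoring.mismatch

    @functools.lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i == len(m) and j == len(t):
            return 0.0
        fac = scoring.position_factor(min(i + 1, len(m)))
        best = float("inf")
        if i < len(m) and j < len(t):
            best = min(best, pen(m[i], t[j]) * scoring.position_factor(i + 1)
                       + f(i + 1, j + 1))
        if i < len(m):
            best = min(best, scoring.gap * scoring.position_factor(i + 1) + f(i + 1, j))
        if j < len(t):
            best = min(best, scoring.gap * fac + f(i, j + 1))
        return best

    return f(0, 0)


def categorize_oracle(pos: int, tplot: TPlot) -> int:
    """Literal re-evaluation of the category rules, in order 0..4."""
    c = tplot.abundance[pos]
    vals = list(tplot.abundance.values())
    M = max(vals)
    med = float(np.median(vals))
    if c == M and vals.count(M) == 1 and c > 1:
        return 0
    if c == M and c > 1:
        return 1
    if c < M and c > med:
        return 2
    if c <= med and c > 1:
        return 3
    assert c == 1
    return 4


# --------------------------------------------------------------------------
# preprocessing / mapping

def test_tag_length_boundaries():
    recs = [("a", "A" * 14 + ADAPTER, ""), ("b", "ACGTACGTACGTACG" + ADAPTER, ""),
            ("c", ADAPTER, "")]
    tags = preprocess_degradome(recs, ADAPTER)
    assert tags == ["ACGTACGTACGTACG"]  # 15 nt kept, 14 nt and dimer removed


def test_map_tags_counts_and_rate():
    tx = {"t1": "A" * 99 + "ACGTACGTACGTACGTACGT" + "A" * 50}
    tag = "ACGTACGTACGTACGTACGT"
    tplots, rate = map_tags([tag] * 7 + ["G" * 20], tx)
    assert tplots["t1"].abundance == {100: 7}
    assert rate == pytest.approx(7 / 8)


def test_map_tags_multimapping_counted_everywhere():
    site = "ACGTTGCAACGTTGCAACG"
    tx = {"t1": site + "AAAA" + site}
    tplots, _ = map_tags([site], tx)
    assert tplots["t1"].abundance == {1: 1, len(site) + 5: 1}


def test_map_tags_requires_transcripts():
    with pytest.raises(ValueError):
        map_tags(["ACGT"], {})


# --------------------------------------------------------------------------
# duplex scoring

def test_perfect_complement_scores_zero():
    m = "TGACAGAAGAGAGAGAGCACA"
    assert score_duplex(m, revcomp(m)) == 0.0


def test_wobble_penalty_doubled_in_seed_region():
    m = list("TGACAGAAGAGAGAGAGCACA")
    # G:T wobble opposite miRNA position 20 (outside 2-13) and 5 (inside)
    m20 = m.copy(); m20[19] = "G"
    s20 = list(revcomp("".join(m20))); s20[1] = "T"
    assert score_duplex("".join(m20), "".join(s20)) == pytest.approx(0.5)
    m5 = m.copy(); m5[4] = "G"
    s5 = list(revcomp("".join(m5))); s5[len(m) - 5] = "T"
    assert score_duplex("".join(m5), "".join(s5)) == pytest.approx(1.0)


def test_mismatch_doubling_positions_2_vs_20():
    m = "TGACAGAAGAGAGAGAGCACA"
    site = revcomp(m)

    def mutate_site_opposite(pos):  # break pairing at miRNA position pos
        s = list(site)
        idx = len(m) - pos  # site index pairing miRNA pos (0-based)
        orig = m[pos - 1]
        # choose a base that neither Watson-Crick- nor wobble-pairs
        for b in "ACGT":
            sb = s[idx]
            trial = b
            if trial != s[idx]:
                pair = (orig, trial)
                if pair not in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                                ("G", "T"), ("T", "G")}:
                    s[idx] = trial
                    return "".join(s)
        raise AssertionError
    assert score_duplex(m, mutate_site_opposite(2)) == pytest.approx(2.0)
    assert score_duplex(m, mutate_site_opposite(20)) == pytest.approx(1.0)


def test_score_matches_exhaustive_oracle_short_duplexes():
    rng = stream_rng(55, "duplex-oracle")
    for _ in range(120):
        n = int(rng.integers(6, 13))
        m = random_seq(rng, n)
        site = list(revcomp(m))
        for _ in range(int(rng.integers(0, 4))):  # sprinkle mutations
            site[int(rng.integers(0, n))] = "ACGT"[int(rng.integers(0, 4))]
        site = "".join(site)
        assert score_duplex(m, site) == pytest.approx(score_oracle(m, site))


def test_score_symmetry_without_wobbles():
    """Swapping strands of a wobble-free duplex preserves the score."""
    rng = stream_rng(56, "duplex-sym")
    done = 0
    while done < 30:
        n = int(rng.integers(8, 13))
        m = random_seq(rng, n)
        site = list(revcomp(m))
        k = int(rng.integers(0, n))
        b = "ACGT"[int(rng.integers(0, 4))]
        pair = (m[n - 1 - k], b)
        # G:U wobbles are not complement-invariant by design: exclude pairs
        # that are wobbles in either orientation (A:C complements to G:U)
        if pair in {("G", "T"), ("T", "G"), ("A", "C"), ("C", "A")}:
            continue
        site[k] = b
        site = "".join(site)
        assert score_duplex(m, site) == pytest.approx(
            score_duplex(revcomp(site), revcomp(m)))
        done += 1


# --------------------------------------------------------------------------
# categorisation

def test_category_worked_examples():
    tp = TPlot("t", 400, {100: 9, 200: 2, 300: 1})
    assert categorize(100, tp) == 0
    assert categorize(200, tp) == 3
    assert categorize(300, tp) == 4
    tied = TPlot("t", 400, {100: 5, 200: 5})
    assert categorize(100, tied) == 1


def test_categorize_requires_tags():
    with pytest.raises(ValueError):
        categorize(50, TPlot("t", 100, {10: 3}))


def test_categorize_matches_bruteforce_on_random_profiles():
    rng = stream_rng(57, "categories")
    for _ in range(500):
        n_pos = int(rng.integers(1, 12))
        positions = rng.choice(np.arange(1, 200), size=n_pos, replace=False)
        tp = TPlot("t", 200, {int(p): int(rng.integers(1, 20)) for p in positions})
        for pos in tp.abundance:
            got = categorize(pos, tp)
            assert got == categorize_oracle(pos, tp)
            assert got in (0, 1, 2, 3, 4)


# --------------------------------------------------------------------------
# target discovery

def _toy_target_setup():
    rng = stream_rng(58, "targets")
    m = random_seq(rng, 21)
    tx = {"t1": random_seq(rng, 80) + revcomp(m) + random_seq(rng, 60)}
    site_start = 81
    cleavage = site_start + 21 - 10  # opposite miRNA position 10
    return m, tx, cleavage


def test_find_targets_at_planted_site():
    m, tx, cleavage = _toy_target_setup()
    tag = tx["t1"][cleavage - 1:cleavage + 19]
    tplots, _ = map_tags([tag] * 6, tx)
    found = find_cleavage_targets({"miR-x": m}, tplots, tx)
    assert any(it.cleavage_pos == cleavage and it.alignment_score == 0.0
               for it in found)


def test_max_score_zero_keeps_only_perfect_complements():
    m, tx, cleavage = _toy_target_setup()
    tag = tx["t1"][cleavage - 1:cleavage + 19]
    mutated = list(m); mutated[0] = "A" if m[0] != "A" else "C"
    tplots, _ = map_tags([tag] * 3, tx)
    strict = find_cleavage_targets({"perfect": m, "off": "".join(mutated)},
                                   tplots, tx, max_score=0.0)
    assert {it.mirna for it in strict} <= {"perfect"}


def test_raising_max_score_never_removes_interactions():
    m, tx, cleavage = _toy_target_setup()
    tag = tx["t1"][cleavage - 1:cleavage + 19]
    mutated = list(m); mutated[3] = "A" if m[3] != "A" else "C"
    tplots, _ = map_tags([tag] * 3, tx)
    mirnas = {"a": m, "b": "".join(mutated)}
    keys = lambda found: {(it.mirna, it.cleavage_pos) for it in found}
    low = keys(find_cleavage_targets(mirnas, tplots, tx, max_score=0.0))
    mid = keys(find_cleavage_targets(mirnas, tplots, tx, max_score=2.0))
    high = keys(find_cleavage_targets(mirnas, tplots, tx, max_score=4.0))
    assert low <= mid <= high


# --------------------------------------------------------------------------
# two-library comparison

def _fake_interaction(gene):
    return TargetInteraction("m", gene, (1, 21), 0.0, 12, 0, 5)


def test_compare_sets_partition():
    a = [_fake_interaction(g) for g in ("g1", "g2")]
    b = [_fake_interaction(g) for g in ("g2", "g3")]
    venn = compare_sets(a, b)
    assert (venn["n_unique_a"], venn["n_unique_b"], venn["n_common"]) == (1, 1, 1)
    assert venn["common"] == ["g2"]
    same = compare_sets(a, a)
    assert (same["n_unique_a"], same["n_unique_b"], same["n_common"]) == (0, 0, 2)
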