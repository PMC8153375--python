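"""Degradome (PARE) target calling: t-plots, duplex scoring, categories.

Degradome tags mark uncapped mRNA 5' ends; miRNA-guided cleavage leaves a
pile-up at the transcript position opposite miRNA positions 10-11.  The
workflow: trim and length-filter tags (>= 15 nt), map them exactly to the
transcriptome to build per-transcript t-plots, score the miRNA:site duplex
with the Allen-convention penalties (mismatch 1, G:U wobble 0.5, gap 1, all
doubled at miRNA positions 2-13), keep sites with score <= 4 whose cleavage
position carries tags, and classify each interaction by the relative tag
abundance at the site:

* category 0 - site is the unique transcript maximum, count > 1
* category 1 - site ties the maximum (non-unique), count > 1
* category 2 - below the maximum but above the median of tagged positions
* category 3 - at or below that median, count > 1
* category 4 - a single tag

The median is over positions with non-zero tags; categories are evaluated
in the order 0, 1, 2, 3, 4, which resolves the all-equal edge toward 1.
The cleavage position is the transcript nucleotide paired to miRNA
position 10 (1-based, 5'->3': the canonical 10-11 cut).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import to_dna
from .srna_preprocess import trim_adapter

__all__ = [
    "TPlot",
    "TargetInteraction",
    "DuplexScoring",
    "preprocess_degradome",
    "map_tags",
    "score_duplex",
    "find_cleavage_targets",
    "categorize",
    "compare_sets",
]


@dataclass
class TPlot:
    """Per-transcript degradome profile: tag 5'-end counts by position."""

    transcript_id: str
    length: int
    abundance: dict[int, int] = field(default_factory=dict)

    def add(self, pos: int, n: int = 1) -> None:
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside transcript")
        self.abundance[pos] = self.abundance.get(pos, 0) + n


@dataclass(frozen=True)
class DuplexScoring:
    """Penalty scheme for miRNA:target alignment (CleaveLand/Allen style)."""

    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 1.0
    doubled_start: int = 2
    doubled_end: int = 13

    def position_factor(self, mirna_pos: int) -> float:
        return 2.0 if self.doubled_start <= mirna_pos <= self.doubled_end else 1.0


@dataclass(frozen=True)
class TargetInteraction:
    mirna: str
    transcript_id: str
    site: tuple[int, int]       # 1-based inclusive span on the transcript
    alignment_score: float
    cleavage_pos: int           # transcript nt opposite miRNA position 10
    category: int
    tag_count: int

    @property
    def gene(self) -> str:
        return self.transcript_id


# --------------------------------------------------------------------------
# tag preprocessing and mapping

def preprocess_degradome(records: Iterable[tuple[str, str, str]], adapter: str,
                         min_len: int = 15, min_overlap: int = 6) -> list[str]:
    """Adapter-trim degradome reads and keep tags of >= ``min_len`` nt."""
    tags: list[str] = []
    for _, seq, _qual in records:
        insert, status = trim_adapter(seq, adapter, min_overlap)
        if status == "dimer":
            continue
        tag = to_dna(insert)
        if len(tag) >= min_len:
            tags.append(tag)
    return tags


def map_tags(tags: Sequence[str], transcripts: Mapping[str, str]
             ) -> tuple[dict[str, TPlot], float]:
    """Exact-match tag placement; returns t-plots and the mapping rate.

    Multi-mapping tags are counted at every matching locus; the mapping
    rate is the fraction of tags with at least one placement.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    seqs = {tid: to_dna(seq) for tid, seq in transcripts.items()}
    tplots = {tid: TPlot(tid, len(seq)) for tid, seq in seqs.items()}
    mapped = 0
    for tag in tags:
        any_hit = False
        for tid in sorted(seqs):
            seq = seqs[tid]
            start = 0
            while True:
                idx = seq.find(tag, start)
                if idx < 0:
                    break
                tplots[tid].add(idx + 1)
                any_hit = True
                start = idx + 1
        mapped += any_hit
    rate = mapped / len(tags) if tags else 0.0
    return tplots, rate


# --------------------------------------------------------------------------
# duplex scoring

def _pair_penalty(m: str, t: str, scoring: DuplexScoring) -> float:
    if (m, t) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
        return 0.0
    if (m, t) in {("G", "T"), ("T", "G")}:
        return scoring.wobble
    return scoring.mismatch


def score_duplex(mirna: str, target_site: str,
                 scoring: DuplexScoring = DuplexScoring()) -> float:
    """Minimum penalty over all gapped antiparallel alignments of the duplex.

    The miRNA is read 5'->3'; the target site (5'->3') pairs antiparallel,
    so the site is reversed before alignment.  Gap penalties take the
    position factor of the current miRNA position.  A perfect complement
    scores 0.
    """
    m = to_dna(mirna)
    t = to_dna(target_site)[::-1]  # antiparallel: miRNA 5' vs site 3'
    nm, nt = len(m), len(t)
    INF = float("inf")
    dp = np.full((nm + 1, nt + 1), INF)
    dp[0, 0] = 0.0
    for i in range(nm + 1):
        fac = scoring.position_factor(i) if i >= 1 else scoring.position_factor(1)
        for j in range(nt + 1):
            cur = dp[i, j]
            if cur == INF:
                continue
            if i < nm and j < nt:
                pen = _pair_penalty(m[i], t[j], scoring) * scoring.position_factor(i + 1)
                dp[i + 1, j + 1] = min(dp[i + 1, j + 1], cur + pen)
            if i < nm:  # miRNA base unpaired (gap in target)
                dp[i + 1, j] = min(dp[i + 1, j],
                                   cur + scoring.gap * scoring.position_factor(i + 1))
            if j < nt:  # target base unpaired (gap in miRNA)
                dp[i, j + 1] = min(dp[i, j + 1],
                                   cur + scoring.gap * scoring.position_factor(min(i + 1, nm)))
    return float(dp[nm, nt])


# --------------------------------------------------------------------------
# site discovery and categorisation

def categorize(cleavage_pos: int, tplot: TPlot) -> int:
    """Category 0-4 from the relative tag abundance at the cleavage site."""
    c = tplot.abundance.get(cleavage_pos, 0)
    if c < 1:
        raise ValueError("no tags at the cleavage position")
    counts = sorted(tplot.abundance.values())
    maximum = counts[-1]
    med = float(np.median(counts))
    if c == maximum and c > 1:
        unique = sum(1 for v in counts if v == maximum) == 1
        return 0 if unique else 1
    if c < maximum and c > med:
        return 2
    if c <= med and c > 1:
        return 3
    return 4


def find_cleavage_targets(mirnas: Mapping[str, str], tplots: Mapping[str, TPlot],
                          transcripts: Mapping[str, str],
                          max_score: float = 4.0, min_tags: int = 1,
                          scoring: DuplexScoring = DuplexScoring()
                          ) -> list[TargetInteraction]:
    """Score candidate sites anchored at tagged positions; keep score <= 4.

    For every transcript position carrying >= ``min_tags`` tags and every
    miRNA, the unique site window placing miRNA position 10 opposite that
    position is scored; qualifying sites yield one categorised interaction.
    """
    out: list[TargetInteraction] = []
    for tid in sorted(tplots):
        tp = tplots[tid]
        seq = to_dna(transcripts[tid])
        for pos in sorted(tp.abundance):
            n_tags = tp.abundance[pos]
            if n_tags < min_tags:
                continue
            for name in sorted(mirnas):
                m = to_dna(mirnas[name])
                L = len(m)
                end = pos + 9          # miRNA position 10 pairs `pos`
                start = end - L + 1
                if start < 1 or end > len(seq):
                    continue
                score = score_duplex(m, seq[start - 1:end], scoring)
                if score <= max_score:
                    out.append(TargetInteraction(
                        mirna=name, transcript_id=tid, site=(start, end),
                        alignment_score=score, cleavage_pos=pos,
                        category=categorize(pos, tp), tag_count=n_tags))
    return out


def compare_sets(targets_a: Iterable[TargetInteraction],
                 targets_b: Iterable[TargetInteraction]) -> dict:
    """Two-library Venn partition of target genes.

    Returns unique/common gene lists and counts; the counts satisfy
    |unique_a| + |common| = |genes(A)| and likewise for B.
    """
    genes_a = {t.gene for t in targets_a}
    genes_b = {t.gene for t in targets_b}
    common = genes_a & genes_b
    return {
        "unique_a": sorted(genes_a - common),
        "unique_b": sorted(genes_b - common),
        "common": sorted(common),
        "n_unique_a": len(genes_a - common),
        "n_unique_b": len(genes_b - common),
        "n_common": len(common),
    }
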