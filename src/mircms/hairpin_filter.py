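"""Pre-miRNA hairpin prediction and the 11 structural criteria.

Novel plant miRNAs are accepted only when the genomic locus of an unmapped
small-RNA read folds into a qualifying stem-loop.  This module provides

* a deterministic maximum-pairing folder (`fold_simple`, Nussinov dynamic
  programming over Watson-Crick + G:U pairs) with a simple per-stacked-pair
  energy model,
* a dot-bracket parser producing an annotated `HairpinStructure`
  (pairs, terminal loop, bulges), including a parser for Vienna/RNAfold
  output files so externally computed structures can be used instead,
* `evaluate_criteria`, the engine applying the 11 hairpin criteria
  (stem bulge size, stem pairing, free energy, hairpin and loop lengths and
  the six mature-region rules),
* `predict_novel`, which locates reads on a genome, folds the read±flank
  windows, extracts the stem-loop containing the read and applies the
  criteria.

Coordinates are 1-based inclusive throughout structure reporting.
"""
from __future__ import annotations

import functools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import to_dna

__all__ = [
    "HairpinCriteria",
    "HairpinStructure",
    "CriteriaReport",
    "NovelPrediction",
    "HairpinParseError",
    "parse_dotbracket",
    "parse_vienna",
    "fold_simple",
    "evaluate_criteria",
    "extract_hairpin",
    "predict_novel",
    "CRITERIA_NAMES",
]


class HairpinParseError(ValueError):
    """Raised for malformed dot-bracket input or non-hairpin topologies."""


# --------------------------------------------------------------------------
# criteria thresholds

@dataclass(frozen=True)
class HairpinCriteria:
    """Thresholds of the 11 structural criteria for a candidate pre-miRNA.

    Units: nucleotides for lengths/bulges, base pairs for pairing counts,
    kcal/mol for free energy.  ``max_free_energy`` is an upper bound (more
    negative = more stable).
    """

    max_stem_bulge_nt: int = 12
    min_stem_bp: int = 16
    max_free_energy: float = -15.0
    min_hairpin_len: int = 50
    max_loop_len: int = 200
    max_mature_bulge_nt: int = 4
    max_biased_errors_per_bulge: int = 2
    max_biased_bulges: int = 2
    max_mature_errors: int = 4
    min_mature_bp: int = 12
    min_mature_in_stem_fraction: float = 0.80

    def __post_init__(self):
        if not (0.0 < self.min_mature_in_stem_fraction <= 1.0):
            raise ValueError("min_mature_in_stem_fraction must be in (0, 1]")


CRITERIA_NAMES = (
    "stem_bulge_nt",
    "stem_bp",
    "free_energy",
    "hairpin_len",
    "loop_len",
    "mature_bulge_nt",
    "biased_errors_per_bulge",
    "biased_bulges",
    "mature_errors",
    "mature_bp",
    "mature_in_stem_fraction",
)


# --------------------------------------------------------------------------
# structures

@dataclass(frozen=True)
class Bulge:
    """Unpaired region between two consecutive stem pairs.

    ``left``/``right`` are 1-based inclusive spans of the unpaired run on the
    5' and 3' side of the stem; a one-sided bulge has one empty side (None).
    """

    left: tuple[int, int] | None
    right: tuple[int, int] | None

    @property
    def left_len(self) -> int:
        return 0 if self.left is None else self.left[1] - self.left[0] + 1

    @property
    def right_len(self) -> int:
        return 0 if self.right is None else self.right[1] - self.right[0] + 1

    @property
    def size(self) -> int:
        """Total unpaired nucleotides in the bulge, both strands."""
        return self.left_len + self.right_len

    @property
    def one_sided(self) -> bool:
        return (self.left is None) != (self.right is None)

    def positions(self) -> set[int]:
        pos: set[int] = set()
        if self.left is not None:
            pos.update(range(self.left[0], self.left[1] + 1))
        if self.right is not None:
            pos.update(range(self.right[0], self.right[1] + 1))
        return pos


@dataclass(frozen=True)
class HairpinStructure:
    """A single stem-loop: sequence, pairing and derived annotation.

    ``pairs`` is the nesting chain ordered outermost-first, 1-based (i, j)
    with i < j.  ``span`` is the outermost pair, ``loop`` the terminal-loop
    span enclosed by the innermost pair.  Bases outside ``span`` are
    external and belong to neither stem nor loop.
    """

    sequence: str
    dotbracket: str
    free_energy: float
    pairs: tuple[tuple[int, int], ...]
    span: tuple[int, int]
    loop: tuple[int, int]
    bulges: tuple[Bulge, ...]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def paired_positions(self) -> set[int]:
        return {p for ij in self.pairs for p in ij}

    @property
    def stem_positions(self) -> set[int]:
        """Everything inside the outermost pair except the terminal loop."""
        lo, hi = self.span
        la, lb = self.loop
        return {p for p in range(lo, hi + 1) if not la <= p <= lb}

    def render(self) -> tuple[str, str, float]:
        """(sequence, dot-bracket, energy) triple; inverse of parsing."""
        return self.sequence, self.dotbracket, self.free_energy


# --------------------------------------------------------------------------
# energy model

#: Stacking free-energy increments (kcal/mol) credited for each pair whose
#: inward neighbour is also paired, keyed by the pair's own identity.
STACK_ENERGY = {"GC": -2.2, "AU": -1.1, "GU": -0.6}


def _pair_kind(a: str, b: str) -> str | None:
    s = {a, b}
    if s == {"G", "C"}:
        return "GC"
    if s == {"A", "T"}:
        return "AU"
    if s == {"G", "T"}:
        return "GU"
    return None


def stacking_energy(sequence: str, pairs: Iterable[tuple[int, int]],
                    model: Mapping[str, float] = STACK_ENERGY) -> float:
    """Energy of a structure under the per-stacked-pair model.

    Each pair (i, j) with (i+1, j-1) also paired contributes the increment
    for its own pair type; isolated pairs contribute nothing.
    """
    seq = to_dna(sequence)
    pairset = set(pairs)
    total = 0.0
    for i, j in pairset:
        if (i + 1, j - 1) in pairset:
            kind = _pair_kind(seq[i - 1], seq[j - 1])
            if kind is not None:
                total += model[kind]
    return round(total, 6)


# --------------------------------------------------------------------------
# dot-bracket parsing

def _match_brackets(dotbracket: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise HairpinParseError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch not in ".,":
            raise HairpinParseError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise HairpinParseError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def _terminal_pairs(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pairs enclosing no other pair (the closing pairs of terminal loops)."""
    out = []
    for i, j in pairs:
        if not any(i < k and l < j for k, l in pairs if (k, l) != (i, j)):
            out.append((i, j))
    return out


def _chain_bulges(chain: Sequence[tuple[int, int]]) -> tuple[Bulge, ...]:
    bulges = []
    for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
        left = (i1 + 1, i2 - 1) if i2 - i1 > 1 else None
        right = (j2 + 1, j1 - 1) if j1 - j2 > 1 else None
        if left is not None or right is not None:
            bulges.append(Bulge(left, right))
    return tuple(bulges)


def _structure_from_chain(sequence: str, pairs: Sequence[tuple[int, int]],
                          free_energy: float | None,
                          dotbracket: str | None = None) -> HairpinStructure:
    chain = sorted(pairs)
    inner_i, inner_j = chain[-1]
    if inner_j - inner_i < 2:
        raise HairpinParseError("terminal loop is empty")
    if dotbracket is None:
        chars = ["."] * len(sequence)
        for i, j in chain:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        dotbracket = "".join(chars)
    if free_energy is None:
        free_energy = stacking_energy(sequence, chain)
    return HairpinStructure(
        sequence=to_dna(sequence),
        dotbracket=dotbracket,
        free_energy=free_energy,
        pairs=tuple(chain),
        span=chain[0],
        loop=(inner_i + 1, inner_j - 1),
        bulges=_chain_bulges(chain),
    )


def parse_dotbracket(sequence: str, dotbracket: str,
                     free_energy: float | None = None) -> HairpinStructure:
    """Parse a dot-bracket string into an annotated hairpin.

    Rejects unbalanced brackets and any topology with more than one terminal
    loop ("not a hairpin").  When ``free_energy`` is not given it is
    computed from the stacking model.
    """
    if len(sequence) != len(dotbracket):
        raise HairpinParseError("sequence and dot-bracket lengths differ")
    pairs = _match_brackets(dotbracket)
    if not pairs:
        raise HairpinParseError("not a hairpin: no base pairs")
    if len(_terminal_pairs(pairs)) != 1:
        raise HairpinParseError("not a hairpin: more than one terminal loop")
    return _structure_from_chain(sequence, pairs, free_energy, dotbracket)


_VIENNA_ENERGY = re.compile(r"^(?P<db>[().,]+)\s*\(\s*(?P<dg>-?\d+(?:\.\d+)?)\s*\)\s*$")


def parse_vienna(text: str) -> list[tuple[str, str, str, float]]:
    """Parse RNAfold-style output: name / sequence / dot-bracket (-dG) blocks.

    Returns (name, sequence, dotbracket, free_energy) tuples.  Entries whose
    structure line lacks an energy annotation get energy from the stacking
    model via `parse_dotbracket` downstream (here reported as nan).
    """
    out = []
    name, seq = None, None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            seq = None
        elif set(line) <= set("ACGTUNacgtun") and seq is None:
            seq = to_dna(line)
        else:
            m = _VIENNA_ENERGY.match(line)
            if m is None:
                db, energy = line.split()[0], float("nan")
            else:
                db, energy = m.group("db"), float(m.group("dg"))
            if seq is None:
                raise HairpinParseError("structure line before sequence line")
            out.append((name or f"seq{len(out) + 1}", seq, db, energy))
            name, seq = None, None
    return out


# --------------------------------------------------------------------------
# folding: maximum-pairing nested structure (Nussinov DP)

@functools.lru_cache(maxsize=8192)
def _nussinov_cached(seq: str, min_loop: int) -> tuple[tuple[int, int], ...]:
    n = len(seq)
    if n == 0:
        return ()
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    A, C, G, T = (ord(x) for x in "ACGT")
    P = np.zeros((n, n), dtype=bool)
    for a, b in ((A, T), (T, A), (G, C), (C, G), (G, T), (T, G)):
        P |= (codes[:, None] == a) & (codes[None, :] == b)

    # D[l][i] = max pairs in seq[i .. i+l]; diagonal storage keeps the
    # bifurcation inner loop on contiguous slices
    D = [np.zeros(n - l, dtype=np.int32) for l in range(n)]
    for l in range(min_loop + 1, n):
        m = n - l
        best = np.maximum(D[l - 1][1:1 + m], D[l - 1][:m])
        pd = P[np.arange(m), np.arange(l, l + m)]
        stacked = D[l - 2][1:1 + m] + 1
        np.maximum(best, np.where(pd, stacked, -1), out=best)
        for t in range(min_loop + 1, l - min_loop - 1):
            cand = D[t][:m] + D[l - t - 1][t + 1:t + 1 + m]
            np.maximum(best, cand, out=best)
        D[l] = best

    def M(i: int, j: int) -> int:
        return int(D[j - i][i]) if j > i else 0

    # deterministic traceback; prefers closing (i, j) so helices extend
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        m = M(i, j)
        if m == 0:
            continue
        if P[i, j] and m == M(i + 1, j - 1) + 1:
            pairs.append((i + 1, j + 1))
            stack.append((i + 1, j - 1))
        elif m == M(i + 1, j):
            stack.append((i + 1, j))
        elif m == M(i, j - 1):
            stack.append((i, j - 1))
        else:
            for k in range(i + min_loop + 1, j - min_loop - 1):
                if m == M(i, k) + M(k + 1, j):
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
            else:  # pragma: no cover - recurrence guarantees a split exists
                raise AssertionError("traceback failed")
    return tuple(sorted(pairs))


def fold_simple(sequence: str, min_loop: int = 3,
                energy_model: Mapping[str, float] = STACK_ENERGY
                ) -> tuple[str, float]:
    """Fold into the maximum-pairing nested structure.

    Dynamic programming over Watson-Crick + G:U pairs with at least
    ``min_loop`` unpaired bases in every hairpin loop; ties broken by a
    deterministic traceback that prefers extending helices.  The energy is
    the per-stacked-pair approximation (`stacking_energy`), not a
    thermodynamic minimum.
    """
    seq = to_dna(sequence)
    pairs = _nussinov_cached(seq, min_loop)
    chars = ["."] * len(seq)
    for i, j in pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars), stacking_energy(seq, pairs, energy_model)


def _fold_pairs(sequence: str, min_loop: int = 3) -> tuple[tuple[int, int], ...]:
    return _nussinov_cached(to_dna(sequence), min_loop)


# --------------------------------------------------------------------------
# stem-loop extraction from a general (possibly branched) fold

def extract_hairpin(sequence: str, pairs: Sequence[tuple[int, int]],
                    span: tuple[int, int]) -> tuple[HairpinStructure, int] | None:
    """Carve the stem-loop unit containing ``span`` out of a general fold.

    From each terminal loop the enclosing helix chain is walked outward while
    it stays unbranched; the resulting units partition the paired regions.
    Returns the unit overlapping ``span`` (and its 0-based offset in
    ``sequence``), or None when the span touches no stem-loop.
    """
    if not pairs:
        return None
    ordered = sorted(pairs, key=lambda p: (p[0], -p[1]))
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in ordered:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        par = stack[-1] if stack else None
        parent[p] = par
        children.setdefault(par, []).append(p)
        children.setdefault(p, [])
        stack.append(p)

    units: list[tuple[tuple[int, int], tuple[int, int]]] = []  # (outer, terminal)
    for p in ordered:
        if children[p]:
            continue
        outer = p
        while parent[outer] is not None and len(children[parent[outer]]) == 1:
            outer = parent[outer]
        units.append((outer, p))

    a, b = span
    best = None
    for outer, term in units:
        lo, hi = outer
        overlap = min(hi, b) - max(lo, a) + 1
        if overlap > 0 and (best is None or overlap > best[0]):
            best = (overlap, outer)
    if best is None:
        return None
    lo, hi = best[1]
    chain = [(i - lo + 1, j - lo + 1) for i, j in ordered if lo <= i and j <= hi]
    sub = _structure_from_chain(sequence[lo - 1:hi], chain, None)
    return sub, lo - 1


# --------------------------------------------------------------------------
# criteria evaluation

@dataclass(frozen=True)
class CriteriaReport:
    """Measured values and pass flags for the 11 hairpin criteria."""

    values: dict[str, float]
    passed: dict[str, bool]
    overall: bool

    def failing(self) -> list[str]:
        return [name for name in CRITERIA_NAMES if not self.passed[name]]


def evaluate_criteria(structure: HairpinStructure, mature_span: tuple[int, int],
                      criteria: HairpinCriteria = HairpinCriteria(),
                      mature_total_len: int | None = None) -> CriteriaReport:
    """Apply the 11 criteria to a hairpin with a candidate mature region.

    ``mature_span`` is 1-based inclusive on ``structure.sequence`` (it may be
    clipped to the structure when the mature read extends beyond an
    extracted stem-loop; pass the full read length as ``mature_total_len``
    so the in-stem fraction is computed over the whole read).  Definitions:

    * a *mature bulge* is a stem bulge with at least one unpaired nucleotide
      inside the mature span; its size counts both strands,
    * *biased errors in one bulge* = |5'-side − 3'-side| unpaired counts,
    * a *biased bulge* has all unpaired nucleotides on one strand,
    * *errors in the mature region* = unpaired mature nucleotides lying in
      the stem (loop overhang is penalised by the in-stem fraction instead),
    * *hairpin length* = nucleotides from the outermost pair to its partner
      (stems, bulges and terminal loop).
    """
    ms, me = mature_span
    n_mature = mature_total_len if mature_total_len is not None else me - ms + 1
    if not (18 <= n_mature <= 25):
        raise ValueError(f"mature length {n_mature} outside 18-25 nt")

    n = len(structure)
    mature = {p for p in range(ms, me + 1) if 1 <= p <= n}
    paired = structure.paired_positions
    stem = structure.stem_positions

    mature_bulges = [b for b in structure.bulges if b.positions() & mature]

    values: dict[str, float] = {
        "stem_bulge_nt": float(max((b.size for b in structure.bulges), default=0)),
        "stem_bp": float(len(structure.pairs)),
        "free_energy": float(structure.free_energy),
        "hairpin_len": float(structure.span[1] - structure.span[0] + 1),
        "loop_len": float(structure.loop[1] - structure.loop[0] + 1),
        "mature_bulge_nt": float(max((b.size for b in mature_bulges), default=0)),
        "biased_errors_per_bulge": float(
            max((abs(b.left_len - b.right_len) for b in mature_bulges), default=0)),
        "biased_bulges": float(sum(1 for b in mature_bulges if b.one_sided)),
        "mature_errors": float(sum(1 for p in mature if p in stem and p not in paired)),
        "mature_bp": float(sum(1 for p in mature if p in paired)),
        "mature_in_stem_fraction": sum(1 for p in mature if p in stem) / n_mature,
    }
    c = criteria
    passed = {
        "stem_bulge_nt": values["stem_bulge_nt"] <= c.max_stem_bulge_nt,
        "stem_bp": values["stem_bp"] >= c.min_stem_bp,
        "free_energy": values["free_energy"] <= c.max_free_energy,
        "hairpin_len": values["hairpin_len"] >= c.min_hairpin_len,
        "loop_len": values["loop_len"] <= c.max_loop_len,
        "mature_bulge_nt": values["mature_bulge_nt"] <= c.max_mature_bulge_nt,
        "biased_errors_per_bulge":
            values["biased_errors_per_bulge"] <= c.max_biased_errors_per_bulge,
        "biased_bulges": values["biased_bulges"] <= c.max_biased_bulges,
        "mature_errors": values["mature_errors"] <= c.max_mature_errors,
        "mature_bp": values["mature_bp"] >= c.min_mature_bp,
        "mature_in_stem_fraction":
            values["mature_in_stem_fraction"] >= c.min_mature_in_stem_fraction,
    }
    return CriteriaReport(values=values, passed=passed, overall=all(passed.values()))


# --------------------------------------------------------------------------
# novel-miRNA prediction from genomic context

@dataclass(frozen=True)
class NovelPrediction:
    """Outcome of folding one genomic locus of an unmapped read."""

    read_id: str
    sequence: str
    contig: str
    position: int  # 1-based start of the read on the contig
    window: tuple[int, int]
    structure: HairpinStructure | None
    report: CriteriaReport | None
    passed: bool


def _occurrences(needle: str, haystack: str) -> list[int]:
    out, start = [], 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return out
        out.append(idx)
        start = idx + 1


def _evaluate_window(contig_seq: str, wlo: int, whi: int, rlo: int, rhi: int,
                     criteria: HairpinCriteria, min_loop: int
                     ) -> tuple[HairpinStructure | None, CriteriaReport | None, bool]:
    """Fold contig[wlo..whi] (1-based) and test the read span rlo..rhi."""
    window = contig_seq[wlo - 1:whi]
    pairs = _fold_pairs(window, min_loop)
    unit = extract_hairpin(window, pairs, (rlo - wlo + 1, rhi - wlo + 1))
    if unit is None:
        return None, None, False
    sub, offset = unit
    ms = rlo - wlo + 1 - offset
    me = rhi - wlo + 1 - offset
    n_read = rhi - rlo + 1
    clipped = (max(1, ms), min(len(sub), me))
    if clipped[0] > clipped[1]:
        return sub, None, False
    report = evaluate_criteria(sub, clipped, criteria, mature_total_len=n_read)
    return sub, report, report.overall


def predict_novel(reads: Iterable[tuple[str, str]], genome: Mapping[str, str],
                  flank: int = 120,
                  criteria: HairpinCriteria = HairpinCriteria(),
                  min_loop: int = 3) -> list[NovelPrediction]:
    """Fold the genomic neighbourhoods of unmapped reads and apply criteria.

    Every exact sense-strand occurrence of a read yields two candidate
    windows (read plus ``flank`` nt upstream, read plus ``flank`` nt
    downstream).  For each locus the better candidate is reported; a read is
    called novel at a locus when at least one window's extracted stem-loop
    passes all 11 criteria with the read on a stem arm.  Reads absent from
    the genome are silently excluded.
    """
    out: list[NovelPrediction] = []
    for read_id, raw in reads:
        seq = to_dna(raw)
        for contig in sorted(genome):
            cseq = to_dna(genome[contig])
            for idx in _occurrences(seq, cseq):
                rlo, rhi = idx + 1, idx + len(seq)
                windows = (
                    (max(1, rlo - flank), rhi),
                    (rlo, min(len(cseq), rhi + flank)),
                )
                best: NovelPrediction | None = None
                for wlo, whi in windows:
                    sub, report, ok = _evaluate_window(
                        cseq, wlo, whi, rlo, rhi, criteria, min_loop)
                    pred = NovelPrediction(read_id, seq, contig, rlo,
                                           (wlo, whi), sub, report, ok)
                    if ok:
                        best = pred
                        break
                    if best is None or (best.report is None and report is not None):
                        best = pred
                out.append(best)
    return out
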