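"""Raw sRNA read cleanup: adapter trimming, filtering, collapsing, stats.

The cleanup chain mirrors a standard plant sRNA pipeline: drop low-quality
records, drop junk/low-complexity reads, trim the 3' adapter (discarding
adapter dimers), keep 18-25 nt inserts, remove common ncRNA families
(rRNA/tRNA/snRNA/snoRNA) by exact or substring match against reference
sets, and collapse survivors to unique sequences with per-library counts
and reads-per-million normalisation.

"Junk / low complexity" is defined as any non-ACGTUN symbol or a single
nucleotide making up >= 80% of the read.  T and U are treated as equivalent
(sequences are stored in the DNA alphabet).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import mean_quality, read_fasta, to_dna

__all__ = [
    "UniqueRead",
    "PreprocessStats",
    "trim_adapter",
    "is_junk",
    "filter_and_collapse",
    "preprocess_libraries",
    "length_distribution",
    "load_ncrna_dir",
    "write_collapsed_fasta",
]

_VALID = set("ACGTUN")


@dataclass
class UniqueRead:
    """A collapsed unique sRNA sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    normalized: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PreprocessStats:
    """Per-library read accounting; every raw read lands in exactly one bucket.

    ``clean_unique`` counts distinct sequences surviving the length filter,
    ``valid_unique`` those also surviving ncRNA removal (the two published
    notions of unique read counts).
    """

    raw_reads: dict[str, int] = field(default_factory=dict)
    low_quality: dict[str, int] = field(default_factory=dict)
    junk_removed: dict[str, int] = field(default_factory=dict)
    adapter_dimer: dict[str, int] = field(default_factory=dict)
    length_removed: dict[str, int] = field(default_factory=dict)
    ncrna_removed: dict[str, int] = field(default_factory=dict)
    kept: dict[str, int] = field(default_factory=dict)
    clean_unique: dict[str, int] = field(default_factory=dict)
    valid_unique: dict[str, int] = field(default_factory=dict)

    _REMOVAL = ("low_quality", "junk_removed", "adapter_dimer",
                "length_removed", "ncrna_removed")

    def check_partition(self) -> bool:
        """raw == kept + all removal buckets, per library."""
        libs = set(self.raw_reads)
        for lib in libs:
            removed = sum(getattr(self, k).get(lib, 0) for k in self._REMOVAL)
            if self.raw_reads[lib] != self.kept.get(lib, 0) + removed:
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        cols = ("raw_reads",) + self._REMOVAL + ("kept", "clean_unique", "valid_unique")
        libs = sorted(self.raw_reads)
        return pd.DataFrame({c: [getattr(self, c).get(l, 0) for l in libs] for c in cols},
                            index=pd.Index(libs, name="library"))


def is_junk(seq: str) -> bool:
    """Non-nucleotide symbols, or one base making up >= 80% of the read."""
    s = seq.upper()
    if not s or set(s) - _VALID:
        return True
    top = Counter(to_dna(s)).most_common(1)[0][1]
    return top / len(s) >= 0.8


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> tuple[str | None, str]:
    """Remove the longest read suffix matching a prefix of the adapter.

    Returns ``(insert, status)``: status is ``trimmed``, ``dimer`` (empty
    insert -> discard; insert is None) or ``untrimmed`` (no adapter prefix of
    at least ``min_overlap`` nt at the 3' end; read returned unmodified).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read_d = to_dna(read)
    adapter_d = to_dna(adapter)
    n = len(read_d)
    for i in range(n - min_overlap + 1):  # smallest i = longest suffix
        tail = n - i
        if tail > len(adapter_d):
            continue
        if read_d[i:] == adapter_d[:tail]:
            if i == 0:
                return None, "dimer"
            return read[:i], "trimmed"
    return read, "untrimmed"


def load_ncrna_dir(path) -> list[str]:
    """All reference sequences from every FASTA file in a directory."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"ncRNA reference path not found: {p}")
    seqs: list[str] = []
    for fasta in sorted(p.glob("*.fasta")) + sorted(p.glob("*.fa")):
        seqs.extend(to_dna(s) for _, s in read_fasta(fasta))
    return seqs


def _matches_ncrna(seq: str, refs: Sequence[str], substring: bool) -> bool:
    if substring:
        return any(seq in ref for ref in refs)
    return any(seq == ref for ref in refs)


def filter_and_collapse(trimmed_by_lib: Mapping[str, Iterable[str]],
                        ncrna_refs: Sequence[str] = (),
                        min_len: int = 18, max_len: int = 25,
                        substring_match: bool = True,
                        stats: PreprocessStats | None = None
                        ) -> tuple[list[UniqueRead], PreprocessStats]:
    """Length-filter, remove ncRNA matches, collapse to unique reads.

    ``trimmed_by_lib`` maps library label to adapter-trimmed insert
    sequences.  Collapsed reads carry per-library counts and RPM values
    normalised to each library's kept total.
    """
    stats = stats or PreprocessStats()
    refs = [to_dna(r) for r in ncrna_refs]
    per_lib_counter: dict[str, Counter] = {}
    for lib, seqs in trimmed_by_lib.items():
        counter: Counter = Counter()
        clean_seqs: set[str] = set()
        n_in = n_len = n_nc = 0
        for raw in seqs:
            n_in += 1
            seq = to_dna(raw)
            if not min_len <= len(seq) <= max_len:
                n_len += 1
                continue
            clean_seqs.add(seq)
            if refs and _matches_ncrna(seq, refs, substring_match):
                n_nc += 1
                continue
            counter[seq] += 1
        if lib not in stats.raw_reads:  # standalone use: raws are the inputs
            stats.raw_reads[lib] = n_in
        stats.length_removed[lib] = stats.length_removed.get(lib, 0) + n_len
        stats.ncrna_removed[lib] = stats.ncrna_removed.get(lib, 0) + n_nc
        stats.kept[lib] = stats.kept.get(lib, 0) + sum(counter.values())
        stats.clean_unique[lib] = len(clean_seqs)
        stats.valid_unique[lib] = len(counter)
        per_lib_counter[lib] = counter

    all_seqs = sorted(set().union(*[set(c) for c in per_lib_counter.values()]) or set())
    totals = {lib: sum(c.values()) for lib, c in per_lib_counter.items()}
    unique: list[UniqueRead] = []
    for seq in all_seqs:
        counts = {lib: per_lib_counter[lib][seq]
                  for lib in per_lib_counter if per_lib_counter[lib][seq] > 0}
        normalized = {lib: 1e6 * n / totals[lib] for lib, n in counts.items() if totals[lib]}
        unique.append(UniqueRead(seq, counts, normalized))
    return unique, stats


def preprocess_libraries(records_by_lib: Mapping[str, Iterable[tuple[str, str, str]]],
                         adapter: str, min_overlap: int = 6,
                         min_len: int = 18, max_len: int = 25,
                         ncrna_refs: Sequence[str] = (),
                         min_mean_quality: float = 20.0,
                         substring_match: bool = True
                         ) -> tuple[list[UniqueRead], PreprocessStats]:
    """Full cleanup of raw FASTQ-style records ((id, seq, qual) per library)."""
    stats = PreprocessStats()
    trimmed: dict[str, list[str]] = {}
    for lib, records in records_by_lib.items():
        out: list[str] = []
        n_raw = n_lowq = n_junk = n_dimer = 0
        for _, seq, qual in records:
            n_raw += 1
            if qual and mean_quality(qual) < min_mean_quality:
                n_lowq += 1
                continue
            if is_junk(seq):
                n_junk += 1
                continue
            insert, status = trim_adapter(seq, adapter, min_overlap)
            if status == "dimer":
                n_dimer += 1
                continue
            out.append(insert)
        stats.raw_reads[lib] = n_raw
        stats.low_quality[lib] = n_lowq
        stats.junk_removed[lib] = n_junk
        stats.adapter_dimer[lib] = n_dimer
        trimmed[lib] = out
    return filter_and_collapse(trimmed, ncrna_refs, min_len, max_len,
                               substring_match, stats)


def length_distribution(unique_reads: Iterable[UniqueRead]) -> pd.DataFrame:
    """Per-library (unique, total) read counts by insert length.

    Rows are lengths present in the data; columns are a MultiIndex
    (library, {unique, total}).
    """
    rows: dict[int, dict[tuple[str, str], int]] = {}
    for ur in unique_reads:
        n = len(ur.sequence)
        row = rows.setdefault(n, {})
        for lib, cnt in ur.counts.items():
            row[(lib, "unique")] = row.get((lib, "unique"), 0) + 1
            row[(lib, "total")] = row.get((lib, "total"), 0) + cnt
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df.index.name = "length"
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["library", "kind"])
    return df.sort_index().sort_index(axis=1)


def write_collapsed_fasta(path, unique_reads: Sequence[UniqueRead]) -> None:
    """Collapsed FASTA with ``>u<N> count=<total>`` headers."""
    recs = [(f"u{i + 1:06d} count={ur.total}", ur.sequence)
            for i, ur in enumerate(unique_reads)]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in recs:
            fh.write(f">{name}\n{seq}\n")
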