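"""Shared helpers: nucleotide alphabet, seeded RNG streams, FASTA/FASTQ I/O.

Sequences are stored internally in the DNA alphabet; U is converted to T on
input so RNA and DNA spellings of the same molecule compare equal.
"""
from __future__ import annotations

import zlib
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Watson-Crick pairs plus the G:U wobble, in the DNA alphabet (U -> T).
WATSON_CRICK = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("T", "G")}


def to_dna(seq: str) -> str:
    """Uppercase and fold U onto T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


def can_pair(a: str, b: str) -> bool:
    """True if the two bases can form a Watson-Crick or G:U wobble pair."""
    return (a, b) in WATSON_CRICK or (a, b) in WOBBLE


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG stream derived from one root seed.

    The stream seed is the pair ``(seed, crc32(name))`` so every generator
    stage draws from an independent stream while staying fully determined by
    the root seed.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def random_seq(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, 4, size=n)
    return "".join(DNA_BASES[i] for i in idx)


# --------------------------------------------------------------------------
# light sequence-file I/O (Biopython-backed)

def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    for r in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in r.letter_annotations["phred_quality"])
        out.append((r.id, str(r.seq).upper(), qual))
    return out


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    recs = []
    for name, seq, qual in records:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def mean_quality(qual: str) -> float:
    if not qual:
        return 0.0
    return float(np.mean([ord(c) - 33 for c in qual]))
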