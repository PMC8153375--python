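"""Synthetic inputs with ground truth for the whole sRNA/degradome pipeline.

The generator emulates the statistical structure of a two-condition plant
small-RNA experiment (a sterile line and its fertile maintainer):

* a miRBase-like catalog of hairpin precursors with mature 5p/3p arms and
  per-family species membership spanning all conservation tiers,
* sRNA libraries: mature reads and isomiRs (end shifts, internal
  substitutions) carrying a 3' adapter, ncRNA decoys (rRNA/tRNA/snRNA/
  snoRNA-like), and random-background reads whose lengths follow the
  configured 24 > 21 > 22 nt distribution,
* a genome with precursor loci, compliant novel-miRNA loci and random decoy
  loci for hairpin prediction,
* a transcriptome with implanted miRNA target sites and degradome tag
  libraries peaked at the position opposite miRNA position 10,
* a gene count matrix with spiked fold changes for differential expression,
* gene -> GO/KEGG-style annotation with one planted family -> term motif.

Every stream derives from the single root seed via named sub-streams
(`mircms._util.stream_rng`), so a fixed seed gives byte-identical output
files.  Precursors and novel loci are rejection-sampled until they pass the
11 hairpin criteria, which is what makes generator truth usable as a
positive set for the hairpin filter.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import random_seq, revcomp, stream_rng, write_fasta, write_fastq
from .hairpin_filter import (
    HairpinCriteria,
    evaluate_criteria,
    extract_hairpin,
    _fold_pairs,
    predict_novel,
)

__all__ = [
    "SimConfig",
    "ConfigError",
    "TruthTable",
    "Catalog",
    "Family",
    "MatureRecord",
    "make_catalog",
    "make_ncrna_refs",
    "build_genome",
    "simulate_srna_reads",
    "make_transcriptome",
    "simulate_degradome",
    "simulate_counts",
    "make_annotation",
    "write_all",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


#: focal species first; 47 codes in total, mirroring the size of the
#: cross-species catalog the conservation tiers are counted against.
DEFAULT_SPECIES = ("gma",) + tuple(f"sp{i:02d}" for i in range(1, 47))

#: read-length weights over 18-25 nt with the 24 > 21 > 22 ordering typical
#: of plant flower-bud sRNA libraries.
DEFAULT_LENGTH_WEIGHTS = {
    18: 0.02, 19: 0.03, 20: 0.08, 21: 0.22,
    22: 0.15, 23: 0.10, 24: 0.30, 25: 0.10,
}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_families: int = 24
    species_pool: tuple[str, ...] = DEFAULT_SPECIES
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    libraries: tuple[tuple[str, int], ...] = (("A", 20000), ("B", 20000))
    variant_rate: float = 0.20
    star_fraction: float = 0.04
    ncrna_fraction: float = 0.10
    random_fraction: float = 0.15
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    low_quality_fraction: float = 0.02
    # differential expression
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    replicates: int = 3
    n_genes: int = 600
    nb_dispersion: float = 0.05
    # degradome
    n_targets: int = 40
    planted_family_targets: int = 10
    target_overlap: float = 0.60
    degradome_depth: int = 4000
    degradome_background: float = 0.20
    signal_tags_per_site: int = 25
    transcript_len: tuple[int, int] = (300, 600)
    # genome / novel loci
    conserved_fraction: float = 0.15
    n_novel_loci: int = 12
    n_decoy_loci: int = 12
    flank: int = 120

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if not self.species_pool:
            raise ConfigError("species_pool must not be empty")
        total = float(sum(self.length_weights.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"length_weights sum {total} != 1")
        if any(not 18 <= k <= 25 for k in self.length_weights):
            raise ConfigError("length_weights keys must lie in 18-25")
        for name in ("variant_rate", "star_fraction", "ncrna_fraction",
                     "random_fraction", "low_quality_fraction", "de_fraction",
                     "target_overlap", "degradome_background",
                     "conserved_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


# --------------------------------------------------------------------------
# ground truth container

@dataclass
class TruthTable:
    """Everything the generator knows that the pipeline must recover."""

    true_mirnas: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (name, mature sequence, precursor name, arm)
    true_novel: list[tuple[str, str, str]] = field(default_factory=list)
    # (read name, sequence, contig)
    decoy_loci: list[tuple[str, str, str]] = field(default_factory=list)
    true_targets: list[tuple[str, str, int]] = field(default_factory=list)
    # (miRNA name, gene, 1-based cleavage position)
    targets_by_library: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)
    true_de_genes: dict[str, float] = field(default_factory=dict)
    read_provenance: dict[str, str] = field(default_factory=dict)
    planted_family: str | None = None
    planted_term: str | None = None


# --------------------------------------------------------------------------
# catalog

@dataclass(frozen=True)
class MatureRecord:
    name: str
    family: str
    arm: str  # "5p" | "3p"
    species: str
    precursor_name: str
    precursor_seq: str
    start: int  # 1-based inclusive on precursor
    end: int

    @property
    def sequence(self) -> str:
        return self.precursor_seq[self.start - 1:self.end]


@dataclass(frozen=True)
class Family:
    family: str
    species: tuple[str, ...]
    tier_intent: str
    conserved: bool
    precursor_name: str
    precursor_seq: str
    mature_arm: str          # the annotated arm
    mature_span: tuple[int, int]
    star_span: tuple[int, int]

    def mature_record(self, species: str = "gma") -> MatureRecord:
        return MatureRecord(
            name=f"{species}-{self.family}-{self.mature_arm}",
            family=self.family, arm=self.mature_arm, species=species,
            precursor_name=f"{species}-{self.precursor_name}",
            precursor_seq=self.precursor_seq,
            start=self.mature_span[0], end=self.mature_span[1])

    @property
    def star_arm(self) -> str:
        return "3p" if self.mature_arm == "5p" else "5p"

    @property
    def mature_seq(self) -> str:
        return self.precursor_seq[self.mature_span[0] - 1:self.mature_span[1]]

    @property
    def star_seq(self) -> str:
        return self.precursor_seq[self.star_span[0] - 1:self.star_span[1]]


@dataclass
class Catalog:
    families: list[Family]

    @property
    def conserved_families(self) -> set[str]:
        return {f.family for f in self.families if f.conserved}

    def matures(self, species: str = "gma") -> list[MatureRecord]:
        return [f.mature_record(species) for f in self.families
                if species in f.species]

    def other_species_matures(self, focal: str = "gma") -> list[MatureRecord]:
        out = []
        for f in self.families:
            for sp in f.species:
                if sp != focal:
                    out.append(f.mature_record(sp))
        return out

    def family(self, name: str) -> Family:
        for f in self.families:
            if f.family == name:
                return f
        raise KeyError(name)


_TIER_CYCLE = ("non-conserved", "low", "moderate", "high")
_TIER_SIZES = {"non-conserved": (1, 1), "low": (2, 4),
               "moderate": (5, 10), "high": (11, 18), "conserved": (11, 18)}


def _draw_length(rng: np.random.Generator, weights: Mapping[int, float]) -> int:
    lengths = sorted(weights)
    probs = np.array([weights[k] for k in lengths], dtype=float)
    return int(rng.choice(lengths, p=probs / probs.sum()))


def _build_precursor(rng: np.random.Generator, mature_len: int, arm: str,
                     criteria: HairpinCriteria,
                     max_tries: int = 60) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Construct a criteria-compliant hairpin containing one mature arm.

    Built constructively (stem arm + loop + reverse-complement arm) and
    accepted only when the folded structure passes all 11 criteria for the
    mature span — the rejection step guards against co-optimal folds that
    break the designed stem.
    """
    for _ in range(max_tries):
        arm_len = mature_len + int(rng.integers(8, 15))
        left = random_seq(rng, arm_len)
        loop = random_seq(rng, int(rng.integers(6, 13)))
        lead = random_seq(rng, int(rng.integers(2, 6)))
        tail = random_seq(rng, int(rng.integers(2, 6)))
        precursor = lead + left + loop + revcomp(left) + tail
        off = int(rng.integers(2, arm_len - mature_len - 1))
        if arm == "5p":
            start = len(lead) + off + 1
        else:
            start = len(lead) + arm_len + len(loop) + off + 1
        span = (start, start + mature_len - 1)
        pairs = _fold_pairs(precursor)
        unit = extract_hairpin(precursor, pairs, span)
        if unit is None:
            continue
        sub, offset = unit
        report = evaluate_criteria(sub, (span[0] - offset, span[1] - offset),
                                   criteria, mature_total_len=mature_len)
        if not report.overall:
            continue
        # star span from the actual pairing of the mature ends
        pairmap = {i: j for i, j in pairs}
        pairmap.update({j: i for i, j in pairs})
        partners = sorted(pairmap[p] for p in range(span[0], span[1] + 1)
                          if p in pairmap)
        if len(partners) < mature_len - 4:
            continue
        star_span = (partners[0], partners[-1])
        if star_span[1] - star_span[0] + 1 > 25 or star_span[1] - star_span[0] + 1 < 18:
            continue
        return precursor, span, star_span
    raise RuntimeError("failed to construct a compliant precursor")


def make_catalog(config: SimConfig,
                 species_counts: Sequence[int] | None = None,
                 criteria: HairpinCriteria = HairpinCriteria()) -> Catalog:
    """Build the miRBase-like catalog with per-family species membership.

    Families cycle through the four conservation tiers (with a fraction
    flagged as anciently conserved) unless ``species_counts`` forces the
    membership size of each family explicitly.
    """
    config.validate()
    rng = stream_rng(config.seed, "catalog")
    families: list[Family] = []
    n_cons = max(1, round(1 / config.conserved_fraction)) if config.conserved_fraction else 0
    for i in range(config.n_families):
        fam = f"miR{1000 + i}"
        mature_len = min(24, max(20, _draw_length(rng, config.length_weights)))
        arm = "5p" if i % 2 == 0 else "3p"
        precursor, span, star_span = _build_precursor(rng, mature_len, arm, criteria)
        if species_counts is not None:
            k = int(species_counts[i])
            conserved = False
            tier = "forced"
        elif n_cons and i % n_cons == n_cons - 1:
            tier, conserved = "conserved", True
            k = int(rng.integers(*_TIER_SIZES[tier]) + 1)
        else:
            tier, conserved = _TIER_CYCLE[i % 4], False
            lo, hi = _TIER_SIZES[tier]
            k = int(rng.integers(lo, hi + 1))
        others = [sp for sp in config.species_pool if sp != config.species_pool[0]]
        picked = list(rng.choice(others, size=min(k - 1, len(others)), replace=False)) if k > 1 else []
        species = (config.species_pool[0],) + tuple(sorted(picked))
        families.append(Family(
            family=fam, species=species, tier_intent=tier, conserved=conserved,
            precursor_name=f"MIR{1000 + i}", precursor_seq=precursor,
            mature_arm=arm, mature_span=span, star_span=star_span))
    return Catalog(families)


# --------------------------------------------------------------------------
# ncRNA decoy references

_NCRNA_CLASSES = (("rRNA", 6, (100, 160)), ("tRNA", 8, (70, 95)),
                  ("snRNA", 4, (90, 150)), ("snoRNA", 4, (60, 120)))


def make_ncrna_refs(config: SimConfig) -> dict[str, list[tuple[str, str]]]:
    """Generated decoy reference sets standing in for Rfam-style ncRNA."""
    rng = stream_rng(config.seed, "ncrna")
    refs: dict[str, list[tuple[str, str]]] = {}
    for cls, n, (lo, hi) in _NCRNA_CLASSES:
        refs[cls] = [(f"{cls}_{i + 1:02d}", random_seq(rng, int(rng.integers(lo, hi))))
                     for i in range(n)]
    return refs


# --------------------------------------------------------------------------
# genome

def build_genome(catalog: Catalog, config: SimConfig,
                 criteria: HairpinCriteria = HairpinCriteria()
                 ) -> tuple[dict[str, str], TruthTable]:
    """Genome contigs: catalog precursor loci, compliant novel loci, decoys.

    Novel loci are rejection-sampled until the full flank-window prediction
    (`predict_novel`) accepts the embedded read, so generator positives are
    guaranteed detectable; decoy loci embed a read in random sequence with
    no such guarantee.
    """
    rng = stream_rng(config.seed, "genome")
    truth = TruthTable()
    genome: dict[str, str] = {}
    for fam in catalog.families:
        contig = f"chr_{fam.family}"
        genome[contig] = (random_seq(rng, config.flank + 10) + fam.precursor_seq
                         + random_seq(rng, config.flank + 10))
        rec = fam.mature_record("gma")
        truth.true_mirnas.append((rec.name, rec.sequence, rec.precursor_name, rec.arm))
    for i in range(config.n_novel_loci):
        name = f"novel_{i + 1:03d}"
        contig = f"chr_{name}"
        for _ in range(80):
            mature_len = int(rng.integers(20, 23))
            arm = "5p" if i % 2 == 0 else "3p"
            precursor, span, _ = _build_precursor(rng, mature_len, arm, criteria)
            seq = (random_seq(rng, config.flank + 10) + precursor
                   + random_seq(rng, config.flank + 10))
            read = precursor[span[0] - 1:span[1]]
            if seq.count(read) != 1:
                continue
            preds = predict_novel([(name, read)], {contig: seq},
                                  flank=config.flank, criteria=criteria)
            if any(p.passed for p in preds):
                genome[contig] = seq
                truth.true_novel.append((name, read, contig))
                break
        else:
            raise RuntimeError(f"could not build novel locus {name}")
    for i in range(config.n_decoy_loci):
        name = f"decoy_{i + 1:03d}"
        contig = f"chr_{name}"
        read = random_seq(rng, int(rng.integers(20, 23)))
        genome[contig] = (random_seq(rng, config.flank + 10) + read
                          + random_seq(rng, config.flank + 10))
        truth.decoy_loci.append((name, read, contig))
    return genome, truth


# --------------------------------------------------------------------------
# sRNA reads

def _make_isomir(rng: np.random.Generator, fam: Family) -> str | None:
    """An end-shifted and/or internally substituted variant of the mature."""
    start, end = fam.mature_span
    precursor = fam.precursor_seq
    for _ in range(10):
        d5 = int(rng.integers(-2, 3))
        d3 = int(rng.integers(-2, 3))
        sub = bool(rng.random() < 0.5)
        if d5 == 0 and d3 == 0 and not sub:
            continue
        s, e = start + d5, end + d3
        if s < 1 or e > len(precursor) or not 18 <= e - s + 1 <= 25:
            continue
        seq = list(precursor[s - 1:e])
        if sub:
            pos = int(rng.integers(0, len(seq)))
            choices = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = choices[int(rng.integers(0, 3))]
        return "".join(seq)
    return None


def simulate_srna_reads(catalog: Catalog, config: SimConfig,
                        truth: TruthTable | None = None
                        ) -> tuple[dict[str, list[tuple[str, str, str]]], TruthTable]:
    """Raw sRNA libraries (read = insert + 3' adapter) plus provenance truth.

    Mature-derived read lengths inherit the catalog's length distribution
    (drawn from ``length_weights``), ncRNA decoys are substrings of the
    generated reference sets, and random-background reads draw their length
    from ``length_weights`` directly — together giving the configured modal
    length after trimming.
    """
    config.validate()
    truth = truth if truth is not None else TruthTable()
    ncrna = make_ncrna_refs(config)
    ncrna_pool = [seq for recs in ncrna.values() for _, seq in recs]
    abr = stream_rng(config.seed, "abundance")
    weights = np.exp(abr.normal(0.0, 0.6, size=len(catalog.families)))
    weights /= weights.sum()
    novel_sources = list(truth.true_novel)
    reads_by_lib: dict[str, list[tuple[str, str, str]]] = {}
    for lib, depth in config.libraries:
        rng = stream_rng(config.seed, f"srna:{lib}")
        records: list[tuple[str, str, str]] = []
        p_novel = 0.02 if novel_sources else 0.0
        for r in range(int(depth)):
            rid = f"{lib}_{r + 1:07d}"
            u = rng.random()
            if u < config.ncrna_fraction:
                ref = ncrna_pool[int(rng.integers(0, len(ncrna_pool)))]
                ln = min(_draw_length(rng, config.length_weights), len(ref))
                pos = int(rng.integers(0, len(ref) - ln + 1))
                insert, label = ref[pos:pos + ln], "ncrna"
            elif u < config.ncrna_fraction + config.random_fraction:
                insert = random_seq(rng, _draw_length(rng, config.length_weights))
                label = "random"
            elif u < config.ncrna_fraction + config.random_fraction + p_novel:
                nm, seq, _ = novel_sources[int(rng.integers(0, len(novel_sources)))]
                insert, label = seq, "novel"
            else:
                fam = catalog.families[int(rng.choice(len(catalog.families), p=weights))]
                if rng.random() < config.star_fraction:
                    insert, label = fam.star_seq, "star"
                elif rng.random() < config.variant_rate:
                    iso = _make_isomir(rng, fam)
                    if iso is None:
                        insert, label = fam.mature_seq, "mature"
                    else:
                        insert, label = iso, "isomir"
                else:
                    insert, label = fam.mature_seq, "mature"
            seq = insert + config.adapter
            qual = ("#" if rng.random() < config.low_quality_fraction else "I") * len(seq)
            records.append((rid, seq, qual))
            truth.read_provenance[rid] = label
        reads_by_lib[lib] = records
    return reads_by_lib, truth


# --------------------------------------------------------------------------
# transcriptome + degradome

def make_transcriptome(catalog: Catalog, config: SimConfig,
                       truth: TruthTable) -> dict[str, str]:
    """Gene transcripts with implanted, perfectly complementary target sites.

    The cleavage position recorded in truth is the transcript nucleotide
    opposite miRNA position 10 (site end − 9 in transcript coordinates).
    Targets are split between the two libraries with ``target_overlap``
    shared, giving a planted Venn partition.
    """
    rng = stream_rng(config.seed, "transcriptome")
    lo, hi = config.transcript_len
    transcripts = {f"G{i + 1:04d}": random_seq(rng, int(rng.integers(lo, hi)))
                   for i in range(config.n_genes)}
    genes = sorted(transcripts)
    matures = catalog.matures("gma")
    target_genes = list(rng.choice(genes, size=min(config.n_targets, len(genes)),
                                   replace=False))
    # planted hub: the first family targets several genes of one term
    n_planted = min(config.planted_family_targets, len(target_genes))
    for gi, g in enumerate(target_genes):
        rec = matures[0] if gi < n_planted else \
            matures[int(rng.integers(0, len(matures)))]
        site = revcomp(rec.sequence)
        t = transcripts[g]
        pos = int(rng.integers(30, len(t) - len(site) - 30))
        transcripts[g] = t[:pos] + site + t[pos + len(site):]
        s, e = pos + 1, pos + len(site)
        cleavage = e - 9  # transcript position paired with miRNA position 10
        truth.true_targets.append((rec.name, g, cleavage))
    # planted Venn partition over the two libraries
    targets = list(truth.true_targets)
    n_common = int(round(config.target_overlap * len(targets)))
    idx = rng.permutation(len(targets))
    common = [targets[i] for i in idx[:n_common]]
    rest = [targets[i] for i in idx[n_common:]]
    half = len(rest) // 2
    libs = [lib for lib, _ in config.libraries][:2] or ["A", "B"]
    truth.targets_by_library = {
        libs[0]: sorted(common + rest[:half]),
        libs[1] if len(libs) > 1 else "B": sorted(common + rest[half:]),
    }
    return transcripts


def simulate_degradome(targets: Sequence[tuple[str, str, int]],
                       transcripts: Mapping[str, str],
                       depth: int, background_rate: float, seed: int,
                       adapter: str = "TGGAATTCTCGGGTGCCAAGG",
                       signal_tags: int = 25, tag_len: int = 20
                       ) -> tuple[list[tuple[str, str, str]], list[tuple[str, int]]]:
    """Degradome tags: pile-ups at true cleavage sites over uniform background.

    Each true target receives ~``signal_tags`` tags whose 5' ends sit exactly
    at the cleavage position; ``depth * background_rate`` tags start at
    uniform random transcript positions.  With ``background_rate`` 0 every
    tag marks a true site.
    """
    rng = stream_rng(seed, "degradome")
    records: list[tuple[str, str, str]] = []
    site_truth: list[tuple[str, int]] = []
    k = 0
    for mirna, gene, pos in targets:
        if gene not in transcripts:
            raise ValueError(f"target transcript {gene} missing")
        t = transcripts[gene]
        if not 1 <= pos <= len(t):
            raise ValueError(f"cleavage position {pos} outside {gene}")
        n_sig = max(3, int(rng.poisson(signal_tags)))
        tag = t[pos - 1:pos - 1 + tag_len]
        for _ in range(n_sig):
            k += 1
            records.append((f"deg_{k:07d}", tag + adapter, "I" * (len(tag) + len(adapter))))
        site_truth.append((gene, pos))
    n_bg = int(round(depth * background_rate))
    genes = sorted(transcripts)
    for _ in range(n_bg):
        g = genes[int(rng.integers(0, len(genes)))]
        t = transcripts[g]
        pos = int(rng.integers(1, max(2, len(t) - tag_len)))
        tag = t[pos - 1:pos - 1 + tag_len]
        if len(tag) < 15:
            continue
        k += 1
        records.append((f"deg_{k:07d}", tag + adapter, "I" * (len(tag) + len(adapter))))
    return records, site_truth


# --------------------------------------------------------------------------
# counts

def simulate_counts(config: SimConfig
                    ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Gene count matrix (genes x samples) with spiked fold changes.

    Null genes share a mean across conditions; exactly
    ``round(n_genes * de_fraction)`` spiked genes differ by
    ``2**de_log2fc`` (A over B, random sign, split symmetrically around the
    base mean).  Counts are negative binomial with dispersion
    ``nb_dispersion`` (0 gives Poisson).
    """
    config.validate()
    rng = stream_rng(config.seed, "counts")
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    base = np.exp(rng.normal(4.5, 1.0, size=config.n_genes))
    n_spike = int(round(config.n_genes * config.de_fraction))
    spike_idx = rng.choice(config.n_genes, size=n_spike, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_spike)
    lfc = np.zeros(config.n_genes)
    lfc[spike_idx] = signs * config.de_log2fc
    mean_a = base * np.power(2.0, lfc / 2.0)
    mean_b = base * np.power(2.0, -lfc / 2.0)

    def draw(mean: np.ndarray) -> np.ndarray:
        if config.nb_dispersion <= 0:
            return rng.poisson(mean)
        r = 1.0 / config.nb_dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p)

    data = {}
    for rep in range(1, config.replicates + 1):
        data[f"A_{rep}"] = draw(mean_a)
    for rep in range(1, config.replicates + 1):
        data[f"B_{rep}"] = draw(mean_b)
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    true_de = {genes[i]: float(lfc[i]) for i in sorted(spike_idx)}
    return counts, true_de


# --------------------------------------------------------------------------
# annotation map

_GO_TERMS = [
    ("GO:0048653", "BP", "anther development"),
    ("GO:0010073", "BP", "meristem maintenance"),
    ("GO:0010072", "BP", "meristem initiation"),
    ("GO:0019953", "BP", "sexual reproduction"),
    ("GO:0030154", "BP", "cell differentiation"),
    ("GO:0009734", "BP", "auxin-activated signaling pathway"),
    ("GO:0045490", "BP", "pectin catabolic process"),
    ("GO:0042545", "BP", "cell wall modification"),
    ("GO:0005634", "CC", "nucleus"),
    ("GO:0005618", "CC", "cell wall"),
    ("GO:0005739", "CC", "mitochondrion"),
    ("GO:0009505", "CC", "plant-type cell wall"),
    ("GO:0030599", "MF", "pectinesterase activity"),
    ("GO:0045330", "MF", "aspartyl esterase activity"),
    ("GO:0004857", "MF", "enzyme inhibitor activity"),
    ("GO:0003700", "MF", "DNA-binding transcription factor activity"),
    ("ko03040", "pathway", "spliceosome"),
    ("ko03013", "pathway", "RNA transport"),
    ("ko03018", "pathway", "RNA degradation"),
    ("ko03010", "pathway", "ribosome"),
    ("ko04075", "pathway", "plant hormone signal transduction"),
]


def make_annotation(transcripts: Mapping[str, str], truth: TruthTable,
                    config: SimConfig) -> pd.DataFrame:
    """Gene -> term table (gene, term, namespace, label) over the universe.

    One planted motif: all target genes of the most-targeting family are
    annotated to a single term, so the family dominates the downstream
    term-restricted network (a miR169-style hub).
    """
    rng = stream_rng(config.seed, "annotation")
    genes = sorted(transcripts)
    rows: list[tuple[str, str, str, str]] = []
    by_family: dict[str, set[str]] = {}
    for mirna, gene, _ in truth.true_targets:
        fam = mirna.split("-")[1]
        by_family.setdefault(fam, set()).add(gene)
    planted_term = _GO_TERMS[0]
    if by_family:
        top_family = max(sorted(by_family), key=lambda f: len(by_family[f]))
        truth.planted_family = top_family
        truth.planted_term = planted_term[0]
        for gene in sorted(by_family[top_family]):
            rows.append((gene, *planted_term))
    for g in genes:
        n_terms = int(rng.integers(0, 3))
        if n_terms:
            for t in rng.choice(len(_GO_TERMS) - 1, size=n_terms, replace=False):
                term = _GO_TERMS[int(t) + 1]
                rows.append((g, *term))
    df = pd.DataFrame(rows, columns=["gene", "term", "namespace", "label"])
    return df.drop_duplicates().sort_values(["gene", "term"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# orchestration / file layout

def write_catalog(catalog: Catalog, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    write_fasta(out_dir / "precursors.fasta",
                [(f"gma-{f.precursor_name}", f.precursor_seq) for f in catalog.families])
    matures = []
    for f in catalog.families:
        rec = f.mature_record("gma")
        matures.append((rec.name, rec.sequence))
    write_fasta(out_dir / "matures.fasta", matures)
    rows = [(f.family, f.tier_intent, str(f.conserved).lower(), f.mature_arm,
             f.mature_span[0], f.mature_span[1], ",".join(f.species))
            for f in catalog.families]
    pd.DataFrame(rows, columns=["family", "tier_intent", "conserved", "mature_arm",
                                "mature_start", "mature_end", "species"]
                 ).to_csv(out_dir / "families.tsv", sep="\t", index=False)


def write_all(config: SimConfig, out_dir: str | Path) -> dict:
    """Generate and write every pipeline input; returns the in-memory bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = make_catalog(config)
    genome, truth = build_genome(catalog, config)
    reads_by_lib, truth = simulate_srna_reads(catalog, config, truth)
    transcripts = make_transcriptome(catalog, config, truth)
    counts, true_de = simulate_counts(config)
    truth.true_de_genes = true_de
    annotation = make_annotation(transcripts, truth, config)

    write_catalog(catalog, out / "catalog")
    write_fasta(out / "genome.fasta", sorted(genome.items()))
    for cls, recs in make_ncrna_refs(config).items():
        write_fasta(out / "ncrna" / f"{cls}.fasta", recs)
    for lib, records in reads_by_lib.items():
        write_fastq(out / f"srna_{lib}.fastq", records)
    write_fasta(out / "transcripts.fasta", sorted(transcripts.items()))
    degradome: dict[str, list] = {}
    mirna_seqs = {f.mature_record("gma").name: f.mature_seq for f in catalog.families}
    for li, (lib, _) in enumerate(config.libraries[:2]):
        targets = truth.targets_by_library.get(lib, [])
        records, _ = simulate_degradome(
            targets, transcripts, config.degradome_depth,
            config.degradome_background, config.seed + 1000 + li,
            adapter=config.adapter, signal_tags=config.signal_tags_per_site)
        write_fastq(out / f"degradome_{lib}.fastq", records)
        degradome[lib] = records
    counts.to_csv(out / "counts.tsv", sep="\t")
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)

    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    pd.DataFrame(truth.true_mirnas,
                 columns=["name", "sequence", "precursor", "arm"]
                 ).to_csv(tdir / "mirnas.tsv", sep="\t", index=False)
    pd.DataFrame(truth.true_novel, columns=["name", "sequence", "contig"]
                 ).to_csv(tdir / "novel.tsv", sep="\t", index=False)
    pd.DataFrame(truth.true_targets, columns=["mirna", "gene", "cleavage_pos"]
                 ).to_csv(tdir / "targets.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.true_de_genes.items()), columns=["gene", "log2fc"]
                 ).to_csv(tdir / "de_genes.tsv", sep="\t", index=False)
    prov = pd.DataFrame(sorted(truth.read_provenance.items()),
                        columns=["read", "label"])
    prov.to_csv(tdir / "provenance.tsv", sep="\t", index=False)

    return {
        "config": config, "catalog": catalog, "genome": genome, "truth": truth,
        "reads_by_lib": reads_by_lib, "transcripts": transcripts,
        "counts": counts, "annotation": annotation, "degradome": degradome,
        "mirna_seqs": mirna_seqs, "out_dir": out,
    }
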