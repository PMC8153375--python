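"""Known-miRNA identification, isomiR naming, evidence groups, conservation.

Collapsed unique reads are placed on catalog precursors relative to the
annotated mature (end shifts at either terminus plus at most one internal
mismatch by default).  Sequence variants get canonical isomiR names of the
form ``L±n R±m kss<pos><ref><obs>...``:

* ``L+n`` / ``R+m`` - n extra precursor nucleotides at the 5' / 3' end,
* ``L-n`` / ``R-m`` - n trimmed nucleotides,
* ``kss...`` - k internal substitutions, each as 1-based position on the
  observed sequence, reference base, observed base, ascending.

Each annotated read falls in exactly one of six evidence groups:

====== =====================================================================
gp1a   focal-species mature hit, precursor locatable on the genome
gp1b   focal-species mature hit, precursor not on the genome
gp2a   other-species mature hit whose precursor maps to the genome
gp2b   hit on the precursor arm opposite an annotated mature (novel 5p/3p)
gp3    focal-species precursor hit outside any mature arm
gp4    no catalog hit; genome-anchored hairpin passes the 11 criteria
====== =====================================================================

gp1a/gp1b form the conserved evidence class, the rest are non-conserved.
Family conservation is tiered against the cross-species catalog: families
in the designated conserved list are "conserved"; otherwise >10 species =
high, 5-10 = moderate (10 closes the printed five-to-nine / >10 gap
downward), 2-4 = low, 1 = non-conserved.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import to_dna

__all__ = [
    "MappingPolicy",
    "CatalogHit",
    "MiRNAAnnotation",
    "GROUPS",
    "TIERS",
    "map_to_catalog",
    "name_variant",
    "parse_variant_name",
    "apply_variant",
    "assign_group",
    "classify_conservation",
    "family_summary",
    "annotate_reads",
]

GROUPS = ("gp1a", "gp1b", "gp2a", "gp2b", "gp3", "gp4")
TIERS = ("conserved", "high", "moderate", "low", "non-conserved")


class VariantError(ValueError):
    """Observed sequence cannot be anchored on the precursor."""


@dataclass(frozen=True)
class MappingPolicy:
    """End-shift and mismatch tolerances for catalog placement.

    End shifts are not counted as mismatches; ``max_internal_mismatch``
    applies to the aligned (overlapping) positions only.
    """

    max_end_shift_5p: int = 2
    max_end_shift_3p: int = 2
    max_internal_mismatch: int = 1

    def __post_init__(self):
        if min(self.max_end_shift_5p, self.max_end_shift_3p,
               self.max_internal_mismatch) < 0:
            raise ValueError("policy limits must be non-negative")


@dataclass(frozen=True)
class CatalogHit:
    mature: object  # MatureRecord-like: name/family/arm/precursor_seq/start/end
    offset: int     # 1-based start of the read on the precursor
    shift5: int     # signed: +n = n extra 5' nt relative to the mature
    shift3: int     # signed: +n = n extra 3' nt
    mismatches: int


@dataclass
class MiRNAAnnotation:
    sequence: str
    mirna_name: str
    family: str
    arm: str
    group: str
    variant_name: str
    conservation: str
    counts: dict[str, int] = field(default_factory=dict)


# --------------------------------------------------------------------------
# catalog placement

def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def map_to_catalog(read: str, matures: Iterable, policy: MappingPolicy = MappingPolicy()
                   ) -> list[CatalogHit]:
    """All qualifying placements of a read against annotated matures.

    A hit aligns the read inside a precursor with 5'/3' end shifts within
    the policy limits and internal mismatches within the mismatch budget.
    Hits are sorted best-first: fewest mismatches, then smallest total
    shift, then lexicographic miRNA name.
    """
    seq = to_dna(read)
    if not 18 <= len(seq) <= 25:
        raise ValueError(f"read length {len(seq)} outside 18-25 nt")
    hits: list[CatalogHit] = []
    for rec in matures:
        pre = to_dna(rec.precursor_seq)
        for shift5 in range(-policy.max_end_shift_5p, policy.max_end_shift_5p + 1):
            start = rec.start - shift5  # +shift5 extends upstream
            end = start + len(seq) - 1
            shift3 = end - rec.end
            if abs(shift3) > policy.max_end_shift_3p:
                continue
            if start < 1 or end > len(pre):
                continue
            mm = _hamming(seq, pre[start - 1:end])
            if mm <= policy.max_internal_mismatch:
                hits.append(CatalogHit(rec, start, shift5, shift3, mm))
    hits.sort(key=lambda h: (h.mismatches, abs(h.shift5) + abs(h.shift3),
                             h.mature.name))
    return hits


# --------------------------------------------------------------------------
# isomiR naming

_VARIANT_RE = re.compile(
    r"^(?:L(?P<l>[+-]\d+))?(?:R(?P<r>[+-]\d+))?"
    r"(?:(?P<k>\d+)ss(?P<subs>(?:\d+[ACGTUN]{2})+))?$")
_SUB_RE = re.compile(r"(\d+)([ACGTUN])([ACGTUN])")


def name_variant(observed: str, reference_mature: str, precursor_context: str,
                 mature_start: int | None = None,
                 max_shift: int = 5, max_mismatch: int = 4) -> str:
    """Canonical isomiR name of ``observed`` relative to the reference mature.

    The observed read is anchored on the precursor at the placement with
    fewest mismatches (then smallest total end shift); the name encodes the
    end shifts and internal substitutions.  Identical sequences yield "".
    """
    obs = to_dna(observed)
    ref = to_dna(reference_mature)
    pre = to_dna(precursor_context)
    if obs == ref:
        return ""
    if mature_start is None:
        mature_start = pre.find(ref) + 1
        if mature_start == 0:
            raise VariantError("reference mature not found on precursor")
    mature_end = mature_start + len(ref) - 1
    best = None
    for start in range(max(1, mature_start - max_shift),
                       min(len(pre) - len(obs) + 1, mature_start + max_shift) + 1):
        end = start + len(obs) - 1
        if abs(end - mature_end) > max_shift:
            continue
        mm = _hamming(obs, pre[start - 1:end])
        key = (mm, abs(start - mature_start) + abs(end - mature_end), start)
        if best is None or key < best[0]:
            best = (key, start, end)
    if best is None or best[0][0] > max_mismatch:
        raise VariantError("unanchored variant")
    _, start, end = best
    shift5 = mature_start - start   # + = extension
    shift3 = end - mature_end
    parts = []
    if shift5:
        parts.append(f"L{shift5:+d}")
    if shift3:
        parts.append(f"R{shift3:+d}")
    subs = [(i + 1, pre[start - 1 + i], obs[i])
            for i in range(len(obs)) if obs[i] != pre[start - 1 + i]]
    if subs:
        parts.append(f"{len(subs)}ss" + "".join(f"{p}{r}{o}" for p, r, o in subs))
    return "".join(parts)


def parse_variant_name(name: str) -> tuple[int, int, list[tuple[int, str, str]]]:
    """Decode a variant name into (5' shift, 3' shift, substitutions)."""
    m = _VARIANT_RE.match(name or "")
    if m is None:
        raise VariantError(f"malformed variant name: {name!r}")
    shift5 = int(m.group("l") or 0)
    shift3 = int(m.group("r") or 0)
    subs = [(int(p), r, o) for p, r, o in _SUB_RE.findall(m.group("subs") or "")]
    if m.group("k") is not None and int(m.group("k")) != len(subs):
        raise VariantError(f"substitution count mismatch in {name!r}")
    return shift5, shift3, subs


def apply_variant(reference_mature: str, precursor_context: str, name: str,
                  mature_start: int | None = None) -> str:
    """Reconstruct the observed sequence from a variant name (name round-trip)."""
    ref = to_dna(reference_mature)
    pre = to_dna(precursor_context)
    if mature_start is None:
        mature_start = pre.find(ref) + 1
        if mature_start == 0:
            raise VariantError("reference mature not found on precursor")
    shift5, shift3, subs = parse_variant_name(name)
    start = mature_start - shift5
    end = mature_start + len(ref) - 1 + shift3
    if start < 1 or end > len(pre):
        raise VariantError("variant extends beyond precursor")
    seq = list(pre[start - 1:end])
    for pos, ref_base, obs_base in subs:
        if not 1 <= pos <= len(seq):
            raise VariantError(f"substitution position {pos} outside sequence")
        if seq[pos - 1] != to_dna(ref_base):
            raise VariantError(f"reference base mismatch at {pos}")
        seq[pos - 1] = to_dna(obs_base)
    return "".join(seq)


# --------------------------------------------------------------------------
# evidence groups

def assign_group(maps_species_mature: bool, maps_species_precursor: bool,
                 maps_other_species: bool, precursor_on_genome: bool,
                 opposite_arm: bool, hairpin_pass: bool) -> str:
    """Deterministic decision tree over the six evidence groups.

    Flags must be mutually consistent: a mature or opposite-arm hit implies
    a precursor hit.  Raises ``ValueError`` for inconsistent flags or when
    no evidence route supports a miRNA call.
    """
    if maps_species_mature and not maps_species_precursor:
        raise ValueError("inconsistent flags: mature hit without precursor hit")
    if opposite_arm and not maps_species_precursor:
        raise ValueError("inconsistent flags: opposite-arm hit without precursor hit")
    if maps_species_mature:
        return "gp1a" if precursor_on_genome else "gp1b"
    if opposite_arm:
        return "gp2b"
    if maps_other_species and precursor_on_genome:
        return "gp2a"
    if maps_species_precursor:
        return "gp3"
    if precursor_on_genome and hairpin_pass:
        return "gp4"
    raise ValueError("no evidence route supports a miRNA call")


# --------------------------------------------------------------------------
# conservation

def classify_conservation(family: str, species_membership: Iterable[str],
                          conserved_families: Iterable[str] = (),
                          reference_species_count: int = 47) -> str:
    """Tier a family by its cross-species membership.

    ``conserved`` for families on the designated anciently-conserved list;
    otherwise high (>10 species), moderate (5-10), low (2-4),
    non-conserved (1).
    """
    members = set(species_membership)
    if not family or not members:
        raise ValueError(f"unknown family or empty membership: {family!r}")
    if len(members) > reference_species_count:
        raise ValueError("membership exceeds reference species count")
    if family in set(conserved_families):
        return "conserved"
    n = len(members)
    if n > 10:
        return "high"
    if n >= 5:
        return "moderate"
    if n >= 2:
        return "low"
    return "non-conserved"


def family_summary(annotations: Iterable[MiRNAAnnotation]) -> pd.DataFrame:
    """Member counts per family, sorted descending (then by name)."""
    counts: dict[str, int] = {}
    for ann in annotations:
        counts[ann.family] = counts.get(ann.family, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["family", "members"])


# --------------------------------------------------------------------------
# pipeline-level annotation

def _read_in_precursor(seq: str, pre: str, max_mismatch: int = 1) -> int | None:
    """1-based best placement of seq anywhere on the precursor, else None."""
    best = None
    for start in range(len(pre) - len(seq) + 1):
        mm = _hamming(seq, pre[start:start + len(seq)])
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, start + 1)
    return None if best is None else best[1]


def annotate_reads(unique_reads: Sequence, catalog, genome: Mapping[str, str],
                   policy: MappingPolicy = MappingPolicy(),
                   focal_species: str = "gma"
                   ) -> tuple[list[MiRNAAnnotation], list]:
    """Annotate collapsed reads against a catalog; return (annotations, unmapped).

    Routes each read through the evidence tree: focal-species mature arm
    (gp1a/gp1b), opposite arm (gp2b), other-species mature (gp2a), elsewhere
    on a focal precursor (gp3).  Reads with no catalog evidence are returned
    for hairpin-based novel prediction (gp4 candidates).
    """
    focal = catalog.matures(focal_species)
    others = catalog.other_species_matures(focal_species)
    genome_seqs = [to_dna(s) for _, s in sorted(genome.items())]
    conserved = catalog.conserved_families
    fam_species = {f.family: f.species for f in catalog.families}
    star_spans = {f.family: f.star_span for f in catalog.families}

    def on_genome(pre: str) -> bool:
        return any(pre in g for g in genome_seqs)

    annotations: list[MiRNAAnnotation] = []
    unmapped: list = []
    for ur in unique_reads:
        seq = to_dna(ur.sequence)
        hits = map_to_catalog(seq, focal, policy)
        if hits:
            h = hits[0]
            rec = h.mature
            group = assign_group(True, True, False,
                                 on_genome(to_dna(rec.precursor_seq)), False, False)
            variant = name_variant(seq, rec.sequence, rec.precursor_seq,
                                   mature_start=rec.start)
            tier = classify_conservation(rec.family, fam_species[rec.family], conserved)
            annotations.append(MiRNAAnnotation(
                seq, rec.name, rec.family, rec.arm, group, variant, tier,
                dict(ur.counts)))
            continue
        placed = None
        for f in catalog.families:
            pos = _read_in_precursor(seq, to_dna(f.precursor_seq),
                                     policy.max_internal_mismatch)
            if pos is not None:
                placed = (f, pos)
                break
        if placed is not None:
            f, pos = placed
            s_lo, s_hi = star_spans[f.family]
            overlap = min(s_hi, pos + len(seq) - 1) - max(s_lo, pos) + 1
            opposite = overlap >= max(1, len(seq) // 2)
            group = assign_group(False, True, False,
                                 on_genome(to_dna(f.precursor_seq)), opposite, False)
            arm = f.star_arm if opposite else f.mature_arm
            tier = classify_conservation(f.family, fam_species[f.family], conserved)
            annotations.append(MiRNAAnnotation(
                seq, f"{focal_species}-{f.family}-{arm}" if opposite
                else f"{focal_species}-{f.precursor_name}", f.family, arm,
                group, "", tier, dict(ur.counts)))
            continue
        other_hits = map_to_catalog(seq, others, policy)
        if other_hits:
            h = other_hits[0]
            rec = h.mature
            if on_genome(to_dna(rec.precursor_seq)):
                variant = name_variant(seq, rec.sequence, rec.precursor_seq,
                                       mature_start=rec.start)
                tier = classify_conservation(rec.family, fam_species[rec.family],
                                             conserved)
                annotations.append(MiRNAAnnotation(
                    seq, rec.name, rec.family, rec.arm, "gp2a", variant, tier,
                    dict(ur.counts)))
                continue
        unmapped.append(ur)
    return annotations, unmapped


def annotations_frame(annotations: Sequence[MiRNAAnnotation],
                      libraries: Sequence[str]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        row = {"sequence": a.sequence, "mirna": a.mirna_name, "family": a.family,
               "arm": a.arm, "group": a.group, "variant": a.variant_name,
               "conservation": a.conservation}
        for lib in libraries:
            row[f"count_{lib}"] = a.counts.get(lib, 0)
        rows.append(row)
    return pd.DataFrame(rows)
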