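# Methods

This note records the models, definitions and numerical choices behind
`mircms`, in the order the pipeline runs, together with what the bundled
synthetic data does and does not establish about real data.

## Synthetic data model

The generator (`mircms.synthetic_data`) emulates the statistical structure
of a two-condition plant flower-bud sRNA experiment.  One root seed feeds
named RNG streams (`default_rng([seed, crc32(stream_name)])`), so every
output is byte-reproducible and stages can be regenerated independently.

**Catalog.**  Each miRNA family gets a constructively built hairpin
precursor: a random stem arm containing the mature sequence, a 6–12 nt
loop, and the reverse complement of the arm, plus short unstructured
leaders.  A candidate precursor is accepted only if its own fold passes
all 11 structural criteria (rejection sampling); this is what entitles the
truth table to call these loci positives for the hairpin filter.  Mature
lengths are drawn from the read-length weights so the mature-derived read
population carries the configured 24 > 21 > 22 nt mode observed in plant
flower-bud libraries (weights: 18:0.02, 19:0.03, 20:0.08, 21:0.22,
22:0.15, 23:0.10, 24:0.30, 25:0.10).  Families cycle through the four
conservation tiers (membership sizes 1, 2–4, 5–10, ≥11 drawn per tier
against a 47-species pool), with a configurable fraction flagged as
anciently conserved.

**Reads.**  A read is insert + 3' adapter (default
`TGGAATTCTCGGGTGCCAAGG`, the common sRNA adapter), with constant high
quality except for a small injected low-quality fraction (2%) that
exercises the quality filter.  Inserts are matures, isomiRs (end shifts of
up to ±2 nt drawn from the precursor plus at most one internal
substitution; 20% of miRNA-derived reads by default), star-arm reads (4%),
ncRNA decoys (10%; substrings of generated rRNA/tRNA/snRNA/snoRNA
reference sets, standing in for Rfam-style references so no download is
needed) and random background (15%).  Per-family abundances are
log-normal (σ = 0.6).  Depths and quality distributions are not dictated
by any published description and are desk-scale choices: 20,000 reads per
library by default.

**Genome.**  One contig per catalog precursor (precursor flanked by
130 nt of random sequence), plus novel-miRNA loci and decoy loci.  A
novel locus is a compliant hairpin containing a read that is *not* in the
catalog; it is rejection-sampled until the full flank-window prediction
accepts it, making generator positives detectable by construction.
Decoy loci embed a random read in random sequence with no guarantee, so
specificity is a genuine measurement.

**Degradome, counts, annotation.**  Target sites are perfect reverse
complements of catalog matures implanted into random transcripts
(300–600 nt); the recorded cleavage position is the transcript nucleotide
opposite miRNA position 10.  Tag libraries put ~25 tags (Poisson) with 5'
ends exactly at each cleavage site over a uniform background
(`depth × background_rate` tags).  The two libraries draw overlapping
target subsets (60% shared) to plant a known Venn partition.  Gene counts
are negative binomial (dispersion 0.05 by default; 0 gives Poisson) with
exactly `round(n_genes × de_fraction)` spiked genes at ±`de_log2fc`
(default 2), split symmetrically around the base mean.  Gene→term
annotation includes one planted motif: the first family's target genes all
share one term, so the term-restricted network has a known hub family.

**What passing on synthetic data does not show.**  The generator has no
sequencing-error or base-composition model, no genomic repeat structure,
no multi-branch precursors, and exact-match read placement suffices at
its scale.  Results on real data additionally depend on alignment
heuristics, thermodynamic folding accuracy and annotation quality that
the synthetic suite deliberately excludes.

## Preprocessing definitions

"Junk/low complexity" = any non-ACGTUN symbol, or one nucleotide making
up ≥80% of the read.  Adapter trimming removes the longest read suffix
matching an adapter prefix of ≥6 nt (`min_overlap`); a match starting at
read position 1 is an adapter dimer and is discarded.  Records with mean
Phred < 20 are dropped before trimming.  ncRNA removal is exact or
substring matching against the reference sets (substring by default; no
alignment heuristics, which keeps the stage deterministic).  T and U are
equivalent; sequences are stored as DNA.  Normalisation is
reads-per-million of each library's kept total.  The stats report keeps
two unique-read counters — after the length filter (`clean_unique`) and
after ncRNA removal (`valid_unique`) — because published pipelines print
both notions without defining them; we expose both rather than guessing.

## Catalog mapping and isomiR names

A read hits a mature if it aligns inside the precursor with 5'/3' end
shifts within the policy (default ±2 nt each) and ≤1 internal mismatch;
end shifts are not counted as mismatches.  Ties are broken by fewest
mismatches, then smallest total shift, then lexicographic name, making
outputs deterministic.  Variant names are `L±n`/`R±m` for end extensions
(+) or trims (−) and `kss` blocks listing substitutions as 1-based
position on the observed sequence, reference base, observed base,
ascending.  `name_variant` and `apply_variant` are exact inverses, which
the test suite verifies over thousands of generated isomiRs.

The six evidence groups are a decision tree (the upstream tool's exact
definitions are proprietary, so the tree is this package's documented
interpretation): gp1a = focal-species mature hit with the precursor
locatable on the genome; gp1b = mature hit, precursor not on the genome;
gp2b = hit on the arm opposite an annotated mature (novel 5p/3p
candidate); gp2a = other-species mature hit with genome support; gp3 =
precursor hit outside any mature arm; gp4 = no catalog hit but a
genome-anchored hairpin passing the criteria.  gp1a/gp1b constitute the
conserved evidence class.  Conservation tiers close the printed 5–9 /
>10 gap downward: membership 10 is moderate, high is strictly >10.

## Folding and the 11 criteria

`fold_simple` computes the maximum-pairing nested structure (Nussinov
dynamic programming over Watson–Crick + G:U with a minimum hairpin loop
of 3 nt) with a deterministic traceback that prefers closing the outer
pair, i.e. extending helices.  Free energy is a per-stacked-pair
approximation — each pair whose inward neighbour is also paired
contributes GC −2.2, AU −1.1, GU −0.6 kcal/mol — not a thermodynamic
minimum; a 20-bp GC stem therefore scores 19 × −2.2 = −41.8.  Users with
RNAfold output can bypass the stand-in entirely: `parse_vienna` reads
name/sequence/dot-bracket(−ΔG) blocks.

A maximum-pairing fold of a ~140 nt genomic window is generally branched,
so `predict_novel` extracts the stem-loop unit containing the read
(walking outward from each terminal loop while the helix chain is
unbranched) and evaluates the criteria on that unit — the same hairpin
extraction idea used by miRNA predictors.  Both the upstream
(read + 120 nt) and downstream windows are folded; one passing window
suffices.

Criterion definitions on the annotated structure (mature span clipped to
the unit; the full read length is the denominator of the in-stem
fraction):

* **stem bulge ≤ 12 nt** — a bulge is the unpaired region between two
  consecutive stem pairs; its size counts both strands.
* **stem ≥ 16 bp** — pairs in the unit.
* **ΔG ≤ −15 kcal/mol** — stacking model above, on the unit's pairs.
* **hairpin ≥ 50 nt** — outermost pair to its partner (stems + bulges +
  terminal loop).
* **loop ≤ 200 nt** — terminal-loop span.
* **mature bulge ≤ 4 nt** — bulges with ≥1 unpaired nucleotide inside the
  mature span; size counts both strands.
* **biased errors per bulge ≤ 2** — |5'-side − 3'-side| unpaired counts of
  such a bulge.
* **biased bulges ≤ 2** — mature-region bulges entirely on one strand.
* **mature errors ≤ 4** — unpaired mature nucleotides lying in the stem;
  loop overhang is deliberately excluded because the in-stem fraction
  criterion already penalises it.
* **mature ≥ 12 bp** — paired mature nucleotides.
* **mature in stem ≥ 80%** — mature nucleotides inside the stem region.

Counting mature-bulge size on both strands while counting errors on the
mature strand only is what makes the 11 criteria independently violable
(a 5-nt one-sided mature bulge would otherwise always drag the error
criterion down with it); the fixture suite holds one hairpin per
criterion failing exactly that criterion.  These terms are nowhere given
operational definitions in the literature that names them, so the above
are this package's definitions, isolated in `HairpinCriteria` and
`evaluate_criteria` so alternatives can be swapped.

## Degradome scoring and categories

Duplex score = minimum over gapped antiparallel alignments of per-position
penalties: mismatch 1, G:U 0.5, gap 1, each doubled at miRNA positions
2–13 (a gap takes the factor of the next miRNA position consumed).  The
DP is checked against exhaustive alignment enumeration for short
duplexes.  Site search is anchored: for every transcript position with
tags and every miRNA, the unique window placing miRNA position 10
opposite that position is scored — equivalent to scanning all sites and
then requiring tag support, but linear in the number of tagged positions.
Score ≤ 4 keeps an interaction (so 4.5 is out); the cleavage position is
1-based, opposite miRNA position 10.

Categories use c = tag count at the site, M = transcript maximum, median
over positions with >0 tags, evaluated in order: 0 (unique maximum,
c > 1), 1 (tied maximum, c > 1), 2 (c < M, c > median), 3 (c ≤ median,
c > 1), 4 (c = 1).  When every tagged position has the same count > 1 the
ordered evaluation lands on category 1; ties at the median go to 3.
Degradome tags are mapped to the transcriptome (cDNA), not the genome,
and multi-mapping tags count at every locus.

## Differential expression

miRNA DE is a two-sample t-test on RPM across replicates; with one
library per condition the p-value is undefined and only the fold-change
rule applies (both designs occur in sRNA studies, so both are supported).
Zero variance in both groups with equal means gives p = 1.  Gene DE pools
replicate columns into two libraries and tests each gene's proportion
difference with a pooled two-proportion z-test, falling back to an exact
binomial test when the pooled count is <10.  This targets the same
inferential quantity as DEGseq's MA-plot method without reproducing its
exact algorithm.  Because the proportion test models multinomial
sampling, its calibration checks (null type-I error, spike recovery) are
run on Poisson matrices (dispersion 0) — the test's own sampling model —
while the generator default (dispersion 0.05) is used for ordinary
pipeline runs.  Fold changes use a pseudo-count of 1 on the
RPM/proportion scale; exclusive expression (zero in exactly one
condition) is a separate column.  BH adjustment is the step-up procedure,
verified against the max–min closed form and statsmodels.  Two gene
thresholds ship as named presets (`results`: FDR ≤ 0.05 and |lfc| ≥ 1,
the default; `methods`: corrected P < 0.005 and |lfc| ≥ 1) because both
appear in practice for this design; the package does not adjudicate.

## Enrichment and network

Plain upper-tail hypergeometric per term; no gene-length bias correction
(the Wallenius-type correction needs a real length/DE coupling that the
synthetic scope does not model — a documented divergence from GOseq-style
pipelines).  BH is applied within each namespace (BP/CC/MF/pathway)
separately, a deliberate choice where the convention is ambiguous.  The
universe is an explicit required input.  The network keeps enriched
terms, their genes, and the miRNAs targeting those genes; edges are typed
(annotation, targeting) and there are never term–miRNA edges.  GraphML
round-trips attributes; SIF keeps topology.

## Problem sizes and determinism

Default analysis scales (20k reads/library, 24 families, 600 genes, 200 +
200 novel/decoy loci in the acceptance suite) were chosen so a complete
run takes tens of seconds on one CPU while keeping every statistical
check well-powered; all are config fields.  Folding results are memoised
per sequence.  Every random draw descends from the single seed, writers
iterate in sorted order, and no output embeds timestamps, so same-seed
runs are byte-identical — which the acceptance suite verifies literally.

## Known limitations

Maximum-pairing folding overestimates pairing relative to thermodynamic
MFE structures, and the stacking energies are a caricature; criteria
involving ΔG are only meaningful relative to this model (or to imported
Vienna energies).  Read placement is exact-match (no seed-and-extend
alignment), sense strand only.  Multi-branch precursors and pseudoknots
are out of scope.  The gene-DE route inherits the two-library proportion
test's assumption that replicates are exchangeable libraries; it is
anticonservative under strong biological overdispersion, as all tests of
its class are.
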