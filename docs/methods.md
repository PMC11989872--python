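# Methods

## The identification problem

In a heterograft, the scion (here a cultivated-tomato-like genotype) and
the rootstock (a wild-relative-like genotype) are distinct genomes joined
through a common vasculature. A transcript transcribed in one partner and
detected in tissues of the other implies phloem-mediated long-distance
transport. Detection is a genome-of-origin classification problem: every
RNA-seq read from a graft tissue must be attributed to the scion or the
rootstock genome, with sequencing errors and sequence conservation between
the genotypes as the confounders.

The sampled design is "one grafted plant — three samples": scion leaf
(HL), rootstock root (RR), and the leaf of a lateral branch left on the
rootstock (RL), each under control (CK) and drought, with three biological
replicates. Upward mobility is rootstock → scion (detected in HL);
downward mobility is scion → rootstock (detected in RR and/or RL).

## Read classification

Per sample, QC-passed reads go through three stages:

1. **Native mapping.** Reads are mapped to the sample's own genotype
   reference with a semi-global bounded-edit-distance aligner (unit-cost
   Levenshtein; the read is fully consumed, the reference is local). The
   first-pass cap is k = 2 edits. Mapped reads are native transcription.
2. **Cross-check arbitration.** Each unmapped read is searched against
   *both* references with a BLASTN-like seeded local aligner (word size
   11; scoring match +2, mismatch −3, gap open −5, gap extend −2). A hit
   requires the best local alignment to cover ≥ 50 % of the read at
   ≥ 80 % identity. The read is assigned to the genome it matches best:
   candidate mobile (set A/A′) iff its foreign hit outscores any native
   hit; otherwise, any native hit makes it a cross-mapping false positive
   (set B/B′); no hit anywhere discards it. The best-score rule rather
   than "any native hit disqualifies" is essential: at realistic genotype
   divergence (here 5 %) a genuinely mobile read still produces a native
   local hit on its ~95 %-identical ortholog, so a disqualify-on-any-hit
   rule would empty the candidate set entirely. Ties — e.g. reads from
   segments identical in both genotypes — are conservatively assigned to
   the native genome.
3. **Second-pass foreign mapping.** Candidate reads are mapped to the
   foreign reference at the stricter cap k = 1. Reads that map are
   retained (set C/C′) and accumulated into per-gene support counts.

A gene is called mobile in a tissue × condition group (sets D/D′ minus
E/E′) iff it has ≥ 2 retained reads in ≥ 2 of 3 replicates **and** is
expressed in its source tissue — raw count ≥ 5 in ≥ 2 source replicates.
The source of downward candidates is the scion leaf (HL); the source of
upward candidates is the rootstock, whose root and lateral-leaf samples
are pooled per replicate. The source-expression rule excludes genes whose
apparent foreign reads cannot be transcripts that ever existed in the
donor tissue. The per-gene read floor (2) and the expression threshold
(5 in 2) are configurable; the defaults suppress singleton-error
artifacts while keeping single-fragment paired evidence (two mates)
sufficient.

## Alignment internals

The bounded-edit-distance mapper is seed-and-verify. A k-mer index
(default 21-mers, forward strand; reverse-strand placements are found by
probing the read's reverse complement) nominates candidate diagonals via
probes placed at a pigeonhole-safe stride: any placement within e edits
leaves an error-free block of ⌊L/(e+1)⌋ bases, which contains a run of
consecutive exact k-mer starts, and the stride never exceeds that run.
Candidate windows are verified exhaustively with banded dynamic
programming (edlib, infix mode), so the reported distance is the true
minimum over all placements; ties are broken by lowest (chromosome,
start), then + strand. Reads too short for the pigeonhole guarantee fall
back to a full scan of every chromosome. An exact-match fast path
resolves error-free reads by direct lookup.

The local cross-check aligner replaces BLAST's E-value machinery with the
explicit coverage + identity criterion above, calibrated so random
150-mers against a 100 kb reference produce no spurious hits (empirically
< 10⁻³ per read). Identity is computed as identities over alignment
columns, coverage as the aligned query span over read length. Window
scoring is two-phase: score-only over the seeded windows, one full
traceback alignment on the best window.

Mates are classified independently; gene-level evidence requires multiple
reads, which absorbs mate-level noise.

## Transport patterns and condition specificity

Downward mobile genes are partitioned by receiving-tissue membership:
detected in RL only (moved to the distal leaf without passing the root),
in RR only (degraded or diluted below detection in transit), or in both
(moved scion → root → leaf). These are set-theoretic labels; no kinetic
decay model is fitted, because the underlying claim is set membership.
Condition-specific sets are the exact three-way Venn partition of CK vs
drought calls per tissue × direction.

## Quantification and the abundance–mobility question

Counting is best-hit-only; TPM is

    TPM_g = (c_g / L_g[kb]) / Σ_h (c_h / L_h[kb]) × 10⁶

with L_g the exon-model length of the gene's longest transcript. Source
abundances are binned into six classes — (0,1], (1,10], (10,100],
(100,500], (500,1000], (1000,∞); the (100,500] interval is included so
the six classes partition (0,∞).

Whether mobility tracks abundance is tested, rather than plotted: the
summed abundance rank of the mobile genes is compared against a
permutation null (mobile set redrawn uniformly, default ≥ 1000
permutations, two-sided add-one p-value), and the overlap between the
mobile set and the top-100 most abundant source genes is reported. Under
a null mobile set the p-values are uniform (verified by KS calibration in
the test suite).

## The synthetic experiment generator

The simulator emulates the full design with no external data. A base
genome (default 300 single-exon genes of 800–1600 nt on 3 chromosomes,
separated by intergenic spacers) represents the scion; the rootstock
genome is derived from it by i.i.d. substitutions (default 5 % per site)
plus short indels (default 0.2 % per site, ≤ 3 nt), with gene models
lifted over and every difference recorded in a variant table. Indel
events that would delete a gene boundary are dropped so coordinate
liftover stays well defined. Tissue × condition expression profiles are
log-normal (σ = 1.2), normalized to sum 10⁶.

Mobile genes are spiked as full-length source-genotype transcripts into
the sink samples' read pools. Reads are drawn multinomially with weights
TPM × transcript length; fragments are Normal(320, 40) nt, 150 bp
paired-end, with i.i.d. substitution errors (default 10⁻³ per base) and
phred 30–40 quality strings, so the quality pre-filter (mean phred > 20,
N fraction ≤ 0.10) passes essentially everything. All randomness derives
from one master seed through named sub-streams; a fixed seed reproduces
every output file byte for byte.

Two abundance conventions matter and are deliberate:

* **Sink abundance scale.** On a 300-gene transcriptome normalized to
  10⁶, the mean native gene sits at ~3333 TPM — roughly 100× the mean of
  a full-size (~35 k gene) transcriptome. The default spiked sink
  abundance range, 200–5000 TPM (log-uniform), therefore corresponds to
  ~2–50 TPM on a full-size transcriptome: the low-relative-abundance
  regime in which real mobile transcripts are reported, scaled to the
  simulated transcriptome so that recovery is exercised at practical
  sequencing depth (default 30 000 fragments per sample). An absolute
  2 TPM spike would require millions of fragments per sample to yield
  even one read, which is a property of TPM arithmetic, not of the
  pipeline.
* **Source detectability.** Mobile genes are drawn from genes whose
  source-tissue abundance is ≥ 500 TPM (simulated scale) in their active
  conditions. This mirrors biology — a mobile transcript is by definition
  transcribed in its source — and is required for internal consistency:
  the E/E′ filter would otherwise correctly reject a spiked gene that the
  simulator made source-silent.

Downward spikes are partitioned into the three transport classes by
deterministic rounding of the configured fractions (defaults 0.34
RL-direct, 0.33 RR-only, remainder through-root, mirroring the observed
relative class sizes); a configurable fraction (default 0.25) is made
drought-specific. What the generator does **not** emulate: splicing,
PCR duplication, GC bias, strand-specific chemistry, adapter
contamination, structural variation between the genotypes, and conserved
(zero-divergence) gene families. Passing recovery tests therefore
demonstrates the correctness of the set algebra and the origin
classification under the stated divergence model, not robustness to
assembly errors or paralogy in real genomes.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GFF3 I/O converts at the
  boundary.
* Multi-transcript genes use the longest transcript's summed exon span as
  the TPM length.
* A read failing both QC rules is counted once, under low quality.
* The aligner's tie-break (lowest chromosome, start, + strand) and the
  stable sort orders in every output table make runs reproducible to the
  byte.
* CK and drought groups are processed independently and merged
  downstream; a gene may be mobile in one, both, or neither condition.
* The graft union is not sampled in this design, so "moved without
  passing the root" is a statement about RR/RL membership, not about the
  route through the union.
* Problem sizes in the validation suite (300 genes per genotype, 30 000
  fragments per sample, 3 replicates; smaller for fixtures) are the
  package's chosen desk-scale design point; all thresholds are
  configurable for larger runs.

## Known limitations

* Homograft control samples are not modeled; the false-positive sets are
  derived from cross-searching the sample's own genotype reference.
* Multi-mapping reads resolve to a single deterministic best hit; no
  fractional assignment.
* The local-alignment hit criterion approximates BLASTN's E-value
  behavior at desk scale; exact Karlin–Altschul statistics are not
  computed.
* Isoform-level quantification and differential expression are out of
  scope.
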