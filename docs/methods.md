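# Methods

`tlaphase` models Targeted Locus Amplification (TLA) haplotyping end to end:
a generative model of TLA sequencing libraries, a chimeric-read mapper that
splits reads at restriction sites, a depth-filtered genotype caller, a
link-based phaser, and concordance benchmarking against the generated truth.
This note records the model, its assumptions, the parameters that matter, and
the numerical choices behind the implementation.

## The generative model

**Diploid locus.** A locus is a reference sequence (A/C/G/T only) plus an
ordered, non-overlapping set of phased SNVs and small (1–3 bp) INDELs.
Applying one haplotype's alleles yields the haplotype sequence and a monotone
coordinate map; positions strictly inside a replaced span map to −1. The
synthetic-locus generator places variants at least 60 bp apart inside the
central region of the locus (22–78 % by default, which also serves as the
region of interest for coverage metrics), rejects edits that would create or
destroy an NlaIII site (so reference and haplotype fragment grids stay
congruent), and accepts only canonical (left-normalized) indel
representations.

**Digestion.** NlaIII recognizes CATG and leaves a 3′-CATG overhang; the
implementation cuts immediately after the motif (`cut_offset = 4`), so every
fragment except the last keeps CATG at its 3′ end. The orientation of the
convention is a free choice as long as the simulator and splitter share it.
IUPAC-degenerate motifs (NspI, RCATGY) are supported by character-class
expansion; NspI's role in the assay (promoting circularization) is captured
by the amplicon length bounds rather than by a second digestion.

**Circles.** A ligation circle draws one haplotype uniformly, always contains
that haplotype's viewpoint fragment, and adds further fragments of the *same*
haplotype without replacement with probability ∝ (1 + d)^(−α), where d is the
ordinal fragment distance from the viewpoint and α (`decay_exponent`,
default 1.0) controls the steepness of the contact decay — a power law is the
standard proximity-ligation contact model. A geometric number of extra
fragments (mean 3) is drawn, but in practice circle size is governed by the
amplicon bounds: fragments keep being added until the minimum amplicon length
(default 4,000 bp) is reached, and circles over the maximum (10,000 bp) are
rejected and resampled. With ~256 bp mean NlaIII fragments this yields ~16
fragments per circle. Two deliberate departures from naive sampling:

- *Fragment order within the circle is random* (orientation stays forward —
  no inversions). Random ligation order is what lets a single molecule
  juxtapose genomically distant fragments; it is the entire phasing signal
  for short reads.
- *Window-edge fragments never circularize.* Their outer boundary is the
  locus edge, not a cut site, so they are not true restriction fragments and
  would create junctions without a recognition motif.

**Amplicons and reads.** An amplicon is the circle rotated so position 0 is
the forward primer inside the viewpoint fragment (the viewpoint fragment is
therefore split into a leading and a trailing piece). Per-base provenance —
(haplotype, reference interval) for every stretch — is carried through to
every read. Two platform profiles:

| parameter            | short (Illumina-like) | long (Nanopore-like) |
|----------------------|-----------------------|----------------------|
| read structure       | 150 bp pairs, insert 300–600 bp | whole amplicon |
| substitution rate    | 0.001                 | 0.02                 |
| indel rate           | 0                     | 0.01                 |
| amplicon sampling    | ∝ length              | ∝ length^(−β), β = 1 |
| base quality         | Q35 constant          | Q12 constant         |

The long-mode length bias (shorter amplicons sequenced preferentially)
mirrors nanopore behaviour. Error rates are configurable; the long-mode
defaults correspond to a ~3 % total error channel (super-accuracy-basecaller
era). Qualities are constant per platform; quality trimming is out of scope
(the mapper's `min_segment_len` plays the corresponding role downstream).
PCR duplication is implicit: reads sample circles with replacement and no
deduplication is performed anywhere.

## Split mapping

Reads are chimeric, so the mapper iterates: align, split at the recognition
site nearest the mapped clip, re-align.

- **Seeding/extension.** An exact k-mer index (k = 21) over all references
  (decoys included) nominates diagonals on both strands; candidates are
  ranked by seed votes and capped at 32. Each diagonal is scored gaplessly:
  the best-scoring run under match +1 / mismatch −2 (computed with a
  vectorized prefix-minimum scan). A segment is *fully mapped* when both
  soft-clips are shorter than `min_segment_len` (15 bp) and the run's
  mismatch count is within `max_mismatch_rate` (0.05 short, 0.15 long).
- **Splitting.** If a clip of at least `min_segment_len` remains, the read is
  split at the recognition-site cut position closest to the clipped end of
  the mapped run, in read space (the junction motifs physically exist in the
  read; CATG is its own reverse complement, so motif finding is strand-free,
  while the cut side follows the mapped strand's convention). One
  correction matters: a gapless run always extends `cut_offset` bases through
  the junction motif on the side where the motif adjoins the fragment in the
  reference, so the clip boundary is shifted by that offset before choosing
  the nearest site; ties break toward the read 5′ end. Both parts are then
  re-mapped, and the iteration continues until everything is mapped or no
  site remains. Remnants (unmapped, too short, or sub-seed) are reported,
  never silently dropped; segments and remnants always tile the read exactly.
- **Indel rescue (long mode).** Motifs inside a read occur only at ligation
  junctions, so while any site remains, splitting takes priority. A segment
  with no remaining site whose gapless run still leaves a clip is rescued by
  an edit-distance-bounded alignment (edlib, budget `max_mismatch_rate` ×
  length) around the best diagonals — this absorbs sequencing indels and
  small truth indels without absorbing junctions.
- **Ambiguity.** Co-optimal placements (e.g. a segment inside a stretch
  conserved between a gene and its pseudogene decoy) set the `ambiguous`
  flag. The default policy `keep` places the segment by a stable hash —
  reproducible, but mirroring an aligner's arbitrary multi-mapper placement;
  `drop` and `random` are available for experiments. Paired mates are mapped
  independently as single-end reads.

Segments shorter than k carry no seeds and are unmappable by construction.
This reproduces small-fragment dropout: a fragment between two NlaIII sites
closer than k is sequenced but never directly aligned; its bases reach the
reference only in the rare circles that religate its two original neighbours
around it, restoring contiguity.

## Pileup and calling

Every aligned, non-clipped base adds one to depth at its reference position;
depth counts fragments, so two segments of one read overlapping a position
(self-ligation) count twice. Indels are decoded from the alignment path;
indel operations separated by at most 3 match columns are merged into one
composite event (edit-distance paths fragment multi-base indels into
arbitrary co-optimal patterns), then left-normalized against the reference —
this makes the allele representation stable and comparable with the planted
truth. Calling applies the platform depth filter first — 25× for short
reads, 100× for long reads — then allele-fraction rules: ALT fraction within
[0.25, 0.75] and at least 5 supporting reads → 0/1; ALT fraction ≥ 0.85 →
1/1. The fraction thresholds are this package's own defaults (the depth
filters are the assay's published operating points; raw position depth is
used). The short-read mapper is gapless, so short-read runs do not call
indels; this is a documented platform asymmetry of the implementation, not
of the assay.

## Link phasing

All split segments of a read, and both mates of a pair, derive from one
circle and hence one homologous chromosome. For every molecule the allele at
each covered heterozygous call is extracted (indel alleles require the
segment to span the full allele plus a 1 bp anchor on each side;
conflicting observations within a molecule are discarded), and every
co-observed pair contributes to a link's cis (same allele class) or trans
count. Links with |n_cis − n_trans| = 0 carry no orientation evidence.
Connected components of the weighted link graph become phase blocks; within
a block, a maximum-weight spanning tree fixes relative orientations, sides
propagate from the highest-degree node, and a deterministic local refinement
(single flips, then joint pair flips, each followed by re-convergence)
escapes shallow local optima. The refinement never exceeds the exhaustive
optimum, is exact on tree-shaped link graphs, and matches the brute-force
oracle on 96–99 % of dense random 8-variant instances. Blocks are
canonicalized so the lowest-position variant sits on side 0; the brute-force
enumerator (≤ 12 variants, lexicographic tie-break) is the correctness
anchor in the tests. Output follows VCF conventions: `|`-separated genotypes
with a PS tag equal to the 1-based position of the block's first variant.

## Benchmarking

Genotype comparison per class (SNV/INDEL): *covered* = truth variants whose
position reaches the depth filter; *concordant* = call matching position,
alleles and unphased genotype; *discordant* = calls absent from the truth or
with a mismatched genotype; *missing* = covered truth variants with no call
at that site (truth variants below the filter are counted in the reference
total only). Phasing comparison evaluates each block under the global
orientation (flip or not) that maximizes per-variant agreement — all metrics
are invariant to block flips — and counts switch errors as adjacent changes
of the per-variant concordance state along the position-sorted block.

## Scenario presets and problem sizes

Presets encode the assay's qualitative contrasts at desk scale; matched
pairs share a seed and hence a locus. Sizes were chosen so that every
variant position clears the platform depth filter under the contact decay
(long-read presets: ~1,800 whole-amplicon reads on a 12 kb locus give
≥ 150× at the ROI edges; short presets: ~5,000 pairs give ≥ 30×).

- `noise_free_long` — error rates zero, one het-containing viewpoint;
  the clean end-to-end recovery case (100 % concordance, one block,
  no switch errors).
- `small_gene_short` / `four_viewpoints_short` — one- and four-viewpoint
  short-read analyses; the multi-viewpoint preset pools per-viewpoint reads
  before the pileup (the combined analysis).
- `homolog_short` / `homolog_long` — the locus is shadowed by a 94 %-identity
  homolog that is both a mapping decoy and a read source (the same primers
  enrich it, carrying no variants), mirroring a pseudogene. Short reads
  produce at least as many discordant calls and phase at most as many hets
  as long reads on the matched seed.
- `viewpoint_with_het_short` / `viewpoint_no_het_short` — a 24 kb locus with
  steeper decay (α = 1.3) and 5,000 pairs. On a large locus, pairwise
  fragment co-occurrence in circles is rare, so the link graph is sparse and
  hinges on the viewpoint fragment, which is in every circle: a het inside
  it becomes the linking hub, while a viewpoint far from any het leaves
  distant hets poorly linked and poorly covered. On small dense loci this
  contrast saturates and disappears, which is why this pair uses a larger
  locus than the other presets.

Every stage draws from named substreams spawned from the single run seed, so
any stage can be re-run in isolation and two runs of the same configuration
are byte-identical (the manifest stores SHA-256 checksums of every artifact;
the log file is excluded from the manifest).

## What the simulator does and does not emulate

Emulated: haplotype-pure circular ligation, contact-distance decay from the
viewpoint, 4–10 kb amplicons anchored at the primers, platform read lengths
and error channels, PCR duplication (implicitly), pseudogene homology as
both decoy and read source, small-fragment dropout, coverage decay.

Not emulated: basecalling artifacts and quality-score structure (qualities
are constant, so quality-aware trimming and calling cannot be studied),
barcode demultiplexing and pooling, crosslinking efficiency and chromatin
structure beyond the power-law decay, structural variants and hybrid
alleles, inverted ligation junctions, allele-specific amplification bias.
Passing tests therefore demonstrate correctness of the pipeline's logic
under this generative model, not calling performance on real instrument
data; in particular the uniform per-position divergence of the synthetic
homolog understates the long conserved stretches of real pseudogenes, which
makes short-read ambiguity milder here than in real pharmacogene data.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; VCF I/O is 1-based.
- Tie-breaks are deterministic everywhere (position order, then
  lexicographic; stable hash for the `keep` multi-mapper policy), so runs
  reproduce bit-for-bit.
- A motif-free sequence digests to a single fragment; an empty variant list
  yields the identity coordinate map; zero circles yield valid empty
  outputs; an unphasable (link-free) het set yields singleton blocks, and a
  comparison against an unphased call set yields zero phased counters, not
  an error.
- Circles that cannot satisfy the amplicon bounds raise a simulation error
  naming the bounds after 200 attempts.
- The k-mer index stores plain Python dictionaries; references up to a few
  hundred kb are comfortable on one core, which covers the intended
  desk-scale use.
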