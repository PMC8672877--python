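# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open.  The two deliberate
exceptions are the GFF3 boundary (1-based inclusive per the standard,
converted on read and restored on write) and human-facing span reports,
where `span_length(start, end) = end - start + 1` reproduces the convention
of published genome papers (a fragment printed as "139 bp (211,858 to
211,996)").  N bases count toward interval lengths but are excluded from the
numerator and denominator of every GC ratio; a window consisting only of N
is never classified AT-rich.

## AT-rich block segmentation

An AT-rich block is defined by two GC-deficit conditions evaluated jointly:
block GC must be at least `delta_gene` (default 12) points below the mean GC
of annotated genes and at least `delta_genome` (default 6) points below the
whole-genome GC.  Because both must hold, the effective threshold is
`ceiling = min(gene_gc - delta_gene, genome_gc - delta_genome)`; a ceiling
at or below zero is rejected as degenerate.  `gene_gc` is computed over the
union of gene spans, introns included — the annotation-level statistic, not
a CDS-level one.

Segmentation operates at base resolution:

1. **Classification.** A base is flagged when the `window`-wide (default
   500 bp) window centred on it, clipped into chromosome bounds, has
   GC <= ceiling.  This is the limit of a strided-window scan as the step
   shrinks to one base; it makes results independent of any step parameter
   (the `step` field only affects the tiled `gc_profile` output).  The
   implementation uses prefix sums; the test suite re-derives the same rule
   with a naive per-base loop and requires exact agreement.
2. **Run merging.** Maximal flagged runs separated by fewer than
   `merge_gap` (default 100) unflagged bases are merged, so a single high-GC
   island does not split one RIP relic into two blocks.
3. **Edge refinement.** The centred window overshoots a sharp GC step by up
   to half a window.  Each end is therefore walked inward while the terminal
   `edge_window` (default 100 bp) still exceeds the ceiling, which places
   boundaries within a few tens of bases of a planted segment edge.
4. **Trimming.** Ends are trimmed to A/T bases (N is trimmed too), and the
   block is shrunk from the left until its own GC respects the ceiling —
   merging can otherwise leave a block marginally above it.  Every emitted
   block thus satisfies `length >= min_block_len` (default 500) and
   `GC <= ceiling`, and blocks are disjoint and sorted.

Raising either delta never increases total block length (flags are monotone
in the ceiling and merging/trimming preserve containment); this monotonicity
is property-tested.

## Centromere prediction

The centromere model for RIP-shaped genomes: per chromosome, the longest
AT-rich block and the longest interval free of annotated genes (chromosome
ends count as gap boundaries; ties break leftmost and are flagged).
Concordance requires >= 1 bp of overlap — no published overlap rule exists,
so the weakest criterion is used and the call reports block, gap and their
intersection rather than electing one.  Discordant chromosomes and
chromosomes without blocks are surfaced, never silently dropped.  "ORF-free"
is operationalized against the annotation; unannotated open reading frames
are out of scope.

## CAZyme cluster calling

The qualification rule: >= 3 CAZyme genes, or >= 2 CAZymes with >= 1
signature gene (transporter or transcription factor), members within <= 2
"intergenic distances".  The distance is interpreted as the count of
intervening genes between consecutive member genes, on either strand — a
gene-adjacency metric that is scale-free across genomes of different gene
densities.  This interpretation is the main interpretive commitment of the
module and is pinned by an exhaustive-window oracle test.

Chains of member genes are split wherever the intervening-gene bound is
exceeded, so emitted clusters are maximal: the nearest flanking member gene
always violates the bound.  Terminal signature genes are kept only when
anchored — between the cluster's first and last CAZyme, or within the bound
of a CAZyme directly; a signature gene that chains only through other
signature genes is dropped.  Cluster names are positional
(`<prefix> <chromosome index>.<rank>`, ranks by start coordinate); the same
engine emits SM-BGC-style names under a different prefix, but
secondary-metabolite cluster *detection* is delegated to external tools.

Cross-genome sharing uses an explicit artifact policy (no published
criterion exists): two clusters are shared when at least half of the smaller
cluster's members have orthologs among the other's members; the `shared`
count is over set-A clusters with at least one partner.

## Secretome filtering

Effector candidates are rows with signal peptide, zero transmembrane
segments, no GPI anchor and protein length strictly below 300 aa.  The
bound is exclusive and boundary-tested (299 kept, 300 excluded).  SP/TM/GPI
verdicts are consumed as columns produced upstream, which keeps the filter
testable without the predictors themselves.  The filter is monotone:
relaxing any single rule can only grow the candidate set.

## Synteny blocks, breakpoints, and the permutation test

Chaining works on per-chromosome gene ranks, not base coordinates: a block
is a chain of ortholog pairs strictly monotone in both genomes (increasing,
or decreasing for inverted blocks) with consecutive rank gaps of at most
`max_gene_gap` (default 5, allowing skips over unpaired genes); chains
shorter than `min_block_genes` (default 3) are discarded.  Blocks are
extracted *longest chain first* (ties resolved to the lexicographically
smallest chain), so a long collinear backbone absorbs its pairs before any
short interleaved chain can fragment it; the procedure is pinned against a
brute-force enumeration oracle on permutations of up to 15 genes.  Note that
with a permissive gap the longest chain may legitimately step across a short
inversion (ranks 1,2,3,7,8,9,10 is a valid chain when the gap allows a jump
of 4); adjacent-rank chaining (`max_gene_gap=1`) recovers the intuitive
three-block reading of a small internal inversion.

A breakpoint is the interval between the last gene of one block and the
first gene of the next on a chromosome, per genome; chromosome ends are not
breakpoints.  Abutting or interleaving blocks give zero-length breakpoints,
which the association test widens by `widen_zero_length` (default 1 kb)
per side — breakpoints mark neighbourhoods, not bases.

The association test asks whether breakpoints co-locate with AT-rich blocks.
The observed statistic is the fraction of breakpoints overlapping any block
(>= 1 bp).  The null preserves per-chromosome breakpoint counts and interval
lengths and redraws starts uniformly, controlling chromosome-level
composition; `p = (1 + #{null >= observed}) / (1 + n_perm)` with a fixed
seed.  Because the observed fraction is discrete, ties inflate single
p-values slightly (by half the modal tie mass); the calibration test uses 60
breakpoints, where the bias is within ±0.06, and checks that null-generated
breakpoints give p-values with mean within 0.15 of 0.5 and full spread.

## Telomere and NUMT detection

Telomere detection counts perfect tandem copies of the repeat unit
(`TTAGGG` at 3′, its reverse complement at 5′) inside a terminal window
(default 500 bp, clipped on short sequences); a call requires
`min_copies` (default 3).  Detection is strand-symmetric: reverse
complementing a chromosome swaps its 5′/3′ calls.

NUMT search is exact seed-and-extend: 15-mer seeds against both mitogenome
strands, extended to maximal exact matches, with collinear matches merged
across gaps of at most `merge_gap` (default 50 bp, diagonal drift bounded by
the same amount) so an "almost identical" insertion with scattered point
mutations reports as one hit with percent identity = matched bases / span.
Defaults `min_len=100`, `min_identity=90` target the 139–170 bp,
near-identical regime without excluding diverged insertions.  The circular
mitogenome is doubled for matching and coordinates canonicalized modulo its
length (`mito_end` may exceed the length when a hit wraps the origin).
Hits are classified `within` / `adjacent` / `distant` relative to AT-rich
blocks with a configurable flank (default 500 bp).

## The synthetic genome generator

The generator emulates the architecture the analyses target, not sequence
evolution.  Each chromosome of exact configured length is laid out as
`[5' telomere | zone A | centromeric desert | zone B | 3' telomere]`:

- **Background** at `background_gc` (default 55 %, a typical gene-space GC
  for these fungi); genes are intervals on background sequence, so the mean
  gene GC tracks the background and the dual thresholds give a ceiling near
  43 %.
- **Relics**: copies of one master transposon (45 % GC, 2 kb), each passed
  through `n_rip_rounds` (default 3) of RIP at `rip_rate` (default 0.8).
  One round only converts sites already in CpA/TpG context and leaves
  CpA-poor stretches GC-rich; successive rounds open fresh contexts, so
  relics are AT-rich end to end (realized GC ≈ 33 %, safely below the
  ceiling) — the model reading of relics shaped by repeated sexual cycles.
  Only these duplicated copies are RIP-eligible; background is never
  mutated.  A `rip_context_free` flag converts any C/G for sensitivity
  analyses.
- **Centromere**: a tandem array of the master truncated to
  `centromere_block_length` (6 kb) and RIP-mutated, centred in a gene-free
  desert of `centromere_block_length + 2 * desert_pad` (20 kb).  Spacers
  between laid-out units are near-uniform (0.5–1.5× the mean, minimum
  200 bp) and at most one relic sits between consecutive genes, so every
  ordinary intergenic gap stays far below the desert length and the planted
  desert/centromere are the unique argmaxes their callers look for.
- **Clusters** are planted as role assignments over consecutive gene
  indices per `ClusterSpec` (CAZymes anchor both ends); scattered background
  CAZymes/signature genes keep >= 4 plain genes from any other member, so
  they cannot chain under the intergenic bound of 2 and recovery is exact.
- **NUMTs** copy configured mitogenome intervals (defaults 139/166/170 bp,
  the published length regime) into the middle of target relics; the flanks
  are forced to mismatch the mitogenome continuation so the planted interval
  is exactly the maximal match.
- **Rearranged pairs**: genome B is derived from A by a script of segment
  inversions and reciprocal tail translocations whose cuts must avoid genes
  and previously touched regions; the default script cuts at relic midpoints
  near the chromosome quarter points, so every breakpoint is flanked by
  detectable blocks.  The ortholog map is the identity and truth breakpoints
  are the cut positions.

A single generator seeded once drives all randomness in a fixed construction
order (mitogenome, master transposon, then chromosome by chromosome), so
identical seeds give byte-identical outputs.  `rip_mutate` consumes one
uniform draw per eligible site regardless of rate, making runs at different
rates from identically seeded generators monotonically coupled — the basis
of the GC-monotonicity test.

What the generator does **not** emulate — hence what a green recovery test
does not establish: realistic transposon families or nested/truncated
insertions, GC heterogeneity between genes and intergenic sequence,
RIP-index dinucleotide skews beyond the CpA/TpG preference, assembly gaps
(N runs), segmental duplications, or phylogenetically realistic divergence
between genome pairs.  Recovery on simulated data validates the calling
logic and coordinate handling, not robustness to annotation noise or
assembly artefacts.

## Numerical and degenerate-input choices

- GC comparisons use plain float arithmetic (`100 * gc / non_n <= ceiling`);
  the oracle tests perform the same arithmetic, so agreement is exact.
- Length-spectrum bins are right-closed `(lo, hi]`, with a length equal to
  the lowest edge assigned to the first bin.
- Longest-block and longest-gap ties break leftmost and (for gaps) are
  flagged.
- A chromosome fully covered by genes has no ORF-free region and raises; a
  chromosome with no genes returns itself, flagged.
- Zero-length breakpoints are legal values (`start == end`) and widened only
  inside the association test.
- `atrich_summary` accepts a `Genome` or a plain genome length, so published
  table rows can be checked without constructing 35-Mb sequences.

## Known limitations

- The segmentation's 500-bp window and 100-bp edge/merge parameters are
  conventions, not fits; block boundaries carry ~±50 bp of uncertainty
  around sharp GC steps, and very weak blocks (GC just under the ceiling)
  gain or lose bases with composition noise at the ends.
- Cluster calling trusts the feature table; mis-annotated CAZymes shift
  cluster boundaries with no internal error signal.
- The greedy longest-chain-first synteny decomposition is not a global
  optimum over all decompositions; it is, however, deterministic and matches
  the exhaustive single-chain extraction oracle by construction.
- NUMT identity is computed over the merged nuclear span assuming
  substitutions dominate; long indels inside an insertion lower identity
  and may split hits.
- The permutation null places intervals independently and uniformly; it does
  not condition on gene density or recombination landscape.
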