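# Methods

## The assembly model

`sunkasm` targets regions where overlap-based assembly fails: tandem
arrays of higher-order repeats (HORs) whose units are more similar to
each other than the read error rate can distinguish. The method trades
sequence overlap for *positional barcodes*: singly unique nucleotide
k-mers (SUNKs), k-mers occurring approximately once per haploid genome.
Even inside an array whose units are 98–99.9% identical, each unit
carries private variants, and the k-mers spanning them are genome-unique.
A noisy ultra-long read then reduces to an ordered list of SUNK anchors,
and two reads overlap if and only if their anchor lists agree — not just
in membership but in the *pairwise distances* between anchors.

### SUNK selection

Candidate SUNKs are k-mers (default k = 20, canonicalized as the
lexicographic minimum of a k-mer and its reverse complement) whose count
in an accurate-long-read table falls within `coverage_band` (default
[0.5, 1.5]) times the single-copy coverage peak. The peak is located as
the median of counts ≥ 2 (the count-1 bin is error-dominated at real
coverage), refined to the mean of counts within ±50% of that median.
A raw histogram argmax was rejected: counts of neighbouring k-mers are
strongly correlated through shared read coverage, which makes per-count
bins lumpy enough that the argmax lands several counts off-peak and
shifts the selection band; the median is robust to multi-copy
contamination and the refinement removes its half-count discretization
bias, which the band edges amplify. Candidates are validated by
requiring `validation_min_count` (default 1) occurrences in an
independent short-read k-mer table.

At exactly 30× coverage the band excludes a Poisson-tail fraction of
true single-copy k-mers of ~0.5–0.6% in expectation; on a 50-kb genome a
single draw measures this loss with roughly ±1% noise because tail
k-mers arrive in read-length-sized chunks wherever coverage excursions
cross a band edge. The selection-quality tests therefore assess the mean
loss over fifteen independent replicates.

### Pair validation and the two ambiguity guards

Shared SUNKs between two reads are split by strand agreement into a
same-orientation and a flipped-orientation hypothesis. Under each, the
offset delta of every shared SUNK (position on read A minus oriented
position on read B) is computed; a SUNK is *valid* if ≥
`min_support_partners` (default 10) other shared SUNKs lie within
`distance_tolerance_fraction` (default 1%) of the shorter read's length
of its delta, and a pair is accepted with ≥ `min_valid_sunks` (default
3) valid SUNKs among ≥ `min_shared_sunks` (default 50) shared ones. The
pair offset is the median delta over the dominant cluster.

Two rejection rules extend the thresholds, both measured necessities on
the synthetic arrays rather than theoretical flourishes:

* **Dual-orientation ambiguity** — if both orientations reach the valid
  minimum, the pair is unresolvable and rejected.
* **Multimodal offset support** — if the second-best delta cluster
  (further than 3× the tolerance from the dominant centre) holds at
  least half as many SUNKs as the dominant cluster, the orientation is
  rejected. Near-identical tandem units plus read error routinely
  recreate SUNKs from homologous blocks elsewhere in the array, and
  because units are regularly spaced these spurious anchors form delta
  clusters at multiples of the unit length that satisfy the raw
  thresholds. Genuine overlaps concentrate essentially all agreement in
  one cluster (observed: dominant 1,100–4,600 vs second ≤ 37), spurious
  pairs do not (11–56 vs 9–26), so the ½ ratio separates them with a
  wide margin.

### Tiling, eviction and stitching

Accepted pairs define a graph; components are laid out along a
maximum-support spanning tree (support = valid-SUNK count), propagating
orientation and offset from anchor medians. Pairs whose reads end up
placed inconsistently (residual beyond the tolerance) are first dropped
as spurious *edges* when their support is under half the best support at
either endpoint; only violations that survive this filter — the
signature of a genuinely misplaced, e.g. chimeric, read — evict the
worst-offending read before the layout is rebuilt. (Evicting reads
directly proved destructive: spurious low-support edges concentrate on
reads in the homogeneous array centre, and evicting them collapsed the
centre by entire units.)

The tile sequence takes, at each coordinate, the overlapping read with
the most valid SUNKs (ties to the longer read); switches between backbone
reads are cut at a SUNK anchor both reads carry near the junction, so the
junction is exact over the anchor k-mer. Anchor-based cuts require tile-
coordinate agreement within per-read indel drift (max(300 bp, 1% of read
length)) and proximity to the junction; otherwise offset arithmetic is
used, whose error is bounded by the same drift.

Scaffold extension repeats barcoding on the current consensus, validates
pool reads against it, merges the best end-extending read per side
(stitched at a shared anchor), and stops when both unique flank anchors
are contained (edlib infix search, ≤ 20% divergence) or after two
profitless rounds.

### Contig patching

Each high-accuracy contig is barcoded and anchored to the scaffold by
the longest chain of shared SUNKs strictly increasing in both coordinate
systems (patience LIS), evaluated in both orientations. The chain is then
trimmed to its longest run whose consecutive steps agree between contig
and scaffold coordinates (tolerance max(300 bp, 10% of the step)):
without this, a handful of spurious far-away anchors can stretch a chain
far beyond the contig's true span. Overlapping scaffold claims are
resolved in favour of the chain with more anchors (ties: longer contig),
the loser truncated at its nearest surviving anchors. Scaffold bases
under each placement are replaced by contig bases; provenance intervals
partition the output exactly, so `bp_from_contigs + bp_from_scaffold`
always equals the assembly length.

## Analysis modules

**Identity heat map.** Sequences are cut into consecutive windows
(default 5 kb; a final fragment under half a window merges leftward).
Every unordered pair is aligned globally in both orientations with edlib
(unit-cost edit distance) and scored as 100 × matches / (matches +
mismatches + insertions + deletions) from the extended CIGAR; the better
orientation is kept, and pairs under a 70% floor are reported unaligned
(standing in for mapper seeding failure on divergent pairs). Aligned
records are sorted and split into 10 equal-count bins, remainder to the
lowest-identity bins. An affine-gap aligner was considered and rejected:
the module's contract is the rank structure of identities (which layer a
pair falls in), which unit-cost per-base counting preserves, and edlib is
orders of magnitude faster than a hand-rolled affine DP at 5-kb scale.

**Restriction digestion.** IUPAC sites are expanded to regexes; cut
positions are the starts of forward-strand matches plus forward-strand
start positions of reverse-strand matches (palindromes counted once),
and fragments between consecutive cuts always sum to the sequence
length.

**Monomer decomposition.** A joint dynamic program (numba-compiled)
segments the array into consecutive blocks, each assigned the reference
monomer (both strands) minimizing unit-cost edit distance, minimizing
total cost over the whole sequence with free block boundaries; bases are
skippable at cost 1. Block-start indices propagate through the DP
columns alongside costs, so the segmentation is recovered without
storing the full matrices. Per-block identity is recomputed with edlib;
blocks under 60% identity become "gap" annotations. This is a
decomposition in the spirit of consensus-monomer string decomposers;
bit-identical output to any external tool is not a contract. The 11
monomers (A–K) of the human chromosome 8 D8Z2 11-monomer HOR unit ship
as package data.

**HOR units and entropy.** Units start at each occurrence of a start
monomer (default A) and end before the next; gap annotations break the
array into independent runs. A unit not beginning with the start monomer
is partial, as is a final unit whose monomer string is a strict prefix
of another complete unit (edge truncation). Admixture entropy is
−Σ fᵢ·log₂ fᵢ over HOR-type frequencies (typed by monomer count by
default, full monomer string optionally) in sliding windows of 10
complete units, slide 1; only full windows are evaluated and track
positions are window midpoints in bp.

**Quality values.** QV = −10·log₁₀(1 − (1 − E/T)^(1/k)) converts the
fraction of assembly k-mers unsupported by a read set into a per-base
Phred score (base-10 logarithm; the alternative reading of "log" is
inconsistent with the estimator's reference value 63.19);
QV = −10·log₁₀(1 − matches/(matches+mismatches+ins+del)) does the same
for =/X-resolved alignments, with plain 'M' CIGARs rejected. Error-free
inputs return an unbounded marker reported as infinity and 100%
accuracy. Printed comparisons round half-even at presentation precision;
internal math is double precision.

**ChIP k-mer placement.** Read k-mers (k = 50, canonical, string-keyed —
50-mers exceed 2-bit int64 packing) are each placed once, uniformly at
random per occurrence, among all perfect-match sites on either strand of
the target; zero-site k-mers count unplaced, and placed + unplaced
always equals the occurrence total. Coverage is reported in fixed bins
(default 1 kb). The mappability simulation samples random fragments
(default 150 bp) from given regions and counts exact-match sites in the
whole target.

**Divergence and mutation rate.** TN93 distance is computed from pooled
base frequencies, the two transition proportions and the transversion
proportion, with gap/ambiguity columns excluded pairwise and saturation
(non-positive log argument) reported as undefined; windows need ≥ 5 kb
of aligned bases (10-kb grid default). No gamma rate variation is
modelled. The observed divergence D of a human–primate pair mixes
between-species substitutions and ancestral polymorphism,
D = 2μt + 4Nₑμ, so μ = D/(2t + 4Nₑ) with t = divergence years /
generation years. Generation time is drawn uniformly from [20, 29] yr
and divergence years from per-pair ranges (human–chimpanzee [4, 6] Myr,
human–orangutan [12, 14] Myr, human–macaque [23, 25] Myr), Nₑ = 10,000,
10,000 draws by default; min/mean/max are reported so both "minimal
rate" readings (minimum draw vs mean) are available, and the fold change
compares the mean to a basal rate of 2.2 × 10⁻⁸ per bp per generation.

## The synthetic generator

`simulate` produces the study system directly rather than through an
evolutionary mechanism: the layer plan *imposes* the layered outcome
(no unequal crossing-over is simulated). Defaults, fixed once as the
reference conditions:

* Monomers: 11 synthetic 171-bp monomers at 20% mean pairwise
  divergence, generated by substituting a common random ancestor at a
  rate solving 2p − (4/3)p² = 0.2.
* Array: five mirrored layers (each non-innermost layer once per side),
  per-side unit counts 7/8/9/12 and a 24-unit innermost layer;
  substitution rates 0.12/0.08/0.04/0.02/0.001 outermost → innermost;
  cassettes of 11, 7 and 8 monomers (derivatives of the 11-mer), with
  the fourth layer admixed across all three and the centre homogeneous
  7-mers; 25-kb uniform-random flanks; array ≈ 154 kb, genome ≈ 204 kb.
  The rates reproduce the qualitative pattern — within-layer identity
  rising monotonically toward the centre — the layer structure is
  defined by; per-layer divergence is otherwise unconstrained.
* Reads: per-base i.i.d. errors at 1 − accuracy with a fixed
  substitution/insertion/deletion mix (60/20/20 ont-like at 95%
  accuracy, the mid-upper part of the 87–98% range ultra-long nanopore
  data occupies; 90/5/5 hifi-like at 99.9%; substitution-only
  illumina-like at 99.9%). Read intervals may overhang the genome ends
  and are truncated (dropping fragments under min(150 bp, profile
  minimum)), keeping coverage uniform to the boundary as when the
  simulated region is embedded in a larger genome. Consensus contigs are
  modelled error-free, their stated accuracy floor (> 99.99%) being
  indistinguishable from perfect at desk scale.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: basecaller-specific, homopolymer-
biased and locally bursty error; heterozygosity and somatic variation;
HOR unit-length variants arising by internal duplication/deletion rather
than substitution; interspersed transposable elements inside the array;
read-length and coverage biases. The spurious-anchor phenomenon that
motivated the ambiguity guards, however, is a genuine property of
near-identical repeats plus error and arises in the simulation for the
same reason it arises in real arrays.

All randomness flows from one global seed, fanned out per module by
stable name hashing (`RunConfig.module_seed`), so any stage reruns
reproducibly in isolation; identical config + seed gives byte-identical
bundles.

## Numerical and scale choices

Coordinates are 0-based half-open everywhere; 1-based presentation is a
formatting concern with tested converters. Packed k-mer counting limits
k ≤ 31 (2 bits/base in int64); the ChIP module's k = 50 uses string
keys. The reference pipeline runs a ~204-kb genome with 30× hifi-like,
20× ont-like and 30× illumina-like coverage and six contigs at 99%
coverage — sizes chosen so the full workflow, including all tests,
completes in about a minute while every layer still spans multiple read
lengths. Alignment-based error measurement is treated as a lower bound
on injected events (optimal alignments compress ~2% of i.i.d. events);
generator calibration is asserted exactly on event counts and with a 3%
one-sided allowance on alignment measurements.

Known limitations: tile consensus is a stitch of read segments, not a
polished consensus, so unpatched intervals retain raw read error;
contig placement requires SUNK anchor chains and will skip a contig
confined to a SUNK-free region; the offset-cluster guards assume the
spurious lattice spacing exceeds 3× the distance tolerance (unit lengths
≥ ~1 kb at default tolerances); and the HOR-unit partial-flag heuristic
for edge truncation relies on seeing the complete unit elsewhere in the
array.
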