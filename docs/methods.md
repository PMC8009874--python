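# Methods

## Coordinate and interval conventions

All internal coordinates are 0-based half-open.  GFF3/GTF input (1-based
inclusive) is converted at parse time, BED output is natively 0-based
half-open, and VCF positions (1-based) are converted where intervals are
intersected.  Target consolidation merges overlapping *and* book-ended
features — a non-overlapping set admits either adjacency rule, and
merging yields the canonical minimal set.  Strand is carried on features
but ignored by consolidation: capture hybridization is strand-symmetric,
so probes are designed against the forward strand with both strands
handled inside the k-mer and uniqueness logic.

`adjust_regions(rs, pad)` serves three documented uses: pad = +30 for
probe-selection flanks expressed as intervals, pad = −2 for the variant
target restriction, and pad = +100 to mirror exon-plus-flank processing
windows.  Whether the ±30 bp selection flank and a ±30 bp browsing pad
are "the same" mechanism is left to configuration; both are this one
operation.

## Probe design

### Repetitiveness

A genome-wide 15-mer histogram is built once; k-mers containing N are
skipped.  K-mers are counted in canonical form (lexicographic minimum of
forward and reverse complement) because a probe hybridizes either
strand; forward-only counting is a constructor flag.  A probe's
repetitiveness is the mean histogram count over its L − k + 1 sliding
15-base windows, which is identical to per-k-mer counting when the
window equals k (the interpretation adopted here).  Candidates with mean
count > 100 are flagged repetitive and removed *before* uniqueness
scoring, mirroring the published order of operations.

### Close-match uniqueness

A close match is a genome locus, on either strand, where some 30-base
window of the probe aligns with edit distance ≤ 5.  The search is
seed-and-verify: each 30-mer window is split into six non-overlapping
5-base seeds; by pigeonhole, any alignment with ≤ 5 edits contains at
least one exact seed, so seeded search provably finds every hit a full
scan would.  Candidate regions around seed hits are pre-screened with
edlib (infix mode, k = 5) and then verified by an exact semi-global DP
that enumerates all qualifying alignment end positions.  Ends map to
intervals [e − 30, e); intervals overlapping on the same strand merge
into one locus, preventing a single diverged copy from being counted
once per window.  The probe's own origin locus is included in the count
and consumes one of the five allowed placements
(`count_origin_locus=False` raises the cap by one instead).  Candidates
with more than `max_close_matches` (5) loci are ineligible regardless of
score.  Window-level hit sets are memoized, since candidates tiled 5 bp
apart share almost all windows.  The test suite holds the implementation
to *exact* agreement with an independent full-scan DP oracle on
randomized probes.

### Scoring and selection

The published procedure names repetitiveness, uniqueness, melting
temperature and sequence composition as scoring inputs but no formulas,
so these are package choices:

* **Tm** — nearest-neighbor thermodynamics with the unified parameter
  set (via Biopython's `Tm_NN`), 50 mM monovalent salt, 250 pM strand
  concentration, entropic salt correction.  Defaults put random
  50–100-mers at ≈ 67–75 °C, hence `tm_target` = 72 °C.
* **Composition penalty** — `w_gc·|GC − 0.5| + w_homo·max(0,
  longest_homopolymer − 5)` with w_gc = 1.0, w_homo = 0.1; zero for a
  balanced probe, strand-symmetric by construction.
* **Combined score** — weighted sum `(w_rep, w_uni, w_tm, w_comp) =
  (1, 1, 0.2, 1)` over `log10(1 + repetitiveness)`, close matches in
  excess of the self-hit, |Tm − target| and the composition penalty.
  The Tm weight is lower because degrees Celsius span a numerically
  larger range than the other terms.  Lower is better; ties break
  leftmost start, then shortest length, for determinism.

Candidates are tiled from `target.start − 30` at a 5-base step; lengths
enumerate 50, 60, …, 100 by default (`probe_len_step` = 10; full 50–100
enumeration available), trading candidate-set density for speed at small
scale.  Selection windows of 20 bases advance 40 bases from
`target.start − 30` until past `target.end + 30`; each window compares
up to `probes_per_window` (4) lowest-scoring eligible candidates whose
*start* lies in the window and keeps the single best.  Selected probes
can therefore never violate the ±30 flank bounds, and duplicate
selections collapse.

### Coverage

The report partitions target bases into direct (under a probe), indirect
(within `indirect_reach` of a probe terminus but not under one) and
uncovered; the three always sum to the target size.  "Indirect" coverage
has no published definition; the default reach of 100 bp reflects that a
sequenced fragment extends beyond its capture probe by roughly an insert
length minus probe length, and is configurable.  When `indirect_reach ≥
window_advance`, any target that received at least one probe has no
uncovered bases between selected windows.

## Paired-platform comparison

Classification precedes filtering (matching the published workflow,
where common variants are identified prior to filtering); because filter
statistics are platform-specific, post-filter common counts can differ
between platforms.  Matching is exact string equality on (chrom, pos,
ref, alt) after upper-casing; no indel left-alignment is performed —
input is assumed normalized by the caller.  A record fails hard
filtering when *any* type-appropriate rule matches; a missing statistic
makes its rule inapplicable (standard hard-filter practice), and
per-rule failure counts are returned for auditing.  Multi-allelic and
non-SNV/indel records are retained through classification but excluded
from consequence tables, Ti/Tv and spectra.  The ±2 bp target
restriction is implemented by shrinking each target 2 bases per side and
keeping strictly interior variants; the opposite reading (keep target
± 2) is the sign flip `flank_trim = -2`.

Consequence tables roll up (impact, consequence) categories per platform
with common/exclusive counts and percentages rounded to one decimal;
empty categories are omitted and unannotated variants (impact
"modifier") are excluded.  Ti/Tv counts transitions {A↔G, C↔T} over
biallelic SNVs and reports an undefined ratio (None) when no
transversions exist rather than infinity.

## Bias analysis

Per-gene counts are over *classified* sites — a shared site contributes
one count to each platform — so platform differences isolate exclusive
calls rather than filtering noise; callers may filter first if they want
post-filter bias.  Per-individual counts use carrier counting (≥ 1
alternate allele), the natural reading of "mean variants per
individual"; allele-dose counting is a flag.  Platform bias per gene is
count_b − count_a (positive = platform-b excess), expected count is the
two-platform mean, and SNVs/kb uses distinct sites across both platforms
over the gene's consolidated CDS length.  Outliers are the N largest
positive differences (difference, not ratio, since the comparison is of
per-gene count differences), ties broken by gene id.  Sex fold change is
log2((mean_m + 1)/(mean_f + 1)), the +1 preventing division by zero;
sex-difference summaries report means per sex, |difference| and the
percentage of the *male* mean, rounded to 2 decimals.  Chromosome
classes are "X" for the one configured X-name chromosome and "autosome"
otherwise.  Per-individual counts are taken after target restriction;
the restriction step is separable if the opposite convention is wanted.

## Synthetic fixtures

The generator emulates the features the analyses measure:

* a tandem repeat family (unit 60 bp × 150 copies) that defeats the
  15-mer repetitiveness filter;
* a paralog cluster (3 near-identical gene copies at 2 % per-base
  divergence) that inflates close-match counts;
* paired call sets with shared fraction 0.985 and transition
  probabilities 0.797 (shared) / 0.603 (exclusive), so Ti/Tv of the two
  classes sits near 3.92 and 1.52 respectively;
* platform-exclusive sites as singleton hets (allele-count-1 error
  spike) at per-kb rates 1.0 (platform a) and 2.6 (platform b),
  preserving the ~1 : 2.6 exclusive-count asymmetry between exome and
  genome platforms — the absolute rates are scaled far above realistic
  per-kb values, a deliberate one-time choice so a ~7 kb toy target set
  yields measurable exclusive counts;
* male-only platform-b exclusive sites concentrated in 4 designated
  X-chromosome genes, het in 4 male samples (allele-count peak at 4,
  equal to the number of males), emulating degraded-Y gametolog reads
  mis-mapping to X when the reference lacks a Y;
* per-rule hard-filter failures injected independently at 5 % with
  statistic values drawn from disjoint pass/fail ranges.

Site classes are i.i.d. (common with probability f; the exclusive
remainder split by platform rates) and positions are drawn without
replacement, so the truth table and `classify_shared` agree exactly.
The total site count is the exclusive-rate mass divided by (1 − f); at
f = 1 the rate sum is reinterpreted as total density so the boundary
stays defined.  One `SeedSequence` per component (genome, placement,
genotypes, stats, annotation) makes every output byte-deterministic per
seed while changing one field perturbs only its own stream.

What the generator does **not** model: linkage and realistic allele
frequency spectra (shared-site AFs are uniform 0.05–0.5 with binomial
genotypes), read-level effects (mapping quality is drawn, not computed),
indel normalization issues, correlated filter statistics between
platforms at shared sites, and capture efficiency.  Passing tests
demonstrate the *algorithms* recover what was planted under these
simplified conditions, not that real data has these properties.

## Problem sizes and numerical notes

Test and acceptance runs use 3 × 18 kb chromosomes, 18 four-exon genes
(~8.6 kb of targets, ~1.6 k variant sites) and ≤ 10 kb genomes with 200
randomized probes for the oracle-equivalence checks; a 6 kb-chromosome
variant of the fixture backs the design determinism and coverage
summaries.  Statistical recovery checks use 3-binomial-standard-error
bands around generating values.  Degenerate inputs are defined, not
exceptional: empty feature lists give empty designs, targets shorter
than the minimum probe with no flank give empty candidate lists with a
warning, zero transversions give an undefined (not infinite) Ti/Tv, and
a sex class with no members yields missing fold changes.
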