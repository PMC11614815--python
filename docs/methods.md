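# Methods

## Scope and data model

The package analyses genome-aligned small-RNA reads. All coordinates are
0-based half-open (BED convention); the 5′ end of a plus-strand read is
`start`, of a minus-strand read `end − 1`. A read aligned to *k* loci
appears as *k* records sharing one id with `mapping_count = k` and
per-mapping weight 1/*k*; the upstream aligner cap of 50 mappings per
read is enforced on ingestion. The number of distinct mapped reads is
the RPM denominator. The aligner itself, adapter trimming and repeat
discovery are out of scope: the alignment table (a BED6+2 dialect
carrying mapping count and read sequence) is the entry point, and the
synthetic generator stands in for the upstream when no real data are at
hand.

## Classification and apportioned counting

Any overlap (≥ 1 shared base, strand-blind) with a miRNA, rRNA, snRNA,
simple-repeat or low-complexity annotation excludes a read from the
piRNA/siRNA pools — the exclusion lists act as contamination filters,
so strand is deliberately ignored there. When a read overlaps several
excluded classes the label follows a fixed precedence
(miRNA > rRNA > snRNA > simple repeat > low complexity); the non-miRNA
exclusions are reported under one `rRNA_like` bucket. Remaining
TE-overlapping reads of 24–32 nt are piRNAs and of 18–23 nt siRNA
candidates. Both windows are configurable: descriptions of this kind of
pipeline sometimes quote a narrower 24–30 nt piRNA window for specific
analyses, and `ClassRanges` lets either convention be applied; the
24–32 nt default follows the pipeline definition used for
classification.

Counting is apportioned twice: weight 1/*k* per mapping, split evenly
across the *m* features the mapping overlaps. Reads overlapping nothing
accumulate under `unassigned`. This conserves mass exactly — summed
over all groups the counts equal the number of distinct reads — which
every stage logs as a built-in check.

## Cluster calling

Windows of `window_size` (5 000 nt) slide in `step` (1 000 nt) along
each scaffold. Two separate criteria gate a window:

* **density** — the number of uniquely-mapping piRNA 5′ ends inside the
  window per kb must be **strictly greater** than `min_density` (5/kb);
* **coverage** — the fraction of window bases covered by full read
  intervals must be **at least** `min_cov_frac` (0.12).

Membership is by 5′ end (not any-overlap) so that density and coverage
remain genuinely distinct criteria: a stack of co-terminal reads can
pass density yet fail coverage. Windows are clipped at scaffold ends
and a terminal partial window uses its actual width in both criteria,
avoiding edge inflation. Overlapping retained windows are unioned and
unions separated by **strictly less** than `merge_gap` (20 000 nt) are
combined. The strict/inclusive choices mirror the wording of the
thresholds ("greater than", "at least", "less than") and are pinned by
dedicated boundary tests (density exactly 5/kb: rejected; coverage
exactly 12 %: retained; gap exactly 20 kb: not merged).

Clusters are ranked by apportioned read support (weight 1 each for
unique reads) with deterministic ties (scaffold, then start) and named
`cluster_1, cluster_2, …` from most productive down. Support, RPM,
plus-strand fraction and the strandness label are computed from the
reads whose 5′ ends fall inside the final interval. A cluster is
plus- or minus-biased when the corresponding strand fraction reaches
`strand_bias_threshold` (0.75) — the boundary counts as biased, since
"less than 75 %" defines unbiased. Cluster RPM uses apportioned support
by default; calling on unique reads makes this equal to an integer
count, and `unique_only=False` is available where multimappers should
participate.

Because retained windows extend as long as their 5′-end count clears
the density bar, called boundaries can pad a true read-dense region by
up to one window on each side; the planted-cluster tests bound the
error at ± `window_size`.

## Signature statistics

**Ping-pong.** For every opposite-strand pair on one scaffold the
5′–5′ overlap is k = (minus 5′) − (plus 5′) + 1, counted for
k ∈ [1, `max_overlap`] (default 30) when both reads cover the shared
register (k ≤ both lengths). Pairs contribute the product of their
mapping weights, which extends apportioning to pairs: duplicating every
mapping while halving weights leaves counts and z-scores unchanged.

**Phasing.** For same-strand reads, the 3′→5′ distance between an
upstream read and a downstream read is measured in transcription
direction with half-open ends, so immediate adjacency gives d = 0. All
pairs with d ∈ [0, `max_distance`] (default 50) are counted — an
all-pair histogram rather than nearest-neighbour chaining, which keeps
the statistic symmetric with the ping-pong computation and robust to
interleaved reads.

**z-scores.** No closed-form null is assumed: z(k) compares counts[k]
against the mean and sample standard deviation (ddof = 1) of the counts
at all other offsets (leave-one-out). A zero-variance background is
flagged `degenerate` and reported as z = 0 rather than ±∞. The focal
statistics are z(10) (ping-pong register) and Z₀ = z(0) (phasing).
The leave-one-out background makes z-scores scale-free, so library
depth affects power only through counting noise.

**Base composition.** Per-position A/C/G/U frequencies (T read as U)
over the distinct reads of length ≥ that position; multi-mapping reads
count once. The 1U and 10A fractions are `freq(U, 1)` and
`freq(A, 10)`.

`paired_fraction` calls a read paired when ≥ 1 opposite-strand read
5′-overlaps it by any k ∈ [1, max_overlap] — not only the exact 10-nt
register — matching the broader notion of "paired" used alongside the
share of pairs at exactly 10 nt.

## Sense/antisense quantification

Sense versus antisense is read strand versus feature strand at the
genomic locus; unstranded TE records are rejected by name. A mapping
overlapping several TE copies splits its weight among them, consistent
with classification, so the sense + antisense totals equal the
TE-assigned mass exactly. For per-position profiles along a family
consensus, genomic reads are first projected through each insertion's
orientation (a plus-strand read inside a minus-orientation copy is
antisense in consensus space) — the only self-consistent way to compare
genome-space and consensus-space quantifications.

## The synthetic generator

`simulate_genome` plants, on a random-base genome: TE fragments inside
each configured cluster (per-family plus-orientation mix, fragment
lengths 150–800 nt drawn from per-family consensus sequences),
full-length dispersed copies outside clusters (non-overlapping, the
substrate for multimapping), horizontally-transferred-transposon (HTT)
copies exactly where listed, and off-cluster miRNA/rRNA contamination
features. `simulate_library` then samples reads:

* lengths from a two-mode discretised Gaussian mixture (means 22 and
  28 nt, sd 1, weights 0.3/0.7 by default — an embryo-like profile
  where the piRNA mode dominates);
* cluster reads uniform within their cluster, on the cluster strand
  with probability `strand_fraction` (0.9 — uni-strand clusters with a
  small opposite-strand leak);
* dispersed-TE reads antisense to their copy with probability
  `antisense_fraction` (0.6 — antisense piRNAs predominate);
* a `pingpong_fraction` (0.3) of 28-nt-mode reads converted into
  sense/antisense pairs whose 5′–5′ overlap is exactly
  `pingpong_overlap` (10 nt; settable to ~20 nt to emulate the atypical
  overlap reported for some HTT families);
* a `phasing_fraction` (0.2) of reads re-laid as head-to-tail trails of
  3–6 reads (3′→5′ gap 0) on a cluster strand;
* multimappers realised by replicating a dispersed-TE read at 2–5 other
  copies of its family at the same consensus offset, with
  `mapping_count` set accordingly — mirroring how multimappers arise
  from dispersed TE copies;
* sub-threshold decoy regions at a configured read density, for
  specificity tests of the cluster caller.

Base biases are written into the genome before sequences are extracted,
so read sequence always equals the genome slice under its primary
mapping (reverse-complemented on the minus strand) and bias can be
measured from either source. Every read's first base is drawn with
P(U) = `u1_bias` (a first-base U bias on both orientations, as has been
described in some insects) and every sense-class read's tenth base with
P(A) = `a10_bias`; sense 10A is written first and antisense 1U last, so
where an exact 10-nt pair couples the two (the mate's first base *is*
the complement of the anchor's tenth base — the ping-pong register
itself) the primary antisense bias wins. Consequently the two biases
are only independently recoverable at `pingpong_fraction = 0`, which is
how the bias-recovery tests are configured. Duplicate mappings reuse
the primary-locus sequence: same-family copies share the consensus
subsequence, and the duplicate locus is not rewritten, so bases written
there for unrelated reads stay intact.

Overlapping reads share genome bases, so in very dense regions a later
bias write can overprint an earlier read's measured base; the truth
manifest therefore records the *realized* bias and pairing fractions
measured from the final sequences, and recovery tests use geometries
(large, sparse clusters) where the overprint rate is negligible.

What the generator does **not** emulate: sequencing error, adapter
artifacts, quality scores, TE sequence divergence/phylogeny, GC skew,
or genuine transcriptional background. Passing tests therefore show
that the analysis recovers the statistical structure it targets —
registers, biases, densities, strand ratios — not that it is robust to
alignment artifacts or annotation errors in real libraries.

## Pipeline and problem sizes

`run_pipeline` chains simulate (or load) → classify → quantify →
clusters → signatures → summary into a run directory of TSV/BED/JSON
files with no timestamps, so identical config + seed reproduces the
directory byte for byte; each stage logs its conservation check.
`compare_samples` joins per-run summaries (piRNA RPM, siRNA RPM, TE
RPKM, cluster RPM) for cross-stage readouts such as the piRNA-versus-TE
anticorrelation, with TE RPKM computed from a user-supplied RNA-seq
count block (TE-family counts and library size).

Test and acceptance workloads use 100 kb–1.5 Mb toy genomes and
1 500–10 000-read libraries: large enough that detection statistics sit
far from their thresholds (z ≈ 30–50 versus the z = 3 bar; binomial
noise on recovered fractions ≈ 0.01) and small enough that brute-force
oracles — the all-windows cluster enumeration and the O(n²) all-pairs
overlap scans — can verify the optimised paths exactly on every run.
Null calibrations use 100 seeded replicates each.

## Known limitations

* The caller does not model dual-strand or bidirectional clusters as a
  separate class; a merged region with mixed strand reads is simply
  labelled unbiased.
* Boundary precision is one window (± 5 kb at defaults) by
  construction; sub-window boundaries would need a change-point step.
* The leave-one-out z-score treats the non-focal offsets as exchangeable
  background; heavy multi-register signals (e.g. simultaneous 10-nt and
  20-nt registers) deflate each other's z.
* `mapping_count` is trusted as supplied (one row per mapping, same
  count on each row); no re-counting against the genome is attempted.
* SAM/BAM and FASTQ ingestion are out of scope; the BED-dialect table
  is the only alignment input.
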