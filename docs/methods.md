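# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic data does and does not emulate, and the
numerical and design choices made where the design was genuinely open.

## Backcross linkage model

An N2 backcross animal carries one recombinant F1 gamete, so every locus is
heterozygous (`H`) or homozygous for the recurrent parent (`B`) and the
marker–trait recombination fraction is directly countable.  For marker
counts (R recombinants of N informative animals, phase chosen to make
R ≤ N/2, missing genotypes excluded per marker):

* `r̂ = R/N`, and `LOD = (N−R)·log10(2(1−r̂)) + R·log10(2·max(r̂, 1/(2N)))`.
  The `1/(2N)` floor enters only the R-term, so perfect cosegregation gives
  exactly `N·log10 2` (30.1 at N = 100) instead of −∞.
* The trait is modeled as binary with symmetric mislabeling at rate
  1 − penetrance.  No interval mapping or multi-locus modeling is done; the
  peak is placed by converting the trait recombination fractions at the two
  markers flanking the best marker into genetic distances with Haldane's
  inverse, `d = −50·ln(1−2r)` (r capped at 0.499 to keep d finite), and
  scaling the flanking physical interval by `d_A/(d_A+d_B)`.  A maximum at
  either end of the map reports that marker's position.

Haldane's map function is used throughout (simulation and inversion): its
memoryless-crossover assumption matches the independent per-interval
recombination draws of the simulator, so simulated recombination fractions
are consistent with the distances inverted during peak placement.

Penetrance below 1 inflates every apparent recombination fraction by
roughly (1 − penetrance)·(1 − 2r), which flattens the distance ratio between
flanks; the peak therefore wanders within the flanking interval even at
n ≈ 1,100.  The recovery criterion used in the tests — peak within one
marker interval of the truth — reflects that precision limit, not an
implementation tolerance.

## Depth-ratio CNV model

Counts per fixed-width window (default 10 kb, last partial window dropped
so all windows are comparable) are compared between strain and reference:

`ratio_i = ((c_i + p)/L_s) / ((r_i + p)/L_r)`, pseudocount p = 0.5.

With a diploid reference the ratio has expectation CN/2.  Library sizes
default to the sum of window counts but can be supplied explicitly; the
simulator fixes them at the diploid expectation (mean_depth × n_windows),
emulating genome-wide normalization — if the library size were computed
from the profiled region alone, a strain's own CNVs would bias all its
ratios away from CN/2.  Note the mean of a ratio of noisy counts carries a
Jensen bias of order CN/depth (≈1–2% at 100× windows); the state bounds are
far wider than this.

Segmentation median-filters the ratio track (width 5 windows, odd), maps
each window to a state by the bounds 0.25/0.75/1.25/1.75 — the midpoints
between the CN/2 expectations 0, 0.5, 1, 1.5, 2 — merges same-state runs,
and reports non-diploid calls spanning ≥5 windows (suppressing single
window excursions).  On noise-free input the boundary error is at most
⌈width/2⌉ windows.  No GC or mappability correction, and no HMM/CBS-style
segmentation: block deletions and duplications at these spans do not need
them.

Strain distance is the **median** absolute error between ratio profiles —
median as spelled, not the acronym's usual "mean"; a `stat="mean"` /
`--mae-mean` alternative is provided because the naming is ambiguous in the
field.  A median distance is blind to differences covering under half the
windows, which has a design consequence for the simulator (below).
Clustering is scipy agglomerative (average linkage default; single and
complete available) with scipy's deterministic lowest-index tie-breaking;
flat groups come from a cut height or a requested group count (default 2,
the top split).

## Synthetic strain panel

The panel models ten strains over a 4 Mb region at 100× window depth: a
diploid reference plus one more diploid C57-lineage strain, two strains
carrying an 810 kb homozygous deletion (65.79–66.60 Mb), one with the
1.15 Mb extension (65.45–66.60 Mb), and five non-C57-lineage strains
sharing an alternate chromosomal conformation.  That conformation is
rendered as copy-number segments covering ~60% of the region (gains and
losses of 1–4 copies): an extensively divergent haplotype, consistent with
a different subspecies origin of the region.  The magnitude matters — with
a median distance, lineages only separate if their profiles differ over
more than half the windows, so the alternate conformation must be extensive
rather than a single block.  Within-lineage deletions (20% of windows)
stay below the median and do not break lineage grouping.

What the generator does not emulate: mappability and GC structure, reads
(only window counts), partial-window effects, and any small-scale CNV
polymorphism within lineages.  Passing tests show the ratio/segmentation/
clustering machinery recovers engineered architectures under Poisson or
negative-binomial noise; they say nothing about repeat-driven mapping
artifacts in real data, which dominate regions like ZFP clusters.

## Splice acceptors

Classification is the five-position consensus N[C/T]AG↓G: offsets −4..−1
are the last intronic bases (anything; pyrimidine; A; G) and offset 0 the
first exonic base (G).  Minus-strand sites are reverse-complemented before
scoring, giving exact strand symmetry.  `N` in input matches only the
degenerate slot — a masked base at a constrained position fails rather than
silently passing — and ambiguity codes other than N are rejected outright.
Contexts too short to supply four intronic and one exonic base raise.  An
alt site is "high" impact iff its reference passes and it fails; a failing
reference is flagged and yields no impact call.  No branch-point,
polypyrimidine-tract or splice-strength (MaxEnt-style) scoring: the rule is
deliberately the minimal consensus.

## Assembly segments and scaffolding

Segment filtering keeps query spans ≥1000 bp at identity ≥98%, both
inclusive.  Reference multiplicity counts segments overlapping each window;
duplicated regions are maximal runs with count ≥2.  Unique query regions
are the complement of the union of segment query intervals.  Vector
removal merges overlapping hits, excises them, and drops residual fragments
under 1 kb (uninformative for scaffolding).

Scaffolding joins clone ends greedily.  For each clone pair, all four
end-to-end combinations are tested (forward and reverse-complement) for a
suffix/prefix overlap; match counts for **all** candidate overlap lengths
are computed at once by FFT cross-correlation of one-hot encodings
(O(n log n) per pair), and the longest overlap meeting the length
(default 1000 bp) and identity (default 98%) thresholds is the candidate.
Identity is per-position agreement without indels — appropriate for clone
ends derived from the same molecule, not for diverged sequence.  Joins are
applied longest-first with clone-name tie-breaking; each clone end is used
at most once and cycle-closing joins are refused, so scaffolds are simple
chains whose count equals the number of connected components of the
overlap graph.  Merged length is the clone-length sum minus overlap sum.

## Expression

CPM uses explicit per-sample library sizes when available, else column
sums.  The simulator fixes library sizes at a shared constant because the
MLV loci are a small slice of a transcriptome: with column-sum
normalization the upregulated subclasses would inflate group-B libraries
and compress every recovered fold (observed: 14.5× → ~2.3×).

The differential test statistic is the group-mean difference of
log2(CPM+1) (the +1 keeps silenced, zero-count proviruses finite).  Group
labels are permuted: exhaustively when the number of distinct relabelings
is at most `n_permutations` (3 vs 3 gives 20 — always exhaustive), else by
`n_permutations` random draws with the add-one correction
p = (b+1)/(n+1).  q-values are Benjamini–Hochberg; a locus is regulated
when q < 0.01 and |log2FC| > 1.

A structural limitation worth stating plainly: at 3 vs 3 the exhaustive
permutation p cannot go below 2/20 = 0.1 (the identity relabeling and its
complement always attain |obs|), so the q < 0.01 rule can never fire at
that group size under this test.  The machinery is exercised at that size
for calibration (type-I error is trivially controlled) and fold summaries,
and its power is demonstrated at n = 10 per group, where the permutation
floor is ~10⁻⁵.  A parametric count model would be needed to call
regulation at n = 3; wrapping one is outside this package's scope.

Subclass summaries report the arithmetic mean of per-locus linear folds
(2^log2FC) over all loci of the subclass by default; `significant_only`
restricts to regulated loci and `geometric` switches the mean, since which
average a reported "average fold" denotes is genuinely ambiguous.  PBS
stratification compares per-locus log2FC between primer-binding-site groups
with Mann–Whitney (two groups) or Kruskal–Wallis (more), reporting "no
stratification" at p ≥ 0.05.  qRT-PCR normalization is 2^−(Ct_t − Ct_ref),
with target Ct at the 40-cycle cap reported as 0 with an "absent" flag.

## Coordinates and determinism

Internally everything is 0-based half-open; only parsers convert.
Megabase-printed ranges ("13:65.79–66.60 Mb") are scaled exactly at printed
precision (rounded, never truncated, so 65.79 → 65,790,000); bare-integer
ranges follow the 1-based inclusive browser dialect.  En and em dashes and
hyphens all separate bounds.  Every generator and every stochastic analysis
takes a seed and is byte-deterministic given it; the pipeline summary
carries a schema version, the package version and the seed.

## Problem sizes in the test suite

Recovery-rate properties run 100 replicates at the study scale (1,108
animals × 9 markers; ten 400-window profiles; 200-locus null matrices at
3 vs 3), which keeps each property test in the 1–10 second range.  The
fold-recovery check uses 60 loci × 50 samples per group, where the
Monte-Carlo standard error of the mean fold is small enough (≈3% of the
fold) for a meaningful 3-SE comparison.
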