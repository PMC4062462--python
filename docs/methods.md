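# Methods

## The procedure

`polyacomp` maps cleavage/polyadenylation sites from polyadenylated
transcript sequences onto a reference genome and compares the base
composition of the two regions flanking each site with the genome-wide
background:

1. **Screen.** A transcript qualifies as polyadenylated when it ends in
   at least `min_tail` (default 12) continuous A's. The tail is the
   *maximal* trailing A-run; the `anchor_len` bases immediately
   upstream of the run (100 for full mRNA, 80 for fragmented reads)
   form the anchor. Transcripts with fewer upstream bases, or with
   ambiguous letters in the anchor, are rejected and counted by
   category. Duplicate transcripts are collapsed on the anchor string,
   keeping the first occurrence.
2. **Map.** Each anchor is placed on the genome by exact string search
   — zero tolerance for mismatches — on both strands (the anchor and
   its reverse complement are searched on the deposited forward
   strand). The implementation is a C-speed `str.find` sweep whose
   contract is equality with the naive all-offsets scan; a quadratic
   oracle enforces this in the tests.
3. **Call.** For every placement the junction is the last templated
   base. Junction-relative position 0 is the genomic base under the
   first tail A; positions −`anchor_len`..−1 are the 3'UTR window
   (identical to the anchor) and +1..+100 the 3' cleaved-off region
   (3'COR), excluding position 0. Sites with an incomplete downstream
   window (fewer than 101 genomic bases past the junction) are dropped
   with a logged reason. On the minus strand every reported window is
   reverse-complemented into transcript orientation.
4. **Deduplicate.** One site is kept per distinct 100-base upstream
   sequence; the representative is the lexicographically smallest
   (chrom, junction, strand) locus, a deterministic choice for anchors
   hitting several loci.
5. **Flag.** A site whose genomic sequence from position 0 runs into an
   A-stretch of ≥ 12 is flagged as a potential internal-priming
   artifact (`ip_flag`). Flagged sites are never silently dropped;
   `exclude_ip_sites` removes them from profiling only.
6. **Profile and compare.** Per-position A/C/G/U counts over all
   unique sites; pooled window compositions (UTR, COR, the 50-base
   distal UTR slice at −100..−51, and the 6-base window 0..+5);
   region/genome ratios per base with U matched to genomic T; the
   U/A ratio of a window; and cross-species group statistics.

## Coordinate and window conventions

All internal coordinates are 0-based, half-open, forward-strand.
Position 0 belongs to neither the UTR nor the COR window by default,
making the 201-base region arithmetic exact (100 + 1 + 100); the
`cor_includes_site` switch shifts the COR to 0..+99 for the alternative
reading in which the COR starts at the site base. The 6-base A-content
window always includes position 0 and the five following bases.

Because the tail is trimmed maximally, a genome-templated A immediately
before the true cleavage point would shift the called junction upstream
past it. The synthetic generator therefore keeps the last UTR base
non-A; on real data, junction calls at A-ending UTRs land upstream of
the cleavage point by the length of the templated terminal A-run. This
is a deliberate trade: maximal trimming prevents templated A's from
being counted as tail, at the cost of a conservative junction.

## Whole-genome background

The background is the percentage of A, C, G or T over all unambiguous
nucleotides of all chromosomes/scaffolds of the deposited forward
strand; N and other IUPAC ambiguity letters are excluded from numerator
and denominator, and soft-masked lowercase letters are uppercased and
counted. `symmetrize_background` (off by default) averages A with T and
C with G for a strand-symmetric background.

## Group statistics

Group comparisons treat the species as the experimental unit: window
compositions are computed per species, ratios are computed per species
*and then* averaged — never as the ratio of group means (a regression
test pins the difference).

* **One-way ANOVA** by direct sums-of-squares decomposition, p from
  the F distribution.
* **Duncan's multiple range test** on ranked means. The least
  significant range for a stretch of p ordered means is
  `q(1−(1−α)^(p−1), p, df_error) · sqrt(MSE / n_h)`, with studentized-
  range quantiles from `scipy.stats.studentized_range` (pinned against
  published table values) and `n_h` the harmonic mean of the two
  compared group sizes — the Kramer extension, chosen for unequal
  group sizes; other software may resolve unequal n differently.
  Comparisons are protected stepwise (no range significant inside a
  wider non-significant one) and summarized as a shared-letter display.
* **ANOVA protection of the letter display.** In pipeline reports,
  Duncan letters are produced only when the overall F test is
  significant at α; otherwise all units share one letter. Without this
  gate the widest range is tested at level 1−(1−α)^(k−1) (≈ 0.14 for
  k = 4), which would break the near-α familywise behaviour the
  pipeline's null-calibration test asserts. `duncan_mrt` itself is
  unprotected and usable directly.
* **Student's t-test**, two-tailed, pooled equal-variance, df =
  n₁+n₂−2; zero pooled variance with equal means reports p = 1 with a
  degeneracy flag.
* **2×2 Pearson chi-square** without continuity correction (the
  spreadsheet-CHITEST convention), with expected counts from product
  marginals; used for A-count-vs-method contingencies built as
  (A, non-A) × method over pooled 6-base windows. The table
  construction is this package's documented choice.

Reporting precision is two decimals for percentages and ratios, rounded
half-up; full precision is kept internally and in machine-readable
output.

## The synthetic-data generator

`simulate.generate_dataset` emulates the data the method expects, with
ground truth:

* i.i.d. background genome from `background_probs` (default uniform);
  per-chromosome planting of `n_sites` stranded junctions at
  non-overlapping loci ≥ 250 bp apart, so analysis windows never
  collide — a simplification relative to real genomes.
* At each site the 100-base UTR window is drawn from `utr_probs`
  (default A/C/G/T = 0.25/0.15/0.20/0.40: the U-rich, C-poor,
  U ≫ A ≫ G > C structure of real 3' regions) and the 101-base
  downstream region from `cor_probs` (default 0.27/0.16/0.20/0.37,
  slightly less U-rich than the UTR). Transcripts append a poly(A)
  tail of uniform length in `tail_len_range` (default 12–30).
* Internal-priming artifacts (`frac_internal_priming`): a genomic
  A-run of length uniform in [12, 20] is planted at position 0 and the
  transcript ends inside it, so its apparent tail is genome-templated.
* `frac_duplicates` appends verbatim transcript copies so that
  duplicates are the stated fraction of the final pool.
* Fragmentation (`read_mode: fragmented`) emits each transcript's
  3'-terminal fragment (tail kept, so true sites stay detectable at
  anchor 80) plus one fragment ending inside every internal A-run
  ≥ `min_tail` of the templated body — the fragmentation-created false
  poly(A) tails that make read-based mapping internal-priming-prone.
  `body_len` adds templated mRNA body upstream of the UTR window so
  such runs can occur at realistic rates; an A-rich background
  (A = 0.4) produces them at ≈ 1·10⁻⁵ per base versus ≈ 1·10⁻⁸ for a
  balanced genome.

Everything is drawn from one `numpy` generator seeded by `seed`; equal
seeds give byte-identical outputs. The truth table self-validates
against the emitted genome on every generation.

**What passing on synthetic data does not show:** the generator has no
sequencing errors, no quality scores, no splicing, single sites per
locus, i.i.d. composition (no motifs, isochores or repeats), and
anchors planted unique. Real-data behaviour with repetitive genomes,
sequencing error or alternative polyadenylation is out of scope.

## Problem sizes and numerical choices

The test suite and analysis drivers use 40–200 planted sites on 20–100
kb genomes and a 12-species cohort (4 groups × 3 species, 150 sites
each) — sizes chosen so the binomial standard errors of recovered
compositions (≈ 0.3–0.5 percentage points at n_sites × 100 drawn bases)
are far smaller than the planted group differences (2–8 points), while
the whole analysis runs in seconds. Statistical calibration tests use
1000 null replicates (ANOVA type-I error, asserted within [0.035,
0.065]) and 100 replicates for the protected letter display (asserted
≥ 93% single-letter under the null).

Degenerate inputs are flagged, not guessed: empty genomes and empty
site lists raise; zero background percentages make ratios undefined
(`None`); zero pooled variance makes tests degenerate with p ∈ {0, 1};
ties in ranked means are broken by group id for determinism.

## Published worked examples

The package stores the published distal-window (50-base UTR slice at
−100..−51) base contents of 18 animal and plant species
(`reference_tables`). The four printed percentages of a species are
renormalized to sum to exactly 100 (they carry 2-decimal rounding
error) — a renormalization that leaves the U/A ratio unchanged. The
stored printed U/A column is used for the plants-vs-animals t-test;
recomputing ratios from the printed contents instead reproduces the
printed column for 17 of 18 species (one species' printed ratio derives
from unrounded contents and differs by 0.01).
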