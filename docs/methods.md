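# Methods

`quartetconv` detects gene conversion between duplicate genes created by a
shared whole-genome duplication (WGD), using homologous gene quartets built
from two related genomes.  This note records the models, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## The quartet model

Let genomes A and B descend from a common ancestor that underwent a
tetraploidy before the A/B speciation.  A retained duplicate pair (P1, P2)
in genome A then has orthologs (S1, S2) in genome B, with the true gene tree
((P1,S1),(P2,S2)) rooted at the WGD.  Because speciation postdates the WGD,
each ortholog pair is expected to be more similar than the paralog pair.
Gene conversion — the unidirectional overwrite of one duplicate (the
acceptor) by its partner (the donor) — breaks this expectation: the paralogs
become locally or globally more similar than each copy is to its own
ortholog, and in the whole-gene case the quartet topology flips to
((P1,P2),(S1,S2)).

## Distances: NG86 with Jukes–Cantor correction

Pairwise distances are Nei–Gojobori (1986) estimates from protein-guided
codon alignments (Needleman–Wunsch on translations, BLOSUM62, affine gap
open 10 / extend 0.5, back-translated so gaps occupy whole codons):

* site counts: each codon position contributes one site, split
  (synonymous changes)/3 versus the rest, averaged over the two sequences;
  changes producing stop codons count as nonsynonymous, so
  `n_sites + s_sites = 3 x (compared codon columns)` exactly;
* multi-difference codons: differences are averaged over all minimal
  mutational pathways, excluding pathways through stop codons;
* proportions are corrected with the Jukes–Cantor map
  `d = -(3/4) ln(1 - 4p/3)`; raw proportions at or above 0.745 are flagged
  saturated and the distance reported missing.

`Pn`/`Ps` in the output tables are these JC-corrected Ka/Ks values under
the alternative naming common in the gene-conversion literature; they are
numerically identical columns kept for traceability.

## Collinearity and event dating

Homolog pairs (an imported all-vs-all protein search result; e-value < 1e-5
and score > 100 filters are applied when those columns are present) are
first cleared of large families: connected components of the homology graph
with >= 50 members are removed.  Chains of pairs that are strictly monotone
in gene order on both chromosomes, with at most 50 intervening genes between
adjacent anchors on either genome, are extracted greedily by descending
anchor count (ties: lexicographically smallest anchor sequence); chains
shorter than 4 anchors are discarded.  This replaces a block-significance
test with the operational minimum-length criterion, which is the stated
cutoff in this analysis tradition.

Blocks are dated by the median NG86 Ks of their anchors.  The anchor-Ks
distribution is smoothed with a Gaussian kernel of absolute bandwidth 0.05
(512-point grid from 0 to max(Ks)+3h, reflected at zero so the density of
the non-negative support integrates to one; values >= 3 are excluded as
saturated).  The *curve* is then fitted by nonlinear least squares with an
increasing number of Gaussian components until R^2 >= 0.95, mirroring the
common density-curve-fitting practice for WGD dating; initialization is
multi-start from the largest curve maxima, and each k-component fit is also
seeded with the (k-1)-component solution plus one extra component, which
makes R^2 provably non-decreasing in k.  Components, youngest first, define
event windows (mean +- 2 sd, truncated at the midpoint between adjacent
means so windows stay disjoint), and blocks are labeled by the window
containing their median Ks (SCT ~ 0.25-0.31 within genomes, the older
hexaploidy ~ 1.1-1.3, orthologs ~ 0.12 between genomes).

## Quartet assembly and reliability filters

For each anchored paralog pair in a tetraploidy-labeled block, the two
orthologs are looked up through ortholog-labeled block anchors (ties
resolved toward the longest block, then lexicographic gene id); a quartet is
emitted when both orthologs exist and differ.  The four sequences share a
union codon alignment built progressively — (P1,S1) and (P2,S2) pairwise,
then profile-profile with the same scoring; when both guide alignments are
gap-free and equal length the union is the identity.  Quartets with any
pairwise gap fraction > 50% or any pairwise amino-acid identity < 40% are
dropped.  The second genome's paralog pairs are scanned by symmetry.

## Whole-gene conversion (WCV)

A WCV is called for a paralog pair when three conditions hold:

1. Ks(paralogs) < min Ks of the two ortholog pairs;
2. neighbor-joining on the 4x4 JC nucleotide distance matrix yields the
   paralogs-sister topology (for four taxa the NJ Q criterion reduces to the
   four-point pairing rule);
3. codon-column bootstrap support for that topology >= 0.95 (B = 1000).

The acceptor is the copy whose ortholog distance was stretched (the larger
ortholog Ks); when the two ortholog Ks are within a factor 1.2 the direction
is reported as `both_copies` (both duplicates affected, or conversion too
close to speciation to polarize).  Requiring the topology plus bootstrap, and
not the Ks inequality alone, keeps the whole-gene false-positive rate below
1% at the study divergences — raw Ks inequalities over-call at low
divergence.

## Partial-gene conversion (PCV)

Five steps, on the shared alignment columns of a filtered quartet:

1. **Site profiles.**  For the scanned paralog pair and the two ortholog
   pairs, each column is 0 (match), 1 (mismatch) or missing (gap or
   ambiguous base in any of the four genes).
2. **Score.**  `score(i) = o(i) - p(i)` with `o` the missing-aware mean of
   the two ortholog profiles and `p` the paralog profile; missing columns
   score 0.  Scores live in {-1, -0.5, 0, +0.5, +1}: positive where the
   paralogs are locally more alike than orthologs.
3. **Candidate tracts.**  All Ruzzo–Tompa maximal scoring segments;
   segments with fewer than 10 informative columns are discarded.
4. **Significance.**  The top candidate is tested against a null built by
   shuffling the score columns in codon-sized blocks (B = 1000).  Codon
   blocks are used because first/second/third positions carry very
   different mismatch rates; shuffling single columns would clump
   high-variance positions and distort the null.  Permutation (rather than
   resampling with replacement) keeps the observed column multiset fixed, so
   under the null the p-value is exact up to the discreteness of the
   half-integer scores; ties between null and observed count half (mid-p).
   The null statistic is each replicate's maximum-sum subarray, which equals
   its top Ruzzo–Tompa segment score.  Measured per-quartet false-positive
   rate on 1,000 conversion-free quartets: 4.0% at alpha = 0.05.
5. **Recursion.**  A significant segment (p <= 0.05) is reported as a call,
   its columns are masked (score zero), and the scan repeats, up to 10
   rounds, so multiple tracts per gene can be recovered.

Tract coordinates are mapped from alignment columns to the acceptor's
ungapped nucleotides, 1-based inclusive.  Direction: within the tract the
acceptor is the copy whose own-ortholog profile carries the mismatches;
equal counts give `ambiguous` with a deterministic lexicographic acceptor.

## Synthetic data generator

The generator is first-class, tested code; it defines the study conditions
for every calibration and power experiment.

* **Quartets.**  A stop-free random codon sequence evolves on
  ((P1,S1),(P2,S2)): per-branch substitution proposals are uniform per
  nucleotide site (JC-style); synonymous proposals are always accepted,
  nonsynonymous ones with probability Ka/Ks (default 0.3, matching the
  observed Pn/Ps range of duplicate pairs), stop-creating proposals are
  rejected.  Under this acceptance scheme the expected NG86 Ks between two
  tips equals the summed branch lengths, so the divergence targets —
  paralogs 0.25, orthologs 0.12, the within/between-genome peaks of the
  study system — are recovered by the estimator without calibration
  (measured bias < 0.005 at 500 codons over 200 replicates).
* **Conversion.**  At a configurable `time_fraction` (0 = speciation,
  1 = present) the acceptor's tract (or whole gene) is overwritten with the
  donor's current sequence; both copies then evolve on independently.
  Implanted tract lengths default to 30-120 nt, bracketing reported example
  tracts (~41 nt) and exercising the 10-nt detection floor.
* **Genome pairs.**  Each ancestral chromosome yields two homoeologs per
  genome; ancestral genes survive as full quartets with probability given by
  a duplicate-density profile along the chromosome, else as single-copy
  ortholog pairs; duplicates convert with probability given by a second
  profile.  Genes get 1-based bp spans on a uniform spacing (default 5 kb),
  driving the decile/1-Mb-window statistics.  Both members of a converted
  pair are flagged converted in the truth, matching how converted duplicates
  are counted downstream.
* **Expression.**  Pair mean TPM is log-normal; the between-copy log2 fold
  change is zero-mean normal with a smaller spread for converted pairs
  (defaults 1.42 vs 1.67, placing ~52% and ~56% of pairs beyond twofold,
  the regime reported for real duplicate pairs).

What the generator does *not* emulate: indels (real alignments gap),
codon-usage and GC bias, rate variation across genes and sites, tandem
duplications, fractionation-biased gene loss, and genuinely unknown event
times — `time_fraction` is exposed, not assumed.  Passing synthetic tests
therefore demonstrates correctness of the inference machinery under the
stated model, not performance on real genomes.

## Downstream statistics

Exact-count rates (`round(100 n/d, 2)`); decile conversion rates per
chromosome-length tenth with a one-way ANOVA across first/last/middle
position groups over per-chromosome rates; duplicate-density versus
conversion-rate Pearson correlation over 1-Mb windows (windows without
duplicates excluded pairwise; < 3 usable windows or zero variance flagged);
pooled-variance two-sided t-tests for the converted/nonconverted group
comparisons; expression divergence as the fraction of pairs at or beyond a
twofold TPM change after removing non-expressed genes (pseudocount 0.1
guards near-zero survivors); per-GO-term Pearson chi-square without
continuity correction on the converted x in-term 2x2 table, raw p plus
Benjamini–Hochberg q.

## Problem sizes and known limitations

The packaged experiments use 500-codon quartets (n = 1000 for calibration,
n = 200 for power), 2-chromosome genome pairs with 100-200 ancestral genes
and 200-codon genes for end-to-end runs, and 2,000-point samples for
mixture recovery; all are seeded and reproduce bit-identically.

Boundary precision of PCV tracts is information-limited: between an
implanted tract edge and the nearest site at which donor and acceptor
actually differed (density ~ 0.11/nt at paralog Ks 0.25), conversion changes
nothing, so no detector can localize the edge more finely; reported tract
ends also extend to nearby positive-score noise columns.  Expect single-digit
to ~15 nt edge error at these divergences.  Detection power at
time_fraction 1 is ~60-75% for 60-nt tracts and >= 95% from ~90 nt; shorter
or older tracts are found at correspondingly lower rates.  Whole-gene calls
are conservative by design (topology + bootstrap), trading a few percent of
power near time_fraction 0.5 for a < 1% false-positive rate.
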