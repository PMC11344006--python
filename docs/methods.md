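# Methods

This note documents the models, conventions, and design choices behind
`vntrkit`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and alignments

All internal coordinates are 0-based half-open on the forward strand;
BED input/output keeps its native (identical) convention and PAF is
consumed natively. CIGAR ops `=`, `X`, and `M` are all treated as
aligned columns (aligners emit either the extended or the classic
dialect); `I` consumes the assembly, `D` the reference.

Liftover maps a reference interval to the assembly positions of its first
and last aligned bases. When an interval edge falls inside an assembly
deletion the edge **snaps inward** to the nearest aligned base — the
behavior of common extraction-oriented liftover tools — and the projected
interval is correspondingly shorter; an interval lying entirely within a
deletion is an error, not an empty interval. When several alignment
records cover a locus, the one with the longest target overlap wins, with
ties broken by mapq and then query name, which makes the choice
deterministic.

Translation uses the standard genetic code. The raw translation keeps
internal stops as `*` for inspection; the reported protein is truncated
at the first internal stop. ORF classes: *complete* (initiator M, single
terminal stop), *truncated* (internal stop), *incomplete* (missing start,
missing terminal stop, or unliftable exons).

## Domain annotation

Real curation of mucin domain architecture is manual. Here it is
formalized as a greedy left-to-right scan: at each position the library
exemplar with the highest **ungapped identity ≥ min_identity** (default
0.80) is annotated and the scan resumes after the match; ties break by
library order. Unmatched stretches between matches become `PTS` when
their serine+threonine fraction exceeds a floor (default 0.40 — PTS
domains are S/T-rich by definition) and `linker` otherwise. For exemplar
matches the annotation's identity field holds the match identity; for
PTS/linker stretches it holds the S+T fraction of the stretch.

Tandem-repeat domains are matched across haplotypes **by position in the
protein** (TR1 = first in protein order), not by sequence similarity;
this is the simplest testable correspondence rule and is a known
limitation for haplotypes that gain or lose whole domains, where
positional indices shift.

Protein groups are equivalence classes of identical architecture vectors
(cys copy numbers, TR domain count, per-domain motif counts). Classes of
size ≥ `min_group_size` get labels P1…Pk ordered by descending size and
then by their lexicographically smallest member; smaller classes are
`ungrouped`. `min_group_size=2` is the strict policy (a group must
contain more than one haplotype); `min_group_size=1` admits informative
singletons, appropriate at near-invariant loci. The label ordering is a
package convention, not a biological statement.

## Motif decomposition

Domains are tiled into consecutive fixed-size blocks (8 aa / 24 nt and
29 aa / 87 nt are the common mucin consensus sizes). Fixed-frame tiling
is the only segmentation consistent with exhaustive unique-motif
counting at a fixed consensus size; a `best-consensus` phase policy is
offered for domains whose annotated boundary may be off-frame — it
chooses the offset maximizing the number of blocks starting with the
consensus prefix (default `TTSTTS`), ties to the smallest offset.
Trailing partial blocks (and any skipped prefix) are excluded from
counts but preserved, so *prefix + motifs + remainder* reconstructs the
domain byte-exactly — an invariant the tests rely on. Amino-acid and
nucleotide catalogs are built independently by running the same tiling
at the respective length.

Usage matrices normalize per row (motif count / total motifs, absorbing
VNTR length variation) and optionally per column by min–max scaling to
[0, 1] ("normalization within motifs"; constant columns map to 0 — they
carry no contrast). Min–max was chosen over z-scoring for boundedness;
z-scores of near-constant columns explode.

UPGMA is implemented directly: merge the closest pair, with the distance
between merged clusters the unweighted average over leaf pairs, and node
height **half** the merge distance (the ultrametric convention, so leaf
branch lengths read as distance/2). Ties break by the lexicographically
smallest cluster representatives and leaf order is smaller-subtree-first,
making trees deterministic. The default metric is Euclidean on the
normalized matrix. Tests cross-check merge heights against SciPy's
average linkage (×2) and a naive oracle.

## Tajima's D and the permutation null

D follows the 1989 definition with constants computed by direct
summation; π is the mean over all haplotype pairs of per-site
disagreements. Sites with more than 25 % missing calls in a bin are
excluded from both S and π; remaining missing entries are handled
pairwise-complete. D is **undefined** (returned as `None`, never an
exception) when S = 0 or the variance term vanishes — at n = 2 the c₁/c₂
constants are exactly zero, so no two-haplotype bin ever gets a value.

Bins are half-open `[k·b, (k+1)·b)` (default b = 10 kbp) and retained
only with ≥ 10 SNPs segregating in the analyzed haplotype subset.
Percentile ranks against the background distribution count strict
inequalities; flags are bottom5/bottom10/top5/top10 at the 5/10/90/95 %
ranks. Per-haplogroup scans are plain haplotype subsetting before
binning — no separate machinery.

The permutation null resamples `n_bins_per_replicate` background bin
values per replicate (without replacement when the background is large
enough, otherwise with replacement, logged) and records the replicate's
tail-percentile cut point (5th percentile for the lower tail). The
empirical p of a bin is `(1 + #{cut points at least as extreme as D}) /
(1 + R)` — for the lower tail, cut points ≤ D — which cannot be zero.
Because the cut points estimate a fixed percentile of the background,
p behaves like a detector threshold: under the null about 5 % of bins
fall below p = 0.05 (the calibration the acceptance test checks), while
p is not uniform across (0, 1). A `pooled` flag offers the alternative
reading in which the sampled values themselves form the null. Multiple
testing uses Bonferroni over bins × populations; the correction method
is a package choice. The tail is an explicit parameter: lower for
positive-selection scans, upper for balancing selection.

## LD, blocks, tag SNPs

D′ and r² come directly from phased gamete frequencies (no EM), with
missing haplotypes dropped pairwise-complete; monomorphic sites raise an
undefined-LD error rather than returning 0. Dmax follows Lewontin's
normalization. Site filters (MAF ≥ 0.05, diploid call rate ≥ 0.75, HWE
p ≥ α with α defaulting to 10⁻³ — the conventional pre-LD screen)
operate on genotypes formed by pairing consecutive haplotypes.

Gabriel blocks need a confidence interval on |D′|; this package uses a
nonparametric **bootstrap over haplotypes** (B = 200, percentile 5/95
bounds, seeded), rather than the Haploview composite-likelihood grid —
simpler, assumption-free, and adequate at the panel sizes involved. A
pair is strong LD when the CI lower bound ≥ 0.70 and upper ≥ 0.98,
strong recombination when the upper bound < 0.90; candidate site ranges
where strong pairs make ≥ 95 % of informative pairs are accepted greedily
from largest bp span downward, skipping overlaps. Note an arithmetic
property of the ≥ 95 % rule: a sufficiently large block can absorb an
adjacent independent site and still satisfy the ratio; block detection is
therefore most crisp for blocks up to a few dozen sites. `max_span_bp`
(default 200 kbp) caps pair enumeration.

Haplogroups are encoded as biallelic pseudo-sites (1 = carrier) placed at
the sentinel position −1 so they can never collide with a real site.
Tag-SNP discovery scores every site in a caller-chosen window — the
window is deliberately a required parameter, since sensible choices
(e.g. 10 kbp around the gene versus 50 kbp around the locus) differ by
use case — and hits require r² **strictly** greater than the threshold
(default 0.85). The same scoring path accepts an explicit position list
for externally supplied GWAS/eQTL variants.

## Synthetic data

The generators produce the statistical structure each analysis responds
to, not sequence realism:

* **Grammar cohorts** sample domain copy numbers and motifs from a
  template, reverse-translate with a fixed codon table, and mutate with a
  per-block substitution count of `min(Binomial(L, μ), ⌈μ·L⌉)` — the cap
  guarantees every emitted motif stays within a provable Hamming budget
  of its grammar source, which makes catalog-recovery tests exact.
  Nonsense substitutions are resampled away unless `allow_stops` is set,
  keeping fixtures translatable.
* **SFS matrices** draw per-site allele counts from P(i) ∝ 1/i (neutral
  expectation), ∝ 1/i² (rare excess), or ∝ i/(n−i) truncated to
  minor-allele counts i ≤ n/2 (common excess; without the truncation the
  law would concentrate on nearly fixed alleles, which contribute to D
  like rare variants). Sites are exchangeable and unlinked — there is no
  coalescent correlation structure, so calibration results speak to the
  statistic, not to genome-scale autocorrelation.
* **Planted LD blocks** give each haplotype one of k local patterns per
  block (k ≤ 3 keeps every within-block pair at |D′| = 1) with
  independent Bernoulli(½) spacer sites; truth block indices are emitted.
* **Diploids** sample genotypes from (q²+Fpq, 2pq(1−F), p²+Fpq), clipped
  and renormalized; F = −1 at p = ½ forces all heterozygotes.

Every generator is a pure function of config + seed (one
`numpy.random.default_rng` per call), so all fixtures are bit-reproducible.

Passing tests on these inputs demonstrates correctness of the
implementations and their calibration under the stated sampling laws;
they do not demonstrate robustness to assembly error, alignment
ambiguity, recombination-driven LD decay, or population structure, none
of which the generators emulate.

## Problem sizes

The test suite and the acceptance script run at deliberately modest
sizes chosen to make the statistical checks decisive while keeping runs
interactive: 200 random matrices (n ≤ 10, S ≤ 20) for the Tajima oracle,
1,000 neutral replicates at n = 50, S = 50, a 500-replicate permutation
null scored on 1,000 query bins, 500 HWE replicates at N = 200 diploids,
50 block layouts at n = 200 haplotypes plus 100 specificity runs, and
100 random UPGMA/liftover instances each.

## Known limitations

* Positional TR-domain correspondence breaks down across haplotypes with
  domain gains/losses (see above).
* The Gabriel ≥ 95 % ratio rule can merge a very large block with an
  adjacent independent site (a property of the definition itself).
* Bootstrap |D′| CIs are not bit-compatible with PLINK/Haploview's
  composite-likelihood intervals; block boundaries can differ on
  borderline pairs.
* The permutation p is a cut-point exceedance probability, not a
  uniformly distributed p-value (documented above).
* The segmentation is indel-blind: a single-residue indel inside a
  domain shifts every downstream motif frame.
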