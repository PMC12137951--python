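# Methods

This note documents the statistical machinery implemented in popscan, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions adopted where the
underlying procedures are conventionally underspecified.

## Estimators

**Nucleotide diversity.** Per biallelic site with n non-missing alleles and
c alternate copies, π = 2c(n−c)/(n(n−1)) — the unbiased average pairwise
difference. Windowed π sums site values over a window and divides by the
full window length in bp (default 100 kb windows, 50 kb steps, tiling each
chromosome from position 1). Dividing by window length, not by variant
count, is the default because it yields per-bp diversity on the familiar
10⁻³ scale and treats invariant positions as zero diversity; a per-variant
mode is exposed. Trailing windows shorter than the window size are emitted
with their true length, flagged `truncated`, and included in means.

**Individual inbreeding coefficient.** For one sample,
F = (O_hom − E_hom)/(L − E_hom) over the L sites where the sample is called
and at least two alleles are called in total; per-site expected
homozygosity is the unbiased 1 − 2c(n−c)/(n(n−1)) (the same n/(n−1)
correction as π, matching the convention of the standard VCF tools).
F is undefined (an error) when every usable site is expected fully
homozygous. Note that E_hom is computed from the pooled sample: in a
structured panel the Wahlund effect pushes individual F above the
within-cluster inbreeding coefficient, so parameter-recovery tests
validate F against a panmictic simulation.

**Weir–Cockerham F_ST.** Per site, the 1984 variance components for r = 2
diploid populations are computed from group sample sizes n_i, allele
frequencies p_i and observed heterozygote proportions h_i, via the
intermediates n̄, n_c, p̄, s², h̄:

- a (among populations), b (among individuals within populations),
  c (within individuals); the site estimate is θ = a/(a+b+c).

Sites where either group has no call, or with n̄ ≤ 1, or monomorphic across
both groups (denominator 0) contribute zero components and are excluded
from ratios. The windowed default is the **weighted** ratio of sums
Σa/Σ(a+b+c) — the headline output of the standard tools — with
mean-of-per-site-θ as an alternative. Negative per-site estimates are kept
in the sums (clamping is a flag): removing them would bias the estimator's
expectation upward.

**Variant spacing and density ratios.** Spacing is genome length divided by
variant count, rounded half-up to the nearest integer bp. Cross-species
comparison uses combined (SNP + indel) density per bp; the ratio a/b and
the percent reduction 100·(1 − b/a) are reported.

## Outlier-region procedure

Windows with defined F_ST are ranked; the top-q set holds the ⌈(1−q)·N⌉
largest values with boundary ties broken toward inclusion, and the reported
threshold is the largest value *not* in the set, so membership is exactly
"F_ST > threshold". (If every value is identical the set is empty and the
threshold is that value.) Each top-1% window seeds a region, which extends
left and right through consecutive overlapping-or-adjacent windows in the
top-5% set; overlapping or bookended regions merge. Two contrasts are then
cross-checked: every pair of regions overlapping by ≥ 1 bp yields a merged
candidate, tiered by the strongest window support inside the overlap —
tier 1 when the overlap intersects top-1% windows of both contrasts,
tier 2 for top-1% of exactly one plus top-5% of the other, tier 3 for
top-5% of both only. Regions with no cross-contrast overlap are reported
untier-ed. Gene intersection uses ≥ 1 bp overlap in 1-based inclusive
coordinates, as does the named-locus check.

Deliberately open choices, decided here: extension through top-5% flanks is
unbounded (no cap on region length); the top-5% window supporting a tier-2
call may be any top-5% window, not necessarily a flank of a seed region in
its own contrast; cross-check overlap is ≥ 1 bp.

## Filtering

Rules run in a fixed order with each removed site attributed to the first
rule that fires: QUAL → indel → multi-allelic → missingness → MAF. Before
any site rule, genotype calls with DP ≤ 10 are masked to missing, so they
count toward the missingness rule — the usual per-genotype depth
semantics. All boundaries are strict: QUAL must exceed 20, a site is
removed with strictly more than 3 missing calls (3 is kept), and a site at
MAF exactly 0.05 is kept ("MAF < 0.05 removed"). MAF is computed over
non-missing alleles after depth masking. The defaults correspond to the
stricter of the two quality/depth settings commonly run (Q > 20, DP > 10);
both are configurable, and the filter is idempotent.

LD pruning slides windows of 50 SNPs advanced by 5 along each chromosome
(a chromosome with fewer SNPs gets a single window). Within a window,
pairs of still-retained SNPs are visited in index order; when the dosage
r² (Pearson, over samples called in both columns) exceeds 0.5, the
later-indexed SNP is dropped — a deterministic tie-break independent of
traversal order, in place of MAF-based heuristics. Pairs with fewer than 2
shared samples or zero variance are treated as not in LD. The guaranteed
post-condition: no retained pair within any window exceeds the threshold.

## Phylogeny

The pairwise distance between two diploid genotypes is allele-multiset
mismatch: per jointly-called site 1 − (shared alleles)/2, i.e. hom–hom
same 0, hom–het 0.5, hom–hom different 1, het–het with the same alleles 0;
the pair distance is the mean over joint sites. For biallelic SNPs this is
|dosage_i − dosage_j|/2. The het–het-same → 0 convention is a documented
choice (the distance tools in circulation do not all agree) and is
oracle-tested internally. p-distances may violate the triangle inequality;
that is expected and harmless for NJ.

Neighbour joining uses the Studier–Keppler Q-criterion, joining the pair
minimising Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with ties broken
toward the lowest index pair so results are deterministic. Negative branch
lengths are clamped to zero with the deficit transferred to the sibling
edge (raw lengths available via flag). NJ is consistent on additive
matrices — random additive trees of 5–12 taxa are recovered with
Robinson–Foulds distance 0 and branch lengths to 1e−9 — but plain NJ is
not guaranteed to match BME-refined NJ variants on noisy matrices.

Bootstrap resamples SNP columns (sites) with replacement to the original
count; each replicate rebuilds the distance matrix and tree, and each
internal edge of the full-data tree is annotated with the percentage of
replicates containing the same leaf bipartition. A replicate that leaves
some pair with no jointly-called site is redrawn (capped at 100 retries).
Outgroup rooting places the root on the edge subtending the outgroup leaf,
splitting its length equally; supports travel with their subtrees.

## SSR mining

Maximal perfect tandem repeats of primitive 1–6 bp motifs, with minimum
unit counts 10 (mono), 8 (di), 6 (tri) and 4 (tetra/penta/hexa). For each
unit size k the scan finds maximal k-periodic stretches; a stretch of
length L anchored at its left end yields ⌊L/k⌋ complete units. Requiring
the motif to be primitive resolves multi-period runs to their smallest
true period once (poly-A is mono, (AT)n is di and never mono or the
tetramer ATAT), preventing double counting. Matching is case-insensitive;
N never matches anything. Compound/interrupted repeats are out of scope —
only perfect repeats are reported. Canonical motif classes are the
lexicographic minimum over all rotations of the motif and of its reverse
complement.

## Synthetic data generator

The generator emulates a small, strongly inbred, three-cluster diploid
resequencing panel. Per site, an ancestral frequency p is drawn uniform on
[maf_floor, 1 − maf_floor] (default floor 0.05, so the MAF filter removes
a predictable, modest fraction after sampling noise); per-cluster
frequencies follow the Balding–Nichols model,
p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F), giving mean p and variance F·p·(1−p).
Genotypes within a cluster deviate from Hardy–Weinberg by a
within-individual inbreeding coefficient f: P(alt hom) = p² + f·p·q,
P(het) = 2pq(1−f), P(ref hom) = q² + f·p·q.

Defaults mirror the study system the package was written around: 3
clusters of 9/9/8 samples (a 26-accession ingroup), divergence F = 0.10
(field estimates of pairwise cluster F_ST spanned 0.07–0.13), f = 0.55
(observed individual F_IS 0.52–0.58), 13% of variants emitted as 1–5 bp
indels (70,509 indels among 539,800 variants in the motivating dataset),
2% missing calls, Poisson(30) per-call depth, and QUAL uniform on
[25, 60]. Where the motivating study reports no value (missing rate, depth,
QUAL), the choice is a typical mid-coverage resequencing panel and is not
tuned. The reference FASTA is random sequence with a deterministic census
of planted SSRs; the GFF3 carries genes tiling any planted windows plus
background genes every 150 kb; a sample→cluster TSV and a JSON truth
sidecar (cluster assignments, ancestral and per-cluster frequencies,
planted windows and SSRs) accompany every dataset. One RNG stream drives
the dataset, with per-chromosome sub-streams seeded from (seed, index), so
output is byte-identical given a seed.

"Planting" a divergent window for a named contrast shifts in-window
frequencies of the contrast's A-clusters by +δ and B-clusters by −δ,
clipped to [0, 1]: δ = 1 plants a fixed difference (window F_ST = 1),
δ = 0 is the identity, and δ = 0.8 over a background of F = 0.13 reliably
lifts a window above the genome-wide top-1% threshold.

What the generator does **not** emulate: linkage disequilibrium and
recombination structure (sites are exchangeable given their frequencies,
so LD pruning on simulated data removes only chance correlations),
realistic site-frequency spectra (the uniform ancestral choice is a
modelling convenience), indel length distributions, sequencing error, and
non-random missingness. A green parameter-recovery test therefore
establishes estimator correctness under the stated generative model, not
robustness to those real-data features.

## Numerical notes

- Quantile rank counts use ⌈(1−q)·N − ε⌉ with ε = 1e−9 to absorb binary
  floating-point noise in (1−q)·N.
- The windowed LD r² block computation takes moments over the samples
  jointly called in each pair, so it agrees exactly with the scalar
  pairwise definition; pairs sitting on the cutoff to within an ulp may
  differ from an independently rounded computation by 1e−9-scale amounts.
- Weir–Cockerham components are computed vectorised across sites; sites
  with undefined intermediates are zeroed rather than propagated as NaN.
- All coordinates are 1-based inclusive internally; BED output alone is
  converted to 0-based half-open.
- Bootstrap supports are exact percentages of replicates; they are written
  to Newick as integer internal-node labels.

## Known limitations

- F_ST is implemented for two-group contrasts (r = 2) only; the multi-way
  cluster comparisons reduce to pairwise contrasts.
- Plain NJ (not BME-refined); topology on non-additive matrices may differ
  from FastME-style tools.
- Individual F on structured panels conflates inbreeding with the Wahlund
  effect (by construction of the estimator; see above).
- The reader supports diploid GT records only; haploid or polyploid VCFs
  are rejected rather than coerced.
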