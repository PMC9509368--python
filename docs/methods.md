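# Methods

This note documents the models behind each silkpan module, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Statistical kernels (`silkpan.stats`)

**Fisher's exact test** uses the two-sided probability-mass rule: the
p-value is the total hypergeometric probability of all tables sharing the
observed margins whose probability does not exceed that of the observed
table. The enumeration runs in exact integer arithmetic (all candidate
tables are rationals over one common denominator), so "does not exceed" is
decided exactly rather than to float precision — floating-point near-ties
between mirror tables cannot flip a term in or out of the sum. The test
suite cross-checks against `scipy.stats.fisher_exact` and against an
independent exact-fraction enumeration.

**Benjamini–Hochberg**: q(i) = min over j ≥ i of m·p(j)/j on the ascending
order statistics, capped at 1, input order preserved. After the monotone
pass q ∈ [p, 1] elementwise. Cross-checked against
`statsmodels.stats.multitest.multipletests`.

**Two-sample t-test** defaults to the pooled-variance Student form (Welch by
flag), delegating to `scipy.stats.ttest_ind`. Degenerate inputs are given
explicit conventions rather than NaN: both groups constant with equal means
→ p = 1; both constant with different means → p = 0.

**Fold change** is max/min of two frequencies. One zero frequency → +inf
(a fixed difference passes any finite threshold); two zeros → 1 (never
significant). This choice guarantees a fixed presence/absence difference is
never silently dropped by the fold-change filter.

**Silk fineness** is the linear mass density F(dtex) = 10,000 · weight(g) /
length(m).

## Window statistics (`silkpan.popgen`)

Windows start at 0 every 500 bp, are 5 kb wide, and the final window of each
chromosome is truncated at its end. Diploid genotypes are treated as 2n
exchangeable lineages; missing genotypes are dropped per site. Windows with
fewer than three usable sites score NaN and are excluded from percentile
ranking. Internally all coordinates are 0-based half-open; VCF I/O converts
at the boundary.

**π** uses the unbiased per-site estimator 2p̂(1−p̂)·n/(n−1) summed over
sites, with n the called alleles at that site.

**Tajima's D** = (π − S/a1) / sqrt(e1·S + e2·S(S−1)) with the standard
constants computed from n. Sites with any missing genotype are dropped for
D so that S and π refer to one fixed lineage count. S = 0 or n = 2 (zero
variance) → missing.

**FST** accumulates per-site numerator and denominator over the window and
returns the ratio of sums. The default estimator is Hudson's:
num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1),
den = p1(1−p2) + p2(1−p1); ratio-of-sums is used because it is robust to
unbalanced sample sizes. A Weir–Cockerham θ (allele-count form) is
selectable; on balanced simulated data the two agree within 0.02.
Sites monomorphic across both populations are skipped.

**XP-CLR score.** The method is a composite likelihood ratio over the SNPs
of a window, contrasting a neutral drift model against a hitchhiking model
anchored at the window midpoint:

* Neutral transition density: f(p2 | p1) = Normal(p1, ω·p1(1−p1)) truncated
  to (0,1), with the truncated tail mass placed as point masses at 0 and 1.
  ω is a drift-variance scale estimated genome-wide by method of moments,
  ω̂ = mean[(p_obj − p_ref)² / (p_ref(1−p_ref))] over sites polymorphic in
  the reference population. When sample frequencies (rather than true
  frequencies) enter this estimator, sampling noise inflates ω̂ somewhat,
  which makes the scan conservative; we accept this rather than subtracting
  estimated sampling variance.
* Sweep model: each lineage escapes the sweep with probability
  c = 1 − exp(−r·ln(2Ns)/s), r = physical distance × recombination rate;
  otherwise it is dragged to the selected background, so a pre-sweep
  frequency p becomes 1 − c + c·p. The observed derived-allele count is
  binomial given the post-sweep frequency. s = 0 (or 2Ns ≤ 1, too weak to
  model) degenerates to the neutral c = 1.
* Score = max over the s grid of 2(logCL(s) − logCL(0)) ≥ 0. The default
  grid is {0} ∪ 20 log-spaced values in [1e-4, 0.5].

The likelihood integral over p2 uses 300-node Gauss–Legendre quadrature on
(0,1); the integrand (Gaussian × binomial) is smooth, and the test suite
verifies agreement with an independent 10,000-point trapezoid oracle to
1e-6. No linkage-disequilibrium weighting of SNPs is applied (the original
software down-weights correlated SNPs; with the LD-free generator used here
that machinery would be untestable).

## Sweep calling (`silkpan.sweeps`)

Quantile thresholds are computed genome-wide over non-missing windows with
linear-interpolation empirical quantiles; ties at the threshold are included
(conservative and deterministic). A window is a sweep window iff it is in
the top 1% of FST, the top 5% of XP-CLR, the lowest 5% of descendant
Tajima's D, and descendant D < ancestral D at that window. Passing windows
sharing ≥ 1 bp are merged into maximal regions after the intersection (the
alternative — merging each track's selected windows before intersecting —
would report broader regions; intersect-then-merge is the stricter reading).
Genes overlap a region by ≥ 1 bp under half-open arithmetic. The intended
contrasts are wild (ancestral) vs local (descendant) for domestication and
local vs each improved group separately for improvement.

## Pan-gene analysis (`silkpan.pangene`)

Occupancy classes over N genomes: count = N → core; 0.9N < count < N →
softcore; 2 ≤ count ≤ 0.9N → dispensable; count = 1 → private. The
boundary is deliberately strict: at N = 100, count 91 is softcore and 90 is
dispensable.

Accumulation curves report the expected pan (union) and core (intersection)
orthogroup counts as genomes are added. Default is the mean over 100 random
permutations with a recorded seed; a user-supplied fixed order (e.g.
phylogeny-guided stepwise addition) is also supported since both appear in
practice. pan(x) is non-decreasing, core(x) non-increasing, and
pan(N) = total orthogroups for every order.

The plateau model y = A + B·e^{Cx} is fitted by least squares
(`scipy.optimize.least_squares`) from a deterministic initialization —
A0 = max(y) for a rising curve (min(y) for a falling one), C0 and B0 from a
log-linear regression of log|y − A0| on x — plus five jittered restarts,
keeping the best residual sum of squares; non-convergence raises with
diagnostics rather than returning silently. `plateau_size` solves
|B·e^{Cn}(e^C−1)| < ε·A in closed form (ε = 0.001 by default) and verifies
the integer boundary; C ≥ 0 is signalled as "no plateau".

Group frequency differentiation builds one 2×2 presence table per
orthogroup ("frequency" of an orthogroup in a group = fraction of the
group's genomes containing it), applies Fisher + BH across all tested
orthogroups, and flags q < 1e-4 with fold change > 2, reporting the
direction of change in the second group.

## SV toolkit (`silkpan.sv`)

Non-redundant sites come from single-linkage clustering within
(chromosome, type): two calls link when their start positions differ by
≤ 500 bp and min(len)/max(len) ≥ 0.7; when both calls carry sequences an
edlib identity ≥ 0.25 is also required (alignment-based refinement beyond
identity is out of scope — breakpoint + size clustering keeps the procedure
reproducible without alignment machinery). The representative is the member
with the median position, ties to the smallest sample id, making the result
invariant to input order. A second parameter preset (1 kb distance, same
type, 50 bp minimum length) mirrors the consolidation used for error-prone
region discovery.

Filters remove, in order: calls longer than 100 kb (strictly — a 100,000 bp
call survives), homozygous-reference (0/0) calls, and calls intersecting an
error-prone region expanded by ±2.5 kb. The removal tally plus survivors
always equals the input count.

Allele frequency is alt alleles / (2 × called samples); a carrier-frequency
mode (fraction of samples with ≥ 1 alt allele) backs the divergence scan,
since presence/absence is the natural scale for a Fisher test on carriers.
Rare means AF < 0.05 strictly. Divergence scans mirror the pan-gene
machinery on carrier tables (FDR < 1e-4, fold change > 2).

Context annotation: CDS if the SV interval overlaps any CDS exon, else
regulatory if it overlaps a gene body outside CDS (introns and UTR exons)
or the ±5 kb flanks, else intergenic; multi-gene hits list every gene with
the category set by precedence. Insertions are 1 bp points for all overlap
tests.

Multi-allelic loci reuse the clustering predicate with the type and size
constraints removed: nrSVs of any type within 500 bp form one locus; the
summary reports the alleles-per-locus histogram, maximum, and multi-allelic
fraction. SV–TE correlation counts both in non-overlapping 500 kb windows
(TEs by midpoint, SVs by position) and reports Pearson r, r², and the
regression F-test p. Pan-SV curves apply the accumulation machinery to
presence (dosage > 0). Group-specific SVs are present in every target
sample, absent from every contrast sample, and have cohort AF below 0.05.

## SV–expression association (`silkpan.expression`)

FPKM = counts / ((length/1000)·(library/1e6)). SV–gene pairs require the SV
in the gene's introns or ±5 kb flanks and ≥ 3 carrier plus ≥ 3 non-carrier
strains among those with expression data. Replicates are averaged per
strain × tissue before testing; the test is a pooled-variance t-test on
log2(FPKM+1) — the log stabilizes variance across expression levels and is
declared in the output. BH correction is pooled across all pair × tissue
hypotheses jointly (the stricter and deterministic choice versus per-tissue
correction); a pair is significant when q < 0.001 in at least one tissue.
Both tallies — pairs and pair × tissue tests — appear in the output table
so either counting convention can be read off.

## Synthetic cohorts (`silkpan.simulate`)

**SNP cohorts** follow the Balding–Nichols model: ancestral frequency
p ~ Beta(0.5, 0.5) per site, population frequency
p_i ~ Beta(p(1−F)/F, (1−p)(1−F)/F) so that Var(p_i|p) = F·p(1−p) and the
genome-wide Hudson FST between two populations at divergence F converges to
F; genotypes are Binomial(2, p_i). Defaults emulate a wild-vs-local
contrast at F = 0.05 / 0.10 with 25 diploids each — divergence of the same
order as reported wild/domestic silkworm contrasts — on a 600 kb chromosome
with ~120 bp SNP spacing. Hard sweeps transform descendant frequencies
through the same hitchhiking operator the XP-CLR model uses
(p → 1−c+c·p). Because sites are independent (no LD) the chromosome is
desk-scale, so the recombination rate is scaled up to 1e-6 per bp, putting
an s = 0.1 sweep's footprint at tens of kb — the same fraction of the
scaled chromosome that a real sweep occupies of a real one. Two caveats
follow: (i) sweep power tests exercise the frequency transform, not
haplotype structure — passing them says nothing about LD-based detection on
real data; (ii) an independent "diffuse" check exists in the tests in the
form of frequency-shift cohorts for the divergence scan, so not every
positive control is the model tested against itself. The Beta ancestral
law with binomial sampling also yields a site-frequency spectrum richer in
intermediate frequencies than a neutral coalescent, so absolute Tajima's D
values sit above zero genome-wide; all sweep criteria are therefore
relative (percentiles and contrasts), never absolute D thresholds.

**Occupancy matrices** are constructed, not sampled, to hit requested class
counts exactly: core rows all-present, private rows round-robin, softcore
and dispensable occupancies drawn uniformly from their legal ranges with
carriers drawn uniformly. Classification of the output recovers the
requested counts by construction, which makes the round trip a sharp test
of the classifier boundaries rather than of the generator.

**SV cohorts** draw null-site allele frequencies from a two-component
mixture (rare: Uniform(0.002, 0.025); common: Uniform(0.10, 0.90)) with the
mixture weight set to the configured rare-allele target (default 0.81, the
empirical pan-SV value); the component bounds were chosen so that binomial
sampling noise at 80 diploids does not push realized frequencies across the
0.05 boundary in bulk. Sites are redrawn until at least one carrier exists
— an SV site is only ever ascertained in a carrier. Shifted sites place
carrier-frequency contrast between groups (default AF 0.05 vs 0.60 at 100
of 5000 sites, a strong domestication-like shift).

**Expression** simulates log2 expression = baseline + δ·carrier +
Normal(0, σ) per strain × tissue × replicate (defaults δ = 1, i.e.
two-fold, σ = 0.1, six tissues, two replicates, matching the cohort's
RNA-seq design), back-transformed so log2(FPKM+1) equals the simulated
value exactly.

All generators are deterministic given (config, seed), and every writer
they share with the readers round-trips (read(write(x)) = x).

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the whole
suite completes in a few minutes on one CPU: 600 kb chromosomes with ~5,000
SNPs and 25+25 diploids for sweep recovery (10 seeds), 20,000 sites and
50+50 diploids for FST consistency, 5,000 SV sites with 40+40 samples for
divergence scans, and 19,411-row occupancy matrices for the classification
summaries. These sizes are stated here as the package's test design; the
statistics themselves stream over windows and scale linearly in sites ×
samples.

## Known limitations

* No linkage disequilibrium in the generator, hence no haplotype-based
  statistics (iHS/EHH) and no LD-weighted XP-CLR; sweep detection power on
  real data will differ from the synthetic figures.
* The XP-CLR normal-drift density is an approximation that degrades near
  fixation (it is what makes the score cheap and reproducible); point
  masses at the boundaries absorb most of the error.
* Orthogroup inference, SV calling from reads, graph-genome genotyping, and
  enrichment analyses are upstream/downstream of this package and out of
  scope; their outputs are this package's inputs.
* The Fisher-exact enumeration is exact but O(min margin) per table with
  big-integer arithmetic; for cohorts of hundreds of samples per group the
  scans remain fast (seconds for thousands of sites), but million-site
  scans would warrant a vectorized approximation.
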