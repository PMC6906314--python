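# Methods

This note documents the statistical models behind `introscan`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## The analysis problem

The package targets a common comparative-genomics design: one high-coverage
diploid genome per species for a small clade (here a four-species dwarf-lemur
clade plus a mouse-lemur outgroup), used to ask (i) whether species exchanged
genes after divergence, (ii) where and when, and (iii) how effective
population size and diversity have changed. All statistics operate on
biallelic SNPs from a joint VCF, per-sample consensus FASTAs, a per-site
coverage table, and MSMC2-format demographic output.

## Site patterns and Patterson's D

After polarizing alleles against the outgroup's homozygous state, each site
contributes frequency-weighted ABBA and BABA pattern counts for an ordered
quartet (P1, P2, P3, O):

    ABBA = (1 - p1) p2 p3 (1 - p4)
    BABA = p1 (1 - p2) p3 (1 - p4)
    D    = (sum ABBA - sum BABA) / (sum ABBA + sum BABA)

With one diploid per population the frequencies lie in {0, 0.5, 1}; the
frequency form is exact and deterministic, unlike the single-read-sampling
variant some genotype-likelihood tools use (equivalent in expectation).
Significance uses a delete-one block jackknife over contiguous genomic
blocks (default 1 Mb; any span much longer than linkage blocks is valid, and
the simulation experiments use 100 kb because simulated loci are independent
at the 2-kb scale). Sites where P3 carries no derived allele have zero
weight and are not counted. The jackknife needs enough informative blocks to
be calibrated; `jackknife_z` refuses to run with fewer than 20 non-empty
blocks, and users should treat |Z| from sparse tables (tens of informative
sites) with suspicion.

## Windowed f_d and candidate regions

f_d (the dynamic-donor admixture-proportion estimator) is computed in
sliding windows (default 40 kb, 10-kb step) as sum(num)/sum(den) with
per-site terms

    num = ABBA(p1, p2, p3, p4) - BABA(p1, p2, p3, p4)
    den = ABBA(p1, pD, pD, p4) - BABA(p1, pD, pD, p4),   pD = max(p2, p3)

choosing the donor site-wise. Windows whose own D is non-positive, or with
zero denominator, are recorded as f_d = 0 with a flag (following the
estimator's published guidance) rather than dropped. Coverage masking
removes windows where more than 30% of assayed sites fail the per-scaffold
depth filter (strictly above twice, or strictly below half, the scaffold's
mean of per-site cross-sample mean depths; the boundary values pass).
Candidate regions are all unmasked windows at or above the genome-wide
f_d quantile (default top 0.05%, ties kept), merged (touching intervals
merge) and clipped to scaffold ends. The quantile is computed genome-wide
jointly, not per scaffold.

## Triplet blocks and the divergence clock

For three aligned consensus sequences, windows of 100 segregating sites
(step 50) are scored by pairwise differences; maximal runs of windows where
the same non-background pair is strictly most similar are fused into
candidate blocks. The background pair is the triplet's sister pair when a
species tree is supplied (the pipeline always supplies it), else the
genome-wide most-similar pair. Windowed run boundaries overshoot a true
tract by up to a window per side, which materially inflates clock ages of
kb-scale blocks because flanking sequence is an order of magnitude more
divergent; block edges are therefore refined to the maximum-scoring
contiguous subsegment under a two-rate model (per-site log-likelihood ratio
of in-block versus background divergence, maximized with Kadane's
algorithm). Refinement is on by default and exposed as a flag.

Diploid consensus inputs use IUPAC codes: identical codes count 0
differences, codes with overlapping allele sets 0.5, disjoint sets 1.0;
`N` masks the position. Per block, the p-value is the lower binomial tail
P(X <= diffs) with X ~ Binomial(callable length, background divergence),
the background being the pair's divergence outside all candidate blocks
(non-integer half-difference totals are floored). Retained blocks must have
at least 10 segregating sites and p < 1e-6, and blocks between the
triplet's sister species are removed as presumptive incomplete lineage
sorting. Ages follow a strict molecular clock,

    age_years = (diffs / length) / (2 * mu_year),   mu_year = mu_gen / g = 0.2e-8,

with mu_gen = 0.8e-8 per generation and generation time g = 4 years.

## Heterozygosity

Per individual, non-overlapping 100-kb windows count heterozygous genotype
calls divided by (window span - missing genotype calls); invariant
positions absent from the VCF count as callable homozygous-reference.
Non-overlapping windows are the default so that the genome mean does not
double-count sequence (a step option gives sliding windows). Missingness is
per focal sample by default, with a joint-missing option that discards
sites missing in any sample. Both the windowed mean and the pooled estimate
sum(het)/sum(callable) are reported; the pooled value is invariant to
window size. Under neutrality the expectation is 4*Ne*mu per site.

## Topology windows

Local phylogenetic structure is summarized by a transparent surrogate for
HMM-based segmentation tools: per 100-kb window (minimum 50 SNPs), an
allele-sharing p-distance matrix d_ij = mean |f_i - f_j| over four
individuals is classified by the neighbour-joining quartet criterion — the
pairing {i,j},{k,l} minimizing d(i,j) + d(k,l). T1 is the split concordant
with the species tree; ties and sparse windows are unresolved (U). This is
explicitly not an HMM: there is no state persistence or emission model,
just independent window classification followed by run fusion into
segments and genome fractions per label.

## Demography summaries

MSMC2-format tables (scaled time boundaries, scaled coalescence rate
lambda) convert to biological units as time_years = scaled/mu_gen * g and
Ne = 1/(2 mu_gen lambda). The long-term summary is the harmonic mean of
per-segment Ne after dropping the first five and last five segments (the
poorly resolved extremes). The mean is unweighted across segments by
default — matching a plain average over time segments — with a
duration-weighted option (which must exclude the unbounded final segment).
The package also writes this format (`make_msmc_output`) as the exact
inverse of the conversion, so the full write -> parse -> convert ->
summarize path is testable to floating-point accuracy.

## Gene-set enrichment

Gene intervals overlapping candidate regions (half-open, >= 1 bp) are
cross-tabulated against membership in a focal gene set and tested with the
2x2 chi-square, df = 1, no continuity correction by default (a Yates flag
exists). The direction of deviation (excess/deficit) is reported with the
p-value, since a significant result can reflect a deficit.

## The synthetic-data generator

`simgenomes` draws an independent coalescent genealogy for each 2-kb locus
on a fixed species tree, then drops mutations on branches (Poisson with
rate mu per site per generation; each mutation claims a unique position, so
sites are biallelic and pairwise differences keep their closed-form
expectations). Defaults are the study conditions: topology
(((major, crossleyi), medius), sibreei) + outgroup; divergences 1.5, 2.5,
4.5 and 7.5 million generations (6/10/18/30 My at 4 years per generation);
mu_gen = 0.8e-8; Poisson(30) per-site coverage; 1% missing genotypes.

Per-branch diploid Ne defaults to 100,000 on terminal branches — the level
of the study clade's long-term harmonic means — and 500,000 on ancestral
branches. The ancestral value is chosen so the clade exhibits substantial
incomplete lineage sorting, which is what the observed behaviour of the
real data implies: a D-statistic machinery yielding |Z| ~ 17 at D ~ 0.014
on a 2-Gb genome requires on the order of 1e-3 informative site-pattern
weight per bp, two orders of magnitude more than this tree produces with
Ne = 1e5 on every branch. With the default demography a 5-Mb null genome
carries ~8,000 ABBA+BABA weight units and the jackknife Z is well
calibrated; with uniform small Ne it carries ~30 and is not.

Planted tracts are the ground truth for recovery experiments: inside a
tract, the recipient haplotype's lineage is held apart from its species and
coalesces with a donor lineage at exactly `admix_time_gens`, so the tract
has a true age recoverable by the clock (expected pair divergence
2 * mu_year * age, plus a donor-side heterozygosity term when the donor's
lineages have not coalesced by the admixture time — a ~+10% upward bias at
1 My with Ne = 1e5, visible in the recovery experiments). Zygosity is
configurable ("het": one haplotype carries the tract, the default, matching
a single unfixed pulse; "hom": both). The outgroup never participates in
admixture.

What the generator does not emulate: recombination within loci (genealogies
are piecewise constant on a 2-kb grid, so tract edges are exact and linkage
decays artificially fast); sequencing and mapping error beyond missingness
and Poisson depth; reference bias (the reference equals the ancestral
sequence); more than one diploid per species; selection. Passing recovery
tests therefore demonstrates correctness of the estimators under the model,
not robustness to artefacts of real short-read data.

## Scales and conditions of the verification experiments

All simulation-backed checks run at desk scale, chosen so the full suite
completes in minutes: null D calibration uses 200 replicates of 5-Mb
genomes under the default demography; f_d recovery plants 25 homozygous
40-kb tracts (10% of a 10-Mb recipient genome, admixture 50k generations
ago) and measures the genome-wide mean f_d against the planted fraction
and tract recall of candidate regions called at the quantile matched to
that fraction (top 10%) — the production default of top 0.05% is a
genome-scale setting that cannot, by construction, recover 10% of a
1,000-window genome; block dating plants tracts 250k generations (1 My)
old and runs under uniform Ne = 1e5, a low-ILS condition that isolates the
clock from occasional deep-coalescence windows that would otherwise pass
the p < 1e-6 filter and contaminate the mean age; heterozygosity and
topology checks use single 5-Mb genomes. Recovered values sit within a few
to ~15% of their targets (tract-age means ~+10% for the reason above).

## Known limitations

- The jackknife Z is only trustworthy with ample informative sites; the
  package warns by refusing tiny block counts but cannot detect all sparse
  regimes.
- f_d is reported as 0 (flagged) for non-positive-D windows; genome means
  over windows therefore carry a small positive bias under the null.
- Binomial block p-values ignore coalescent clustering of differences and
  are anti-conservative at locus scale; the sister-pair removal and SNP
  count filters absorb most of this in practice.
- The topology surrogate has no HMM smoothing, so single noisy windows
  break segments that an HMM would bridge.
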