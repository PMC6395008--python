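# Methods

This note documents the models, parameter choices, numerical details and
limitations behind `homeokit`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

All genotype data are biallelic SNPs. A `GenotypeMatrix` holds diploid
codes (hom-ref / het / hom-alt / missing) with optional per-genotype depth;
a `HaplotypeAlignment` holds haploid 0/1/missing alleles. Positions are
1-based within scaffolds (VCF/GFF convention); interval masks and window
coordinates are 0-based half-open (BED convention). Filters follow the
documented cascade: genotypes outside read depth 6–100 (inclusive at both
boundaries — the thresholds are coverage percentiles, so the named values
pass) are set missing; sites with *strictly more than* 80% missing
genotypes are dropped; repeat/pericentromere masks remove sites whose
0-based position falls in a masked interval. Upstream caller annotations
(MQ, SOR, QD, FS, rank sums) are honored through a generic per-site
threshold engine when the INFO fields are present; they cannot be
recomputed from genotypes and the synthetic data do not carry them.

## Subgenome phasing

Diagnostic sites are positions where each parental panel is monomorphic
homozygous for a different allele, with at most 20% missing data per panel
(inclusive). A heterozygous parental genotype counts as polymorphism and
excludes the site. An optional pre-restriction to sites heterozygous in a
configurable fraction of tetraploid accessions ("fixed heterozygotes")
exists but is off by default, because the two criteria are nearly redundant
once inter-parental fixed differences are required.

Each phased fragment is oriented by majority vote over its non-flagged
diagnostic sites: fragments with fewer than 2 informative sites are
unassignable; if the prevailing orientation is supported by less than 90%
of informative sites the fragment is chimeric (a read-backed switch
error); an even split has no prevailing state and is treated as chimeric.
Assigned fragments write their alleles to the Co/Cg sequences; chimeric and
unassignable fragments, flagged sites, uncovered heterozygous sites, and
sites where two assigned fragments disagree all become missing on both
haplotypes.

Balanced missingness: per accession and scaffold, the fraction q of
heterozygous sites that ended missing *for any of the reasons above* is
matched by masking the same fraction of homozygous sites, sampled
uniformly with a seed. q deliberately counts every lost heterozygous site
(not only chimera/flag losses): the design goal is that the phased
alignment's heterozygosity equals the unphased input's, and the algebra
only balances when all losses are counted. The suite verifies the ratio
stays within 1%.

Orientation is label-symmetric: swapping the two parental panels swaps the
Co and Cg outputs exactly (tested).

## LD-decay validation

If phasing is correct, SNPs within a subgenome of a selfing lineage are in
strong LD that decays with distance, while SNPs on opposite subgenomes are
genealogically independent. Profiles pair, per scaffold, a seeded sample of
principal SNPs with the next `n_next` SNPs from a chosen source (same
subgenome, the other subgenome, or a positional merge of both), and report
mean r² (squared Pearson correlation over pairwise-complete samples,
requiring ≥ 5 complete samples and polymorphism) in equal SNP-offset bins.
Defaults are 1000 principals and 1000 partners in 100 bins; tests use
250/500/50 to keep runtimes low. Offsets are measured in SNP index; a
bp-based mode is not provided because the bin definition used for
validation is SNP-count-based. The mixture baseline assembles a genome
whose SNP columns come from either subgenome: its profile is attenuated
relative to the within-subgenome profile because half of all nearby pairs
straddle the two subgenomes. The negative control randomly swaps the
subgenome labels of each accession's two alleles per site, which destroys
the within/between contrast.

## Diversity and divergence

Per-site diversity uses the unbiased estimator 2p̂(1−p̂)·n/(n−1) with
pairwise-complete haplotypes (n = non-missing haplotypes at the site; sites
with n < 2 are inaccessible). This equals the mean number of pairwise
differences, which the suite verifies by exhaustive pair enumeration on
random instances with up to 6 haplotypes. Dxy averages per-site difference
fractions over all between-group pairs. Window values divide by the
accessible (callable) site count when the caller supplies it (the correct
scaling, requiring an all-sites input); with SNP-only input the values are
per callable SNP and flagged `unscaled`. Windows overlapping masked
regions shrink their accessible denominator rather than being dropped.
Mean comparisons bootstrap whole 100-kb windows (10,000 resamples,
add-one-corrected two-sided p, so the smallest attainable p is 2/10001).

π₀/π₄ classifies every CDS position by codon degeneracy under the standard
table (0-fold: every substitution changes the amino acid; 4-fold: none
does; everything else, and positions in conflicting overlapping CDS,
"other"); reverse-strand codons are read on the complement, CDS phase is
honored, and a trailing partial codon is skipped with a warning. Class
positions absent from the SNP alignment count as monomorphic in the
denominator. A lowest-missingness sample subsetting (`max_samples`) mirrors
the practice of computing π₀/π₄ on the few most complete samples.

## Window phylogenies and topology weighting

Distances are absolute counts of differing sites under pairwise deletion
(optionally per-site). Neighbor joining is implemented directly because the
contract requires deterministic label-order tie-breaking and clamping of
negative branch lengths with transfer to the sibling branch; the topology
agrees with scikit-bio's `nj` on random additive matrices (tested). Trees
are rooted by the designated outgroup tip for all topology work.

For k groups there are (2k−3)!! rooted leaf-labeled topologies (3, 15, 105
for k = 3, 4, 5), enumerated by recursive leaf insertion and identified by
a sorted nested-parenthesis canonical form. The weight of a topology in a
window tree is the fraction of one-tip-per-group combinations whose induced
outgroup-rooted subtree matches it — computed exhaustively up to 10⁵
combinations, else by Monte Carlo. Weighting windows are SNP-count windows
(100 SNPs) in which every haplotype is genotyped at ≥ 50 SNPs; windows
failing the rule are dropped, not samples. The five-class aggregation keys
on the parental lineage's position: basal → species tree; direct sister to
exactly one population → that population's admixture class; otherwise
other. Over the 15 four-group topologies the classes have sizes
3/3/3/3/3 (verified by enumeration and by an independent sister-set
classification in the tests).

## ABBA-BABA

Pattern sums are computed from derived-allele frequencies
(ABBA = Σ(1−p₁)p₂p₃(1−p_O), BABA = Σp₁(1−p₂)p₃(1−p_O)) after polarizing so
the outgroup's major allele is ancestral; a residually polymorphic outgroup
enters through its frequency. D = (ABBA−BABA)/(ABBA+BABA);
f = S(P1,P2,P3,O)/S(P1,P3,P3,O) with S the ABBA−BABA difference and P3
substituted for P2 in the denominator (the complete-admixture expectation);
a split-half P3 variant (f_G) is available. Standard errors, Z-scores and
two-tailed normal p-values come from a delete-one block jackknife over
fixed 1-Mb tiles (last partial tile kept).

Finite-sample correction: the plug-in denominator contains p̂₃², whose
expectation exceeds the population p₃² by the sampling variance
p₃(1−p₃)/n₃. With 10 haplotypes this biases f downward by roughly 10%
under complete admixture. When the caller supplies the P3 haplotype count,
the unbiased product estimators p̂(np̂−1)/(n−1) and np̂(1−p̂)/(n−1) replace
the plug-in products, making f unbiased (equivalent in expectation to the
split-half estimator but using all data). The calibration suite verifies
f̂ ≈ α within 2 jackknife SE for replacement fractions α ∈ {0, 0.2, 1}.

## Homeolog-specific expression

Counts below 10 total RNA reads per SNP call are excluded. DNA counts are
pooled per SNP across accessions and tested two-sided against
binomial(0.5); SNPs below the removal threshold (default 10⁻⁶) or with
zero depth are removed as mapping-biased. The technical overdispersion of
the remaining DNA counts is the ML beta-binomial intraclass correlation ρ
with mean fixed at 0.5 (concentration ν = 1/ρ − 1), with a
normal-approximation CI and a boundary flag at the binomial limit.

The RNA model is a per-gene two-component mixture. Under H₀ the gene ratio
is 0.5 and SNP counts are beta-binomial with the DNA-calibrated ν. Under H₁
the gene's logit ratio is normal(0, σ²) (σ given a half-normal(1.5)
hyperprior — a weakly-informative, symmetric choice; the upstream framework
names no specific form) and SNP counts disperse with ν derived from
ρ_DNA + ρ_RNA, the extra RNA-level dispersion ρ_RNA estimated jointly
(half-normal(0.05) prior). The gene indicator has a shared mixing fraction
φ with a uniform prior. Sampling is Metropolis-within-Gibbs, vectorized
across genes: random-walk MH on the logit ratio where the indicator is on,
a fresh prior draw where it is off (a pseudo-prior equal to the prior keeps
the mixture move exact), Gibbs for the indicator and φ, and MH for σ and
ρ_RNA every fifth sweep. Proposal scales adapt during burn-in only, so the
post-burn-in chain is a valid fixed kernel. Defaults are the documented
long-run settings (200,000 iterations, 20,000 burn-in, thinning 100, three
chains from dispersed starts); convergence is summarized by split-R̂ of the
hyperparameters, with results flagged (never suppressed) above 1.1.

The posterior probability of HSE is the posterior mean of the indicator;
the reported ratio is the posterior mean of (ratio if HSE else 0.5).
Significance uses posterior > 0.99 with the Bayesian FDR
mean(1 − p over calls); the FDR is monotone non-increasing in the
threshold (tested). Genes are assayed per accession when the table carries
multiple accessions; per-accession grand means and population summaries
come from `ratio_summaries`.

## Synthetic data

The default generator is an infinite-sites Bernoulli model over a uniform
genome of 8 named scaffolds: no indels, no recombination within the
sprinkled panels, and exact truth for every downstream quantity. Defaults
mirror the emulated study design: 10 selfing-parent and 13
outcrossing-parent panel samples, 3 tetraploid populations of 10
accessions, 2% inter-subgenome divergence (the 1–3% band), per-site
diversity 0.01 for the outcrossing panel and 0.001 for the selfing panel
(the ten-fold asymmetry), outgroup divergence 0.03, population-private
divergence 0.003 and accession-private variation 2×10⁻⁴ (near-zero
within-subgenome variation), fragment blocks of exponential mean 20 kb
with 4-kb coverage gaps, 5% chimeras, 2% flagged sites, 5% missingness and
Poisson(30) depth. Within-panel allele frequencies follow the neutral SFS
(counts ∝ 1/i), with the segregating-site count chosen so expected per-site
diversity equals θ. Admixture tracts have exponential lengths (mean 100 kb
by default) placed uniformly without overlap — the tract-length law of real
introgressed segments is not modeled, only the genome fraction.

DNA/RNA count tables use beta-binomial draws with ρ_DNA = ρ_RNA = 0.005,
reflecting the near-binomial DNA overdispersion reported for the
calibration framework this model follows; mapping-biased SNPs (5% by
default) shift both DNA and RNA counts on the logit scale, so the DNA
filter is exercised realistically. A fraction φ of genes (default 0.2)
receives a true ratio drawn from {0.3, 0.7}.

The coalescent backend (msprime) supplies what sprinkling cannot: linkage.
`coalescent_subgenomes` simulates each subgenome as an independent
panmictic sample with recombination (defaults Ne = 5×10⁴, r = 2×10⁻⁹ —
low, as selfing demands — μ = 7×10⁻⁹), giving within- but not
between-subgenome LD for the decay validation.
`simulate_quartet_frequencies` simulates (((P1,P2),P3),O) with population
joins at 10, 20 and 100 thousand generations, Ne = 10⁴, μ = 7×10⁻⁹,
r = 10⁻⁸, 10 haplotypes per population; "replacement" admixture swaps a
fraction of the P2 sample for extra P3 haplotypes.

What passing tests do and do not show: the generator reproduces the
statistical structure the methods assume (fixed parental differences,
disomic heterozygosity, block chimeras, overdispersed counts) but not
mapping bias, indels, paralogy, or realistic recombination and
tract-length variation — so green tests demonstrate correctness of the
algorithms under their stated model, not robustness to every artifact of
real short-read data.

## Problem sizes

Desk-scale defaults keep the suite and the acceptance script fast while
leaving the estimators in their asymptotic regime: synthetic genomes of
0.2–1.5 Mb, 6–30 accessions; ABBA-BABA calibration on 80 replicates of
300 kb in the tests and 200 replicates of 500 kb in
`scripts/acceptance.py`; HSE calibration on 20 replicates of 50 genes with
20,000-iteration chains, plus one run at the full documented settings on a
60-gene panel.

## Known limitations

- The phasing assembler resolves overlapping assigned fragments
  conservatively (disagreeing shared sites become missing) rather than
  re-weighting evidence.
- Dxy under heavy, sample-biased missingness averages per-site over
  complete pairs; no imputation is attempted.
- The NJ root is the final trifurcation; branch lengths are not used by the
  topology machinery, which is purely shape-based.
- The HSE model assumes SNPs within a gene share the gene ratio up to
  beta-binomial noise; allele-specific splicing or SNP-level regulatory
  variation would violate this.
- The binomial test used for biased-SNP removal ignores the (small)
  overdispersion, making removal slightly aggressive at very high pooled
  depth; the removal threshold is configurable.
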