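# Methods

This note records the statistical conventions the package implements, the
choices made where several published variants exist, and what the synthetic
data generator does and does not emulate.

## Genotype data model and QC

Alleles are opaque non-negative integers (fragment sizes scored upstream);
no binning or size calling is performed. A call is an unordered pair stored
sorted; missingness applies to whole calls, and half-missing cells are
rejected as malformed rather than imputed. Replicate consensus follows a
two-of-three rule: an allele enters the consensus iff it appears in at least
two of three PCR replicates; one qualifying allele yields a homozygous call,
none yields a missing call, and more than two (a tie) is flagged and set
missing. The completeness filter keeps samples typed at ≥ 75% of loci
(≥ 15 of 20), matching the common threshold for degraded wildlife samples;
it is idempotent.

## Diversity statistics

- Unbiased expected heterozygosity: He = (2n/(2n−1))(1 − Σpᵢ²), n typed
  individuals.
- Allelic richness by rarefaction: Ar(g) = Σᵢ [1 − C(N−Nᵢ, g)/C(N, g)] at a
  standardized gene-copy count g. By default g is the smallest per-locus
  gene count in the analysis set (the FSTAT convention); it is always
  user-overridable and recorded in output, because published tables are
  often ambiguous about the rarefaction base.
- HWE is tested with a chi-square goodness of fit of genotype counts against
  p², 2pq expectations, df = k(k−1)/2 — the GenAlEx-style test. The exact
  (Guo–Thompson) test is out of scope; with sparse genotype classes the
  chi-square is known to be anti-conservative, so calibration checks only
  count loci whose expected counts are all ≥ 5.
- Weir–Cockerham F-statistics use the variance components a (among
  populations), b (among individuals within populations) and c (within
  individuals), computed per allele and locus. Multi-locus estimates are
  ratios of summed components, never averages of per-locus ratios:
  θ̂ = Σa/Σ(a+b+c), f = 1 − Σc/Σ(b+c), F = 1 − Σc/Σ(a+b+c). Per-group FIS
  uses the single-population (b, c) form. Groups with no typed individuals
  at a locus are dropped for that locus; loci with fewer than two
  informative groups contribute nothing.
- Pairwise-FST significance comes from permuting individuals between the two
  groups (sizes preserved) and recomputing θ̂; p = (#{θ_perm ≥ θ_obs}+1)/(B+1),
  so p is never exactly 0. No multiple-testing correction is applied by
  default. Permutations are evaluated in batch (one boolean membership
  matrix per pair), which keeps 10⁴ permutations per pair inexpensive.
- Reference partitions are formed from forest populations with ≥ 7 samples;
  market samples never enter reference partitions.

## Forensic identity

Two samples match iff their calls agree at every mutually typed locus *and*
at least 15 loci are mutually typed — the completeness bound reused so that
missing data cannot fabricate matches. Match groups are transitive closures.
p(gen) is the HWE product over typed loci from pooled frequencies, without an
inbreeding correction (the simplest published definition); p(sex) uses the
single-encounter form 1 − (1 − p(gen))^{n−1}, and the chosen form is recorded
in the report header.

The unbiased single-locus PI is the small-sample estimator
uPI = [n³(2a₂²−a₄) − 2n²(a₃+2a₂) + n(9a₂+2) − 6] / [(n−1)(n−2)(n−3)],
aⱼ = Σpᵢʲ, n typed individuals. Two properties pin the algebraic form down:
it equals 1 at a monomorphic locus for every n, and tends to the naive
2(Σp²)² − Σp⁴ as n → ∞ (0.375 for two equifrequent alleles). Loci with
n < 4 are excluded from the product and flagged.
PIsibs = ¼ + ½a₂ + ½a₂² − ¼a₄ per locus. Minimum-loci curves order loci by
ascending single-locus PIsibs ("optimized" combinations) and report the
smallest k whose cumulative product crosses the threshold; note PIsibs ≥ ¼
at any single locus, so thresholds below 0.25 always need several loci.

## Trade tracing

The procedure assumes markets were stocked from a set of reference
populations and that some alleles are private to single populations.

1. **Rarefaction.** For allele with c of the N gene copies of a population,
   the probability of appearing in a uniform subsample of g copies is
   Q = 1 − C(N−c, g)/C(N, g) (exact hypergeometrics, integer binomials). For
   a K-subset S of populations, the expected number of alleles private to
   j ∈ S is Σₐ Q_{j,a} Π_{j'≠j} (1 − Q_{j',a}); the frequency-weighted
   variant multiplies each term by p_{j,a}. Curves run over g = 2..7
   individuals (2g gene copies, matching diploid rarefaction), averaged over
   all C(J−1, K−1) subsets containing j. Combinations in which a population
   lacks enough copies at a locus are skipped and logged. These expectations
   are verified in the tests against exhaustive enumeration of every
   subsample on all instances with ≤ 8 gene copies per population, at 1e−9.
   Richness curves need not be monotone in g: contributions from alleles
   shared between populations can shrink as subsamples grow — exactly the
   "decreasing" signature the procedure discards. Only truly private alleles
   give provably non-decreasing curves.
2. **Trend classification** formalizes visual curve reading: with v the
   final value and Δ_last, Δ_prev the last two increments — *decreasing* if
   Δ_last < 0; *plateau* if |Δ_last| ≤ 0.05·v and v ≥ 0.50; *exponential* if
   the increments still grow and v ≥ 0.45; otherwise *rejected*. All
   thresholds are configurable. The default selection measure is private
   allelic **richness**: the frequency-weighted measure is bounded above by
   the allele's own population frequency, so 0.50/0.45 thresholds could
   never fire for any allele rarer than 0.5, whereas on the richness scale
   they discriminate as intended. The frequency measure remains available
   (`measure="frequency"`).
3. **Cross-validation.** A (locus, population) is retained only if its curve
   classifies as plateau or exponential *and* that population shows an
   observed private allele at that locus. Both lines of evidence are
   required; either alone is discarded.
4. **Screening.** Market genotypes are screened for the retained alleles.
   An individual is traced iff all its hits agree on one population;
   multi-population hits are reported as ambiguous, never resolved silently.
   The procedure can mis-assign when a sampling-noise "private" allele (one
   that exists in several populations but was observed in only one reference
   sample) passes cross-validation; finite reference samples make this
   irreducible, and the truth-scored examples quantify it.

## mtDNA statistics

All sequence statistics use the complete-deletion site set: sequences
containing N are excluded first (optionally), then every column holding a
gap or N in any retained sequence is dropped, making the site set invariant
to sequence order.

- Hd = n/(n−1)(1 − Σfᵢ²); π is the mean pairwise proportion of differing
  analyzed sites.
- Raggedness r = Σ_{i=1}^{d+1} (xᵢ − xᵢ₋₁)² over mismatch classes 0..d with
  x_{d+1} = 0 — no leading (x₀−0)² term, trailing term included. The
  convention is locked by worked fixtures (all-identical pairs give r = 1;
  frequencies [¼, ½, ¼] give r = 0.1875) and recorded here because both
  boundary conventions appear in the literature.
- Tajima's D uses the standard a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ constants.
- Fu's Fs takes θ̂ = π̂ (mean pairwise differences, the original definition)
  and S′ = P(K ≥ k_obs | θ̂, n) from the Ewens sampling formula, with
  unsigned Stirling numbers of the first kind computed exactly as big
  integers (log-converted with a bit-shift fallback), reliable to n ≈ 200.
  Fs = ln(S′/(1−S′)); S′ of 0 or 1 is flagged ±∞.
- R₂ = √[(1/n)Σᵢ(Uᵢ − π̂/2)²]/S with Uᵢ the singleton count borne by
  sequence i (a variant present in exactly one sequence).
- p-values come from neutral constant-size Kingman-coalescent replicates
  conditioned on the observed S (θ-conditioning is available as an option):
  exponential waiting times at rate C(k,2), S mutations placed uniformly on
  total branch length, each on a distinct site. Lower tail for D, Fs and R₂
  (the DnaSP convention); upper tail for raggedness, whose rejection
  direction is "too ragged". The +1 correction keeps p in (0, 1].
- K2P: d = ½ln(1/(1−2P−Q)) + ¼ln(1/(1−2Q)) over sites comparable in both
  sequences; saturation is flagged infinite. Lineage assignment is
  nearest-reference by mean K2P with a margin to the runner-up; ties (margin
  not exceeding the threshold, default 0) are left unassigned. This
  deliberately replaces tree building with a distance rule; it is exact when
  between-lineage divergence dwarfs within-lineage diversity and is
  validated on constructed two-cluster panels.

## Isolation by distance

Edwards chord distance D = √(1 − (1/L)ΣₗΣₐ√(p_x p_y)) over loci typed in
both units, averaging inside the square root (the common genetics-package
convention; variants exist, hence the record). Individual-level profiles use
within-individual frequencies 0/½/1, dropping loci missing in either member
pairwise. Geographic distances are great-circle kilometres (R = 6371 km)
between population centroids (or supplied centers); a flat-Euclidean
variant is not needed at the sub-degree scales involved, and coordinates
are geographic, so "Euclidean" requests are served as great-circle. The
Mantel statistic is the Pearson correlation of upper-triangle entries;
significance permutes rows/columns of one matrix jointly, one-sided upper,
with the +1 correction.

## Synthetic data generator

The generator emulates the sampling design of a Dahomey-Gap-style study:
six forest reference populations (~104 individuals in the defaults), twelve
markets contributing 65 individuals drawn from known source populations, 20
multi-allelic loci, 5% MCAR missingness. Ancestral allele frequencies are
flat-Dirichlet; population frequencies follow a Balding–Nichols Dirichlet
with concentration p(1−F)/F, giving an interpretable FST knob; inbreeding is
a per-individual autozygosity probability, equal to FIS in expectation and
reproducing the heterozygote-deficit signature. Planted private alleles get
fresh labels absent everywhere else, at frequencies spanning 0.10–0.30 in
the defaults — weak signals near the rarefied frequency range such studies
report, and strong ones capable of passing the trend thresholds. Market
coordinates are uniform over the study window; population allele frequencies
are drawn independently of geography.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: microsatellite mutation (no stepwise-mutation
model; datasets are single-generation draws), null alleles and allelic
dropout, isolation by distance (Mantel tests on synthetic data are null by
construction), migration or demographic history (no bottlenecks or growth),
and linkage. The coalescent sampler is constant-size and neutral by design —
it is the null model, not a demographic simulator.

## Numerical choices and problem sizes

Binomial coefficients are exact integers; rarefaction expectations are
float ratios of exact combs (verified to 1e−9 against rational-arithmetic
enumeration). Permutation p-values always use the +1 correction.
Calibration tests use shared-null-pool ranking (every replicate conditions
on the same n and S, so one pool serves all) with replicate counts sized for
a Monte-Carlo standard error near 0.5%: 2000 coalescent replicates, 1000
Mantel datasets and 600 exchangeable FST datasets at 99 permutations each.
Parameter recovery uses 50 replicates of 4 populations × 30 individuals ×
20 loci. The acceptance script runs the full study-scale pipeline with 999
FST permutations, 9999 Mantel permutations and 1000 coalescent replicates;
one run takes well under a minute on a single core.

## Known limitations

- The chi-square HWE test is anti-conservative at sparse genotype classes;
  an exact test would be the next addition.
- p(gen) uses pooled frequencies with no FIS correction; in inbred data it
  understates homozygote probabilities.
- Tracing confidence is qualitative (verdict + supporting hits); no
  likelihood is attached to an assignment, by design — the procedure is a
  conservative screen, not a Bayesian assignment.
- K2P lineage assignment has no bootstrap support; the margin is the only
  confidence measure.
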