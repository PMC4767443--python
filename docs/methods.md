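# Methods

`somascape` re-implements, as one tested toolkit, the computational core of a
tumor-cohort genomic-landscape analysis: somatic SNV/indel calling from
tumor/normal allele counts, depth-ratio copy-number segmentation with cohort
recurrence scoring, driver-gene discovery against a categorical background
mutation rate, opportunity-aware mutational-signature extraction, and
multi-region intra-tumor heterogeneity analysis. Because no real cohort ships
with the package, a synthetic-cohort generator with planted ground truth is a
first-class module: every downstream stage is validated against what the
generator planted.

## Synthetic cohorts

The generator emulates the data a short-read pipeline produces *after*
alignment and pileup; reads themselves are never simulated.

- **Allele counts.** At a somatic site on `m` of `M` tumor copies with purity
  ρ, the expected tumor allele fraction is `f = ρ·m / (ρ·M + 2(1−ρ))` (mutated
  copies default `m = 1`). Tumor alt reads are Binomial(depth, `f(1−e) + (1−f)e`)
  with per-base error `e` (default 1e-3, a typical Illumina substitution
  rate); matched-normal alt reads are Binomial(depth, `e`) at somatic sites
  and Binomial(depth, 0.5) at germline heterozygous sites. Per-site depths
  are Poisson around the configured mean, scaled by the local planted copy
  state in the tumor.
- **Mutation placement.** In *category mode*, per-gene per-category counts are
  Poisson with mean `rate_c × bases_{g,c}`, where a gene's available bases per
  category follow its configured composition over three site classes (A/T,
  CpG, other C/G; defaults 0.50/0.05/0.45). Default rates total ≈2
  mutations/Mb with CpG transitions tenfold elevated. In *signature mode*,
  the per-sample burden is Poisson(sum of signature weights) and each
  mutation's 96-channel is drawn from the sample's signature mixture.
  Per-sample signature proportions are Dirichlet-distributed around the
  configured weights (concentration 1.0 by default): tumors genuinely vary in
  signature activity, and that variation is exactly what makes the
  factorization identifiable, so a generator with frozen proportions would
  test an unidentifiable regime.
- **Strand.** Channels are defined on the pyrimidine strand; half of all
  planted substitutions are stored as observed on the purine strand so the
  classification code path is exercised.
- **Purity** defaults to 0.7, a typical resected-sarcoma estimate; it is a
  free parameter, not an inference.
- **Multi-region tumors** get exact trunk/shared/private splits (counts are
  requested, not sampled); shared subsets must be proper subsets of size ≥ 2.

What the generator does *not* emulate: read-level artifacts (mapping error,
strand bias — summarized instead as per-site filter-survival fractions),
subclonal allele-fraction continua (region membership is discrete), indel
error models, and realistic genome composition (contexts are assigned, not
read from sequence; a small FASTA writer exists for I/O testing). Passing
tests therefore demonstrate the statistical machinery is correct under its
stated model, not that the caller is robust to alignment artifacts.

## Variant calling

The cascade applies read-evidence filters, a one-sided Fisher exact test of
alt enrichment in tumor versus normal (the 2×2 table of alt/ref by
tumor/normal; one-sided because the somatic alternative is directional),
support thresholds, known-SNP/synonymous exclusion, and — without a matched
normal — rejection of copy-neutral calls with VAF in the closed band
[0.45, 0.55] unless whitelisted. Flags accumulate rather than short-circuit,
so flag content is order-independent; a call is accepted iff unflagged.
Defaults (p < 0.01, t_alt ≥ 4, VAF ≥ 0.05, normal VAF ≤ 0.02, filter-survival
≥ 0.5) are conventional somatic-calling settings, configurable. The
per-read mismatch/mapping-quality filters cannot be applied literally without
reads; the per-site survival fractions are a documented surrogate.

At depth 100 the diploid germline band captures only
P(45 ≤ Binom(100, 0.5) ≤ 55) ≈ 0.73 of heterozygous sites — an intrinsic
limit of the band heuristic; the ≥ 90% regime needs depth ≈ 400. Tests
assert the exact binomial mass at depth 100 and the ≥ 0.9 property at 400.

## Copy number

Log2 depth ratios are computed on a shared bin grid after library-size
normalization; zero-depth bins are dropped and counted. Circular binary
segmentation maximizes the two-sample t statistic over all arcs of the
circularized bin sequence (every arc or its complement is a contiguous
window, so a window scan covers all splits; the variance term is the fixed
segment-wide variance, which is permutation-invariant). A split is accepted
when its permutation p-value is below α; recursion continues on the pieces,
and adjacent segments closer than `merge_tol` in mean are re-merged.
Defaults (α = 0.01, 1000 permutations, minimum 3 bins, merge_tol 0.1) follow
common DNAcopy practice. Permutations stop early once enough exceedances
guarantee the split will be refused. Because the scan is quadratic in bin
count, the pipeline aggregates fine pileup grids to ≤ 500 bins per chromosome
before segmenting.

Discrete states use log2 cutoffs (amp ≥ 0.9, gain ≥ 0.2, loss ≤ −0.2,
homdel ≤ −1.0 — invented, configurable defaults). Cohort recurrence is a
deliberately simplified marker-level G-score: the cohort sum of positive
(negative) amplitudes per marker, tested against a null that circularly rolls
each sample's whole-genome profile and pools permuted scores over markers,
with Benjamini–Hochberg q-values. No peak deconvolution or arm/focal
separation is attempted, and only marker-level scores and frequencies are
claimed. Mutation opportunity per 96-channel is Σ over segments of
copies × context count, copies = round(2·2^mean_log2) floored at zero, with
the three alternate bases of a context sharing its opportunity.

## Driver genes and pathways

Each mutation maps to one of seven categories: A/T transitions, A/T
transversions, CpG transitions, CpG transversions, other C/G transitions,
other C/G transversions, and indels (the C/G class split into transitions
and transversions yields the seven). The background rate of a category is
cohort mutation count over cohort available bases. A gene's expected
nonsynonymous burden is λ_g = Σ_c rate_c·bases_{g,c}·n_samples and its
p-value the Poisson upper tail P(X ≥ k_g); this is the minimal faithful
realization of "rate significantly above background", with an exact
convolution-of-binomials variant behind a flag for small-λ validation. BH
controls the FDR, significance at q < 0.05. Under a discrete, conservative
test the p-values are super-uniform rather than uniform, so calibration is
checked as P(p ≤ t) ≤ t (one-sided), not by a two-sided uniformity test.
The BMR includes all genes by default (candidate drivers excludable by
flag). The pathway test aggregates member genes' k and λ into one
cohort-level Poisson burden test per gene set — a simplification of
per-sample convolution approaches, so printed pathway p-values from richer
models are not comparable.

## Mutational signatures

Counts M[s,c] over 96 channels (COSMIC ordering, emitted in every output
header) are modelled as Poisson(O[s,c]·Σ_k e[s,k]·sig[k,c]) with per-sample
opportunity O. EM alternates mixture responsibilities, closed-form exposure
updates, and a simplex-constrained signature update which — because O varies
across channels — requires a one-dimensional Lagrange-multiplier root per
signature (solved by bracketed Brent iteration). The update sequence is a
conditional-maximization EM sweep, so the log-likelihood is non-decreasing;
tests assert this to 1e-8 relative. Defaults: relative tolerance 1e-6, up to
10,000 iterations, 10 Dirichlet-initialized restarts. The number of
signatures is chosen by BIC with S·(96−1) + n_samples·S parameters — a
transparent surrogate for evidence-based selection. Multiplying O by a
constant rescales exposures by its inverse and leaves fitted means unchanged
(tested). With flat opportunity the model reduces to Poisson NMF, and the
fit is verified to sit at a stationary point of the multiplicative KL update.

## Multi-region heterogeneity

Mutations present in all regions are *common*, in a proper subset of ≥ 2
*shared*, in exactly one region *private*. The presence matrix is the union
of per-region accepted calls; an optional rescue (off by default, matching a
validated-mutation analysis) marks presence when a region shows enough
supporting reads at adequate depth despite no call, guarding against
depth-driven false privacy. Clonal ordering nests region subsets by
inclusion under the deepest superset, trunk first; each region always ends
as a leaf (length zero without private mutations), branch lengths are
mutation counts and sum to the total. Subset pairs that overlap without
nesting cannot coexist on a tree; they are reported as conflicts and placed
greedily (larger subsets first, then descending count, ties by label) —
never fatally. Output is Newick with integer branch lengths.

## Numerical and testing choices

- Fisher p-values are vectorized hypergeometric survival probabilities,
  cross-checked against exhaustive exact-integer enumeration (to 1e-12 on all
  tables with total ≤ 30) and an independent library implementation.
- The CBS false-split check reads "rate ≤ α" statistically: the permutation
  test's exact size (9/1001 ≈ 0.009) cannot be certified from 50 Bernoulli
  trials, so the suite asserts the one-sided binomial-consistent bound of at
  most 3 false splits in 50 fixed-seed profiles.
- Problem sizes in tests and the acceptance script (two 2-Mb chromosomes,
  100-bp bins aggregated for segmentation, 8–30 samples, 10–50 segmentation
  seeds, 10^5-site null calling runs) were chosen as desk-scale stand-ins
  that keep every statistical check well-powered; per-base background rates
  are scaled up in the demo pipeline so per-sample mutation totals stay at
  realistic magnitudes over the shrunken footprint.
- One global seed is fanned out per stage through a stage-name-keyed
  SeedSequence, so stages are independently reproducible and reruns are
  byte-identical.

## Known limitations

Simplified recurrence scoring (no peak deconvolution); no allele-specific
copy number or UPD; no subclonal deconvolution from VAF clusters; no
covariate-adjusted background rates (expression, replication timing); no
fitting to reference signature catalogs — planted-signature recovery is
asserted, catalog identity is not; tumor-only calling inherits the germline
band's depth-dependent leakage quantified above.
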