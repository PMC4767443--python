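# somascape

Somatic-landscape analysis for tumor sequencing cohorts: Fisher-exact somatic
SNV/indel calling from tumor/normal allele counts, circular-binary-segmentation
copy-number analysis with cohort recurrence scoring, driver-gene discovery
against a seven-category background mutation rate, opportunity-aware
mutational-signature extraction by Poisson EM, and multi-region intra-tumor
heterogeneity analysis with clonal-ordering trees. A synthetic-cohort
generator with planted ground truth makes every stage testable end to end
without any external data.

The package is for method developers and analysts who want the statistical
core of a cancer-genomics pipeline as plain, inspectable, seedable Python —
starting from count tables rather than BAMs.

## The statistics in brief

- **Calling.** At each site the 2×2 table of alt/ref reads in tumor vs normal
  is tested one-sided by Fisher's exact test (alt enrichment in tumor);
  candidates then pass read-evidence, support, known-SNP and synonymous
  filters. Without a matched normal, copy-neutral calls with VAF in
  [0.45, 0.55] are removed unless whitelisted.
- **Copy number.** Per-bin log2 depth ratios are segmented by CBS (maximal
  two-sample t over all arcs of the circularized sequence, permutation-tested,
  recursive) and thresholded into states. Cohort recurrence at a marker is
  the G-score Σ over samples of positive (negative) amplitude, against a
  circular-permutation null with BH q-values.
- **Drivers.** Mutations are classified into seven categories (A/T
  transitions/transversions, CpG transitions/transversions, other C/G
  transitions/transversions, indels); per-category background rates are
  cohort counts over available bases, a gene's expected burden is
  λ_g = Σ_c rate_c·bases_{g,c}·n_samples, and significance is the Poisson
  tail P(X ≥ k_g) with BH correction. Pathways aggregate member-gene k and λ.
- **Signatures.** 96-channel counts follow
  M[s,c] ~ Poisson(O[s,c]·Σ_k e[s,k]·sig[k,c]) with per-sample copy-number
  opportunity O; signatures and exposures are fit by EM with a
  simplex-constrained signature update, and the number of signatures is
  chosen by BIC.
- **Heterogeneity.** Multi-region mutations are common / shared / private by
  region membership; clonal ordering nests region subsets by inclusion into a
  tree whose branch lengths are mutation counts (Newick output).

## Worked example

Three regions of one tumor, with a planted split of 13 trunk mutations,
2 mutations shared by regions T1+T2, and 7/12/8 private mutations:

```python
from somascape import simulate, heterogeneity as het

cfg = simulate.SimConfig(seed=1)
_, truth = simulate.simulate_multiregion(cfg, 3, trunk=13, shared=2, private=(7, 12, 8))
mat = truth.region_assignment.set_index(["chrom", "pos", "ref", "alt"]).astype(bool)

labels, counts = het.classify(mat)
print(counts, f"{het.percent_common(mat)}% common")
print(het.clonal_ordering_tree(mat).newick())
```

prints

```
{'common': 13, 'shared': 2, 'private': 27} 31% common
((T2:12,T1:7):2,T3:8):13;
```

— 13 of 42 mutations (31%) are detectable in all three regions; the tree
carries the 13 trunk mutations, a length-2 internal branch for the T1+T2
clade, and terminal branches of 7, 12 and 8.

The full pipeline (simulate → call → copy number → drivers → pathways →
signatures → heterogeneity, with figures and a JSON report) runs as

```sh
somascape run-all --seed 1 --out-dir demo_out
```

and each stage is also available as its own subcommand (`simulate`, `call`,
`cna`, `smg`, `pathway`, `signatures`, `het`) over the TSV/VCF/SEG/GMT files
the pipeline writes.

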