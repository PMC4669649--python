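# Methods

## Data model and notation

A panel holds, for each of `S` SNPs and `n` cohort samples, a raw intensity
pair `x_is = (r_is, g_is)` with `r, g ≥ 0`; red measures allele A, green
allele B, and B denotes the less common allele, so cluster 1 is the major
homozygote AA, cluster 2 the heterozygote AB and cluster 3 the minor
homozygote BB. A subset `M` of `n_a ≤ n` samples carries known genotypes
(possibly with missing entries); each of its identifiers matches exactly
one cohort sample by string equality.

## Stage I: cluster estimation from known genotypes

1. **Split.** The known samples are partitioned at ratio `p:q` with
   `|training| = ceil(n_a·p/(p+q))` — the only rounding rule consistent
   with the designs the method was built around (141 samples → 94/47 at
   2:1 and 71/70 at 1:1). Membership is a uniform permutation under the
   run seed.
2. **Classification.** At each SNP the non-missing training genotypes are
   counted. The SNP is G1 when all three genotypes appear with ≥ 3
   training samples each; otherwise G2. Three is the minimum count that
   leaves a covariance estimable with a degree of freedom to spare.
3. **Reference search (G2 only).** Candidates are the `R` nearest G1 SNPs
   by row index (array order stands in for genomic adjacency since the
   panel carries no coordinates; ties at equal index distance go to the
   lower index). Default `R = 100`, configurable — large enough to find a
   well-behaved probe nearby, small enough to avoid a genome-wide search.
4. **Reference selection.** Intensities are projected to the contrast
   coordinate `b = (r − g)/(r + g)` (undefined at `r + g = 0`, in which
   case the sample is dropped from the distance sums for all candidates
   symmetrically). The chosen reference minimises
   `d(r) = sqrt(Σ_h (b_hs − b_hr)²/s_h²)` over training samples `h`. The
   per-sample scale `s_h` is the standard deviation of sample `h`'s
   projections across the target and all candidates; a zero scale falls
   back to the pooled standard deviation of the whole projection block,
   and if that is also zero the sample is dropped. A literal two-point
   standard deviation of `(b_hs, b_hr)` would make every summand a
   constant, so the across-SNP spread is the only non-degenerate reading.
   Equal minima resolve to the candidate nearest in array order.
5. **Moments.** Cluster means and covariances are the per-genotype sample
   mean and sample covariance (divisor `count − 1`) of the training rows —
   pooled target + reference rows for G2 targets. Near-singular
   covariances (smaller eigenvalue below 1e-10 of the larger, e.g. from
   near-identical QC replicates) are nudged by `1e-6 · (trace/2) · I`
   (plain `1e-6 · I` at zero trace).

## Stage II: augmented-mixture calling

For each SNP, `m` subjects are drawn from the Stage-I model, exactly `m/3`
per cluster; `m` must be divisible by 3 and is rejected otherwise rather
than rounded. Equal per-cluster counts mean the augmentation adds the same
mass to every component and cannot change which *observed* homozygote
cluster is the larger one. The observed cohort plus the simulated block
(size `n* = n + m`) is fitted with a three-component bivariate Gaussian
mixture by EM:

* initialisation: Stage-I means/covariances, uniform weights `π = 1/3` —
  the clusters estimated from known genotypes are precisely the prior
  information the method exists to exploit;
* E-step: posterior responsibilities from the current weights and normal
  densities (log-domain, Cholesky factorisation);
* M-step: responsibility-weighted means and covariances; the weight update
  `π_k = N_k/n*` is the standard multinomial maximiser paired with these
  updates;
* convergence: relative log-likelihood change below `em_tol` (default
  1e-8), cap `em_max_iter = 500`; covariances re-regularised each
  iteration;
* collapse: if a component's effective weight `N_k` falls below 1e-8 the
  fit stops, is flagged unconverged, and the responsibilities from the
  last E-step (at the Stage-I initialisation on the first iteration) stand
  in for calling. This is deliberate: an empty minor-homozygote component
  on an unaugmented rare SNP still yields sensible Stage-I-based calls.

**Scoring.** Every augmented subject is hard-assigned to its max-posterior
component (exact ties to the lower index); its posterior rate PR is that
posterior. The average posterior rate APR is the mean PR over all `n*`
augmented subjects — the formula sums over cluster members and divides by
the summed cluster sizes, which is that mean — and an observed-only APR is
also reported in the per-SNP table since users may want the quality of the
real samples alone. The SNP passes only if (augmented) APR > 0.85; on a
pass, subjects with PR < 0.85 get NoCall (the null component is a
posterior threshold, not a fourth density: the mixture is written with
exactly three components). Components map to genotypes by ordering the
fitted means on `b(μ)`: largest → AA, middle → AB, smallest → BB, exact
ties broken by component index and flagged.

Both thresholds default to 0.85, the customary posterior cutoff for
array callers, and are configurable.

## Evaluation statistics

* call rate = called / attempted;
* concordance = agreement over jointly called positions (NA when none);
  accuracy is concordance against truth;
* MAF = `min(f_B, 1 − f_B)` with `f_B = (n_AB + 2 n_BB)/(2 n_called)`;
* HWE: 1-df chi-square goodness of fit against `(p², 2pq, q²)` with `p`
  estimated from the counts; zero-expectation cells contribute nothing and
  a monomorphic SNP is in exact equilibrium (χ² = 0, p = 1). An exact test
  is out of scope. The failure threshold α defaults to 1e-4 and is
  configurable; per-population stratification is supported through a
  sample → population map.
* MAF-stratified reports use cutoffs 0.1 / 0.05 / 0.01 by default, with
  MAF computed from the truth genotypes.

## Synthetic panels

The generator draws, per SNP, genotypes under Hardy-Weinberg equilibrium
at a configurable MAF and intensities from that genotype's bivariate
normal cluster. Defaults: AA mean (4000, 500), AB (2250, 2250), BB
(500, 4000), diagonal covariance with sd 200 — contrast values near
+0.78 / 0 / −0.78, typical two-channel geometry. Per-SNP cluster means are
perturbed by multiplicative lognormal jitter (log-sd 0.05) to emulate the
probe-to-probe variation that motivates reference borrowing; draws are
truncated at zero; known-genotype entries are blanked at rate 0.02 to
exercise missing-data paths. The rare-SNP fixture interleaves rare targets
(MAF ≤ 0.01) with a MAF-0.5 backbone so every target has a G1 reference
within a two-SNP window.

The generator reproduces only what the calling model assumes: it has no
scanner artifacts, no bead-level replication, no batch effects, no
intensity-dependent or heavy-tailed noise, and no correlation between
SNPs. Passing tests therefore demonstrate correctness of the algorithm
under its own model, not performance on real array data, where cluster
overlap and asymmetric noise make both accuracy and call rate lower.

## Problem sizes and what the checks show

The test suite and the acceptance script run at desk scale: the easy
end-to-end panel is 500 samples × 20 SNPs with `m = 600`; the rare-SNP
comparison uses paired panels (identical data, `m = 3000` vs `m = 0`) of
300 samples with two MAF-0.005 targets each, 60 known samples, repeated
across seeds. On this clean generator both arms call the few heterozygotes
correctly and the augmentation benefit shows up as EM convergence and
component stability (the unaugmented fits collapse on every rare SNP)
rather than as an accuracy gap — consistent with the directional
expectation that augmented accuracy is at least the unaugmented one.

## Known limitations

* Reference candidates come from array order only; probe-sequence
  similarity is not used.
* No joint calling across SNPs (no LD information) and no batch-effect
  normalisation of intensities.
* The HWE test is asymptotic; at very small expected counts an exact test
  would be preferable.
* Vendor binary formats (IDAT, GenomeStudio projects) are not parsed;
  inputs are plain TSV.
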