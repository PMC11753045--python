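# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `methcanyon`.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

A methylome is a table of CpG sites `(chrom, pos, coverage, meth_count)`
with `ratio = meth_count / coverage` (undefined at zero coverage).  `pos`
addresses the C of the CG dinucleotide on the forward strand; both strands
are assumed pre-merged by the upstream quantifier, and no second merge is
attempted.  All interval logic is 0-based half-open; a CpG-run interval
ends at `last_pos + 2` to cover the final dinucleotide.  Sites with
coverage below 4 reads are dropped on input (`min_coverage=4`), the
standard floor for per-CpG ratio estimates.  Region means are unweighted
across CpGs — every covered CpG contributes equally regardless of depth —
and regions with no covered CpG propagate as missing and are excluded
pairwise from downstream tests (drop counts are logged).  The X chromosome
is removed before all cohort-level analyses to avoid X-inactivation
artifacts in mixed-sex cohorts.

## Canyon calling

UMRs are segmented per sample by a two-state HMM over the ordered CpGs of
each chromosome.  Emissions are Beta-Binomial on the raw counts,
`k | n, s ~ BB(n, mu_s * kappa, (1 - mu_s) * kappa)`, which weights
high-coverage sites more strongly than a ratio-based emission would.
Defaults (all exposed on `HmmParams`):

| parameter | default | rationale |
|---|---|---|
| `mu_umr` | 0.03 | near-zero canyon methylation |
| `mu_bg` | 0.70 | typical open-sea somatic methylation |
| `kappa` | 20 | tolerant of biological noise around state means |
| `p_stay_umr` | 0.99 | expected UMR dwell ~100 CpGs |
| `p_stay_bg` | 0.999 | UMRs are rare relative to background |
| `min_cpgs` | 10 | suppresses single-site artifacts; mirrors the DMR CpG floor |

The initial distribution is the stationary distribution of the transition
chain.  Decoding is Viterbi in log space with ties broken toward the
background state (deterministic); a posterior-threshold decoder
(forward–backward, `P(UMR) >= 0.9`) is available but off by default.
Decoded runs with ≥ `min_cpgs` CpGs and mean ratio < 0.1 are emitted as
UMRs.  The Viterbi implementation is verified against exhaustive
enumeration of all 2^12 state paths on 12-CpG instances.

Merging is a left-to-right single pass: a neighbour within 500 bp is
provisionally merged and the mean is **recomputed over every covered CpG
in the union span, including the gap**; the merge is kept iff that mean is
≤ 0.1.  Chains merge transitively and the operation is idempotent.  Where
the thresholds' strictness is stated inconsistently in common usage
(≤ vs <), we fix: merge mean ≤ 0.1, canyon length ≥ 3,500 bp, canyon mean
< 0.1 — all configurable.

Group consensus union-merges canyon intervals across samples and retains a
merged interval when at least `ceil(0.5 * n_samples)` samples contribute an
overlapping canyon; for odd group sizes this keeps strict majorities.
Support is overlap-based (≥ 1 bp), not reciprocal-fraction-based.  Unique
vs shared canyons between two consensus sets are likewise defined by ≥ 1 bp
overlap, and canyons are annotated to every gene they overlap by ≥ 1 bp.

## Differential methylation

The Mann–Whitney U test uses exact null enumeration for combined n ≤ 12
without ties and the tie-corrected normal approximation with continuity
correction otherwise; identical pooled values short-circuit to p = 1.  In
matrix form (positions, promoters) the same selection rule is applied
row-wise via the vectorized scipy backend.

De novo segmentation operates on the per-site difference of group means.
Sites are split into runs at inter-CpG gaps > 300 bp (coverage deserts
should not be bridged by a single region); within a run, the sub-interval
maximizing `|mean d| * sqrt(L)` (equivalently `|S_j - S_i| / sqrt(j - i)`
on prefix sums) is chosen recursively, flanks are re-segmented, and the
candidates are pairwise disjoint by construction.  This is a deliberately
simple recursive binary segmentation, not a re-implementation of any
specific segmentation tool; the contract is the filter-and-test structure:
candidates need ≥ 10 CpGs and |Δ| ≥ 0.1 and must pass BOTH the
Mann–Whitney U test on per-sample region means AND the two-sample 2-D
Kolmogorov–Smirnov test, each BH-adjusted over candidates, at p < 0.05.

The 2-D KS statistic follows the Fasano–Franceschini construction: D is
the maximum over all data points of both samples, and over the four
quadrant orientations anchored at that point (split `(<=, >)` per axis),
of |F_a − F_b|.  The p-value uses the Kolmogorov tail of
`sqrt(n_eff) D / (1 + sqrt(1 - r^2)(0.25 - 0.75 / sqrt(n_eff)))` with
`n_eff = n_a n_b / (n_a + n_b)` and r the mean within-sample Pearson
correlation.  The approximation is coarse for very small point sets; it is
used as a region filter, never as a calibrated tail probability.

Positions use Bonferroni control (familywise, conservative); regions and
promoters use Benjamini–Hochberg.  The pre-defined promoter mode defaults
to `min_delta=0` — significance alone decides — because promoter-level
effect sizes below 0.1 are still reportable there; the filter is exposed.

## Cross-platform promoter comparison

Order of operations: probe intersection (exact `(chrom, pos)` match) →
joint quantile normalization of both cohorts stacked into one matrix →
contrast-score symmetry diagnostic (reported, not gating) → promoter
averaging over 1.5-kb TSS windows → |Δ| > 0.1 (strict) → IQR quartile
filter → Wilcoxon rank-sum per surviving promoter → BH-FDR < 0.05
computed over the tested set.  A `test_all_then_filter` flag switches to
testing every promoter first.

Quantile normalization builds the reference as the mean of per-sample
sorted vectors over complete features; every sample's values are replaced
by the reference value at their rank, tied values receiving the mean of
the tied ranks' reference values, and samples with missing values are
mapped through linear interpolation of the reference at rank quantiles.
Joint normalization of both platforms is what justifies the method: any
monotone platform distortion (emulated in the simulator as a logistic
compression of beta values toward 0.5) is removed exactly in
distribution.

The quartile filter computes Q1/Q3 of the reference cohort's per-sample
promoter means with type-7 (linear interpolation) quantiles and passes a
promoter iff the test-cohort mean lies strictly outside [Q1, Q3].  The
1.5×IQR outlier fences are computed and reported (`within_fence`) but do
not gate, since the strict-quartile reading is the operative rule; both
bounds are surfaced so users can tighten if desired.

The contrast diagnostic scores each feature by the difference of cohort
means after normalization and flags the distribution symmetric when the
positive fraction lies in [0.45, 0.55] and |sample skewness| < 0.5 — a
quick check that the batch effect is gone, not an FDR procedure.

Swapping which cohort is "reference" changes the IQR filter's frame (its
quartiles come from the reference cohort by design), so the pipeline is
not exactly symmetric under cohort exchange; deltas and rank tests are.

The methylation–expression summary computes a Spearman correlation per
gene between promoter methylation and expression across shared samples
and reports the fraction of genes with a negative association; constant
vectors are excluded and counted.

## Annotation

Promoter windows are 1 kb upstream to 500 bp downstream of the TSS in
transcription orientation (1.5 kb total), clipped at position 0; one TSS
per gene is taken as given — no isoform-aware merging.  Island context is
assigned by distance to the nearest island base: island inside; shore at
1–1,999 bp; shelf at 2,000–3,999 bp; open sea beyond — the universal 2-kb /
2–4-kb convention, with the boundary fixed so that a position exactly
2,000 bp outside an edge is a shelf (unit-tested).  Gene-context labels
use precedence promoter > 5'UTR > exon > 3'UTR > intron > intergenic, so
every region gets exactly one label; promoter-first matches the analytic
focus on promoters.  The CIMP marker panel is the canonical six genes
(RUNX3, IGF2, SOCS1, CACNA1G, MLH1, NEUROG1); the marker check BH-adjusts
the six Mann–Whitney p-values across the panel before flagging, so the
"no marker differs" outcome has a calibrated familywise meaning at small
group sizes.

Gene-set overrepresentation is the one-sided hypergeometric tail with a
user-supplied universe; the default universe in pipeline runs is all genes
with a promoter in the annotation.  The universe changes p-values
materially and is therefore always an explicit parameter.  BH adjustment
is per collection.

## The synthetic-cohort generator

The generator emulates the data regime of a 25×-coverage tumor/normal
WGBS study with an added array cohort; its defaults are the study
conditions, not tuning knobs.

* **CpG spacing**: exponential gaps (Poisson process) at 100 bp mean,
  5× denser inside islands, so island/shore/shelf/open-sea classes are
  non-degenerate.
* **Coverage**: negative binomial, mean 25, dispersion 0.2 (moderate
  overdispersion typical of WGBS).
* **Counts**: Beta-Binomial around the local mean with precision 30;
  at infinite precision the count degenerates to `round(coverage * mu)`
  (deterministic limit used in degenerate-case tests).
* **Local means**: open sea 0.75; islands 0.15; tumor groups get −0.10
  global background (hypomethylation) and +0.25 at islands
  (hypermethylation); planted canyons sit at 0.02 with a 200-bp linear
  border ramp so boundary-recovery error is measurable rather than
  trivially zero; planted promoter effects override the window's CpGs.
* **Cohort design**: default 7 normal vs 9 tumor WGBS samples and an
  optional 18-sample array cohort observing ~2% of CpGs (a few probes per
  promoter plus random background — promoter-enriched like a 450K
  design), with an optional monotone logistic beta compression as the
  batch shift.
* **Truth**: canyons (with per-group presence), DMP sites and promoter
  effects are recorded in a `TruthSet`; planted intervals are placed in
  disjoint slots and never overlap within a chromosome.

Six simulated genes carry the CIMP marker names so the panel check runs
end-to-end on synthetic data.

What the generator does **not** model: read-level artifacts (bisulfite
conversion error, mapping bias), FFPE degradation, copy-number aberration,
tumor purity and subclonality, spatially correlated methylation noise, or
realistic repeat-family structure.  Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated count model,
not performance on degraded clinical material.

## Problem sizes and reproducibility

The canyon-recovery experiment uses 6 samples on a 5-Mb single-chromosome
genome with 20 planted canyons; the cross-platform experiment uses 5,000
promoters over a 50-Mb five-chromosome genome with 100 planted effects at
Δ = 0.3 and cohorts of 9 vs 18; error-control simulations use 10,000
sites / 2,000 promoters × 20 seeds.  These sizes make every experiment
rerunnable on a laptop core in minutes while keeping estimator variance
small relative to the property margins.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning — annotation, truth, each sample and the array cohort get
independent child streams — so regeneration is bit-identical and stages
can be rerun in isolation.  `run_all` writes every stage's tables before
the next stage begins and a manifest with the seed, all parameters and
per-stage counts; two runs with the same configuration are byte-identical
(the output directory itself is excluded from the manifest).

## Known limitations

* The HMM parameterization is fixed rather than estimated (no Baum–Welch);
  cohorts with unusual global methylation levels may need `mu_bg` adjusted.
* The de novo segmentation is a simplified recursive scheme; region
  boundaries may differ from dedicated segmentation tools even when the
  same regions are detected.
* The 2-D KS p-value is a large-sample approximation.
* Pre-defined-region tests reduce each sample to one region mean,
  discarding within-region heterogeneity.
* The IQR filter makes the cross-platform pipeline asymmetric in the
  reference cohort by construction.
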