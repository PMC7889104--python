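# Methods

This note documents the statistical models, the synthetic-data generating
process, the numerical choices and the known limitations of `methcord`.

## Design and data model

The unit of analysis is a matched two-tissue design: n subjects, each with
one bone and one blood sample collected at the same time, measured on a
methylation array. Matching is what licenses the within-subject analyses:
correlating the two tissues *across subjects at one site* removes
between-subject genetic confounding that plagues unmatched tissue
comparisons, and the paired structure gives the permutation null its
exchangeability. The sample sheet must contain exactly one sample per
subject per tissue, and at least 3 subjects (the correlation t-test needs
n − 2 ≥ 1 df; in practice n ≈ 12 is the scale the defaults target).

Methylation is carried in two exchangeable domains: β = m/(m+u+α)
(proportion scale, interpretable, bounded) and M = log2((m+α)/(u+α))
(log-ratio scale, approximately homoscedastic, used for every model fit).
The offset α (default 100, intensity units) regularizes low-intensity
probes; the logit2 bridge M = log2(β/(1−β)) is the exact link only at
α = 0. The distortion of the bridge is log2((c+α)/c) for the weaker
channel c, so it is negligible only when *both* channels dominate α —
with both channels ≥ 1000 and α = 100 it is at most log2(1.1) ≈ 0.14
M-units.

## Quality control

- **Detection filter**: a probe is excluded if its detection p-value
  exceeds the threshold (default 0.01) in *any* sample. The per-sample
  p-values are consumed, not computed: computing them needs
  negative-control probes that the data model does not carry. The
  any-sample rule is the most conservative aggregation; with ~24 samples
  it matches the intuition that one failed measurement disqualifies a site
  from paired analysis.
- **SNP filter**: probes flagged as overlapping a polymorphism are removed;
  at such sites the signal confounds methylation with genotype.
- **Sample-level QC** is reported (per-sample channel medians in the QC
  JSON) but never applied automatically — no defensible universal
  threshold exists, so exclusion is left to the analyst.
- Sex chromosomes receive no special handling (appropriate for single-sex
  cohorts; mixed-sex users should filter upstream).

## Batch correction

`batch_correct` is a parametric empirical-Bayes location/scale adjustment
on M-values, in the ComBat family. Per site: fit batch means plus a
protected, centered tissue covariate by OLS; standardize by the pooled
residual SD; estimate per-batch location γ̂ and scale δ̂² of the
standardized residuals; shrink γ̂ toward a normal prior and δ̂² toward an
inverse-gamma prior, both moments-matched across sites; adjust
(z − γ*)/δ* and restore the site mean and tissue effect.

Numerical choices:

- **Iteration-free posterior**: δ²* is the inverse-gamma posterior mode
  given the γ̂-centered residuals, then γ* is the normal posterior mean
  using δ²*. The classical implementation iterates these two to a fixed
  point; one pass changes third-decimal details only, so exact numerical
  parity with any specific implementation is not claimed.
- **Exact mean preservation**: after adjustment each site is re-centered
  so its overall mean is unchanged. Shrinkage alone leaves a residue of
  order (γ̂ − γ*)/n; re-centering removes it without touching batch
  contrasts.
- **Degenerate inputs**: a single batch returns the input unchanged
  (logged); a batch with fewer than 2 samples is an error; when the scale
  estimates have no spread across sites (e.g. noiseless data) the scale
  adjustment is skipped rather than dividing by a degenerate prior; the
  pooled SD is floored at 1e-8.

Tissue is included in the standardization model precisely so that the
biological contrast of interest is not absorbed into the batch estimate —
with both tissues of a subject always on one chip, tissue and batch are
never confounded by design.

## DMP calling

Step 1 fits, per site, an OLS model of M on the group-mean tissue coding
(bone, blood indicator columns) plus centered age, and tests the
bone − blood contrast. Age is always a covariate and never the contrast;
a constant age column is dropped with a warning. The residual variances
s² (d = n_samples − rank df each) are shrunk across sites: with the
working model s² | σ² ~ σ²χ²_d/d and 1/σ² ~ χ²_{d₀}/(d₀s₀²), the
marginal of log s² is a location-shifted log-F, so matching its sample
mean and variance via digamma/trigamma gives closed-form (d₀, s₀²)
estimates (the trigamma inverse is a Newton iteration; d₀ above 1e7 is
reported as infinite, in which case all posterior variances equal s₀²).
The moderated t uses s̃² = (d₀s₀² + d·s²)/(d₀ + d) on d + d₀ df,
two-sided. This reproduces the standard empirical-Bayes moderated-t
methodology; the test suite verifies parity with the Bioconductor
reference implementation to ~1e-8 on a shared fixture.

Step 2 keeps only sites with |mean over subjects of (β_bone − β_blood)|
above the threshold (default 0.2). The *signed* mean is deliberate:
opposite-direction pair differences cancel, so only consistent tissue
shifts qualify. Direction labels (hypo/hyper in bone relative to blood)
come from the sign of the M-difference.

A classical paired t-test on per-subject M-differences (df = n − 1) is
provided as a cross-check route; on data without age effects the two
routes call identical DMP sets (verified on synthetic data), because with
a balanced paired design the tissue contrast estimate is the mean paired
difference in both parametrizations.

Multiple testing uses Benjamini–Hochberg throughout (step-up, q capped at
1, ties sharing a q); NaN p-values propagate to NaN q with a warning.

## SMP calling

Candidates are the probes *not* significant at the DMP stage (q ≥ 0.05).
This both focuses the test on potentially concordant sites and makes the
DMP/SMP call sets disjoint by construction. Per candidate site the
n-vector of bone M-values is correlated with the subject-aligned blood
vector (Pearson); t = r√(n−2)/√(1−r²) on n − 2 df, two-sided; BH within
the candidate set. Two similarity filters are implemented: the per-pair
maximum |Δβ| < 0.2 (default — the strictest reading of "every pair
similar") and the mean-of-pairs variant (config-switchable; the choice is
logged). An SMP additionally requires r > 0: an anti-correlated site
passes a two-sided test but is not "similar". Zero-variance sites yield
r = NaN and are excluded from testing with a logged count; |r| = 1 maps
to p = 0 by convention.

At n = 12, the q < 0.05 cut lands at roughly r ≈ 0.74 — any reported
lower bound on the correlation of called sites is an emergent consequence
of the FDR cut at that sample size, not an input parameter.

## Permutation null

Each iteration draws a uniform random permutation of the blood samples'
subject labels (bone fixed; the identity is an allowed draw — derangements
are deliberately not enforced, as the null is plain exchangeability),
recomputes r, the correlation p-values, BH *within the iteration*, and the
Δβ filter against the permuted pairing, and records the count of sites
passing the full selection. Recomputing BH inside each iteration matters:
the null must mimic the entire selection procedure, not just the per-site
test. The empirical p is (1 + #{null ≥ observed})/(iterations + 1), so its
floor is 1/(iterations + 1). The default is 10,000 iterations; the
acceptance checks use 1,000, which already resolves p down to ~0.001.

## Enrichment

Region enrichment reports, per genomic-feature class (TSS200, TSS1500,
5'UTR, 1st exon, body, 3'UTR, intergenic) and per CpG-island class
(island, N/S shore, N/S shelf, open sea), n_hits/n_array — the fraction of
the class's probes that were called — so classes of very different sizes
are comparable. A probe with several feature annotations (gene isoforms)
counts once in each class; feature hits therefore sum to more than the
number of calls, and this is intentional.

Locus overlap treats an externally supplied gene list as the catalog: a
locus is represented iff at least one called site is annotated to it
(case-insensitive symbol match; no coordinate-window extension). Incidences
(site × locus) and unique sites are both reported, since a site annotated
to two catalog genes is genuinely ambiguous between the two conventions.

Gene-set over-representation is the plain hypergeometric upper tail on
gene counts, with the universe restricted to genes annotated to the
candidate probes and every set intersected with that universe first. No
correction for the number of probes per gene is applied (the
probe-number-bias adjustment of dedicated methylation gene-set tools is
out of scope), and no multiple-testing correction is applied across sets;
the p-values are labelled plain hypergeometric and should be read as
rankings.

## Synthetic data generator

The generator is the package's test bed and defines the study conditions
the acceptance checks run under. It emulates:

- **Design**: n_subjects = 12 matched pairs, ages Uniform(66, 85) per
  subject, two batches with subjects split as evenly as possible and both
  samples of a subject always sharing a batch (so batch never confounds
  the within-pair contrast).
- **Baseline levels**: per-site baseline M from a three-component normal
  mixture — hypo (weight 0.32, mean −3.5, SD 0.8), intermediate (0.22, 0,
  1.2), hyper (0.46, +3.5, 0.8) — giving the bimodal β landscape of real
  arrays, with β strictly inside (0, 1) via the logistic map.
- **SMP sites** (frac_smp = 0.1): a subject effect u_j ~ N(0,
  smp_subject_sd²), default SD 1.0 M-units, added to both tissues of
  subject j, plus N(0, noise_sd²) per sample (default 0.25). The implied
  within-subject cross-tissue correlation is the intraclass correlation
  smp_subject_sd²/(smp_subject_sd² + noise_sd²) ≈ 0.94 at the defaults —
  strong but not degenerate concordance.
- **DMP sites** (frac_dmp = 0.1): a constant M offset on bone, sized per
  site so the β-scale shift equals dmp_delta_beta (default 0.4). The sign
  is chosen toward the feasible side at extreme baselines (random where
  both fit); a configuration whose shift fits neither side raises a config
  error naming the class. The realized mean paired Δβ tracks the target
  within ±0.03 at n = 12 and ≥ 500 sites (Jensen effects of the M-scale
  noise stay below that at the default noise level).
- **Null sites**: independent noise only.
- **Batch effect**: batch_shift (default 0.5 M-units) added to every
  sample outside the first batch. Because it hits both tissues of the
  affected subjects equally, an uncorrected batch effect masquerades as
  within-subject concordance — on all-null data it inflates the mean
  cross-tissue r to ≈ 0.5. This is exactly why the pipeline batch-corrects
  before any correlation, and the all-null calibration checks run through
  the correction step.
- **Detection failures**: each (site, sample) cell fails independently
  with probability 2e-4, drawing p ~ Uniform(0.011, 1) (else
  Uniform(0, 0.009)); with 24 samples this fails ~0.5% of probes under the
  any-sample rule, the order of magnitude seen in practice.
- **SNP flags**: 3.4% of sites, independent of class (as the fraction of
  array probes removed for SNP overlap typically is).
- **Intensities** (optional): total signal T ~ LogNormal(log 5000, 0.3),
  m = Tβ, u = T(1−β), so the intensity path recovers β up to the
  α/(T+α) shrink.
- **Age** has zero true effect by default; age_slope_sd plants per-site
  slopes to exercise covariate adjustment.

What the generator does **not** model: probe type I/II chemistry, dye
bias, spatial chip artifacts, cell-type composition, co-methylation blocks
(sites are independent given the design), or any realistic genomic
correlation in the annotation (feature and island classes are drawn
independently per probe). Passing recovery tests therefore demonstrates
that the statistical machinery is correct under its stated model — not
that real-array artifacts are handled.

## Problem sizes and determinism

The test and acceptance runs use 2,000–5,000 sites, 12 subjects, 20
replicates for null calibration, 1,000 permutation iterations and 50,000
sites for hyperparameter recovery — sizes at which every Monte-Carlo
tolerance in the suite is comfortably stable while the whole suite runs in
well under a minute. All randomness flows through
`numpy.random.default_rng` seeds carried in configs or arguments; equal
configs give bit-identical datasets, and the permutation result is
bit-reproducible under a fixed seed.

## Known limitations

- No IDAT parsing or array-manifest handling: inputs are plain-text
  matrices already at the intensity or β/M level, and background
  correction methods that need out-of-band channel data are out of scope.
- The batch adjustment is a one-pass empirical-Bayes variant (see above).
- The hypergeometric gene-set test ignores probe-number bias; gene-set
  p-values are comparative, not calibrated.
- Region/feature enrichment reports ratios, not tests; no confidence
  intervals are attached.
- With n = 12 pairs the correlation test has limited resolution; sites
  with true r below ~0.7 are largely undetectable at q < 0.05, which is a
  property of the design, not the implementation.
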