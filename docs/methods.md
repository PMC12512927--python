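# Methods

This note records the statistical models, the synthetic-data design, the
numerical choices, and the open design decisions behind `fibretype`, in the
spirit of a package's model documentation. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Study design being modelled

The package targets paired fibre-type studies: from each subject, one pool
of Type I (slow-twitch, MYH7-dominant) fibres, one pool of Type II
(fast-twitch, MYH2-dominant) fibres, and one whole-muscle (WM) sample, with
both sexes represented. Methylation is measured as Infinium-array beta
values (methylation fractions in [0, 1]); proteins as log2 label-free
quantification intensities. WM methylation is treated as a convex mixture
of the two fibre profiles plus, optionally, a non-fibre background
component — the assumption that makes reference-based deconvolution linear
on the beta scale.

## Preprocessing

* **Probe filtering** removes, in a fixed attribution order (detection
  p > 0.01 in any sample → bead count < 3 in any sample → non-CpG → sex
  chromosome → SNP-related → cross-reactive/underperforming), each probe
  counted once under the first rule it fails. Whether a single failing
  sample suffices is a policy parameter (`detection_policy`, default
  `"any"`), since either reading is defensible.
* **Normalization** is per-design-type quantile normalization of beta
  values: within each Infinium design type, every sample's distribution is
  mapped to the mean quantile profile (average-tie convention). This is a
  deliberate simplification of intensity-based probe-type normalization
  (Dasen and kin), which needs raw channel intensities this package does
  not ingest; the goal — removing design-type and between-array
  distributional bias — is the same, and the deviation is documented here
  and in the module docstring.
* **M-values**: tests run on M = log2(β/(1−β)) after clipping β into
  [eps, 1−eps], eps = 1e-3, bounding |M| ≤ ~10 (the practical array dynamic
  range) and making the transform exactly invertible on the clipped domain.
* EPICv2-style replicate probes (suffixed ids) are averaged per locus;
  positions are stored 1-based inclusive internally, exported BED is
  0-based half-open.

## Moderated differential testing

Per-feature linear models with empirical-Bayes variance moderation:
s̃² = (d0·s0² + df·s²)/(d0 + df), t̃ = effect/(s̃·c), referred to t with
d0 + df degrees of freedom. Hyperparameters are moment-matched on log
sample variances: the excess variance of log s² over trigamma(df/2)
determines d0 via a trigamma inverse (Newton iteration), and the mean
determines s0². Non-positive excess variance yields the "infinite prior"
sentinel (d0 capped at 1e6), i.e. complete pooling. Setting the prior df to
0 reproduces the classical t-test exactly, which the tests verify to 1e-10.

**Pairing.** Paired contrasts are resolved by within-subject differencing
and analysed as one-sample moderated tests. This replaces a REML consensus
correlation across duplicate measurements: for complete, balanced pairs the
two approaches estimate the same contrast, and differencing is exact,
simpler and directly testable. Incomplete subject blocks are dropped with a
warning and recorded in the results metadata. Covariates that are constant
within subject (sex) cancel in the differences; unpaired models carry them
as dummy-coded columns, and a binary interaction factor can be designated
as the tested effect.

Beta-scale effect sizes (Δβ) are obtained by applying the identical
contrast to the beta matrix; significance always comes from the M-scale
model. Constant feature rows get NA statistics and are excluded from the
BH denominator.

**Robust calls.** "Robust DMPs" are adjusted p < 0.001 with |Δβ| > 0.10;
"robust DEPs" adjusted p < 0.001 with |log2FC| > 1; both thresholds are
parameters.

## DMR calling

Regions are chains of CpGs individually significant at BH FDR 0.05,
sign-consistent in Δβ, with consecutive genomic gaps ≤ 1000 bp (the
`max_gap` analogue of a kernel bandwidth); chains of ≥ 2 CpGs become
regions, scored by Fisher's combination X² = −2Σln p of member raw
p-values against chi-square(2k). A region is "robust" when it has ≥ 4 CpGs
and Fisher P < 0.001. This gap-chaining construction replaces kernel
smoothing: it reproduces the robustness rule with transparent mechanics,
at the cost that Fisher's independence assumption is violated by local
methylation correlation — the combined p is therefore a ranking statistic,
not a calibrated error rate, and the caller's docstring says so. Probes
sharing a position are collapsed before chaining, so region members are
disjoint by construction.

## Reference matrix and deconvolution

Candidates are robust-effect CpGs (|Δβ| > 0.10) scored by
|Δβ| × (−log10 p_adj). The published ranking phrase ("beta logFC times
adjusted p-value") is ambiguous; this product is monotone in both effect
size and evidence and is exposed as a pluggable scoring choice. Adjusted
p-values are floored at 1e-300 before the log so underflowed values rank by
effect size instead of tying at infinity. The reference takes the top k/2
CpGs hypermethylated and k/2 hypomethylated in TI (balance enforced
structurally), profiled as arithmetic mean beta per fibre type — means of
beta, not M, because mixture linearity holds on the beta scale.

**RPC** (robust partial correlations): per sample, IRLS with Huber weights
(c = 1.345), scale re-estimated each iteration as 1.4826 × MAD of
residuals, intercept included, stopping when the coefficient change falls
below 1e-6 or after 100 iterations (non-convergence flags the sample);
negative cell-type coefficients truncated to zero, the remainder
renormalized to sum to one. A zero MAD (exact fit) terminates immediately.
These details are not fully specified in the deconvolution literature's
prose; the choices above follow the standard robust-regression defaults.

**CP** (constrained projection): for two cell types the least-squares
problem under w ≥ 0, Σw = 1 has the closed form
w = clip(⟨y − μ_TII, d⟩/‖d‖², 0, 1) with d = μ_TI − μ_TII. CP is the
independent oracle for RPC on clean data (tests require agreement to 1e-6
on noiseless mixtures, and both against a 0.001-step brute-force grid);
under outlier corruption the Huber weighting gives RPC the smaller
worst-case error, which the tests check as an ordering, not a magnitude.

Cross-platform use strips replicate suffixes before intersecting probe ids
and reports how many reference CpGs were dropped. Evaluation is Pearson r
and RMSE of estimated vs measured/simulated TI fractions; `sweep_k`
evaluates k ∈ {10, 20, 50, 100, 200, 1000} and breaks ties toward the
smallest k (parsimony).

## Proteomics

Filtering removes contaminants, decoys, and proteins observed in fewer
than 3 samples, read as "overall" rather than per group (a policy flag
offers the per-group variant). Median-centering subtracts each sample's
observed median (idempotent by construction). MNAR imputation is global —
one μ_obs/σ_obs for the whole matrix — drawing missing cells from
Normal(μ_obs − 1.8σ_obs, (0.3σ_obs)²); "width 0.3" is read in σ_obs units,
consistent with the shift also being in σ_obs units (the standard
downshift-and-width convention). Observed cells are never altered and the
imputation mask is carried into differential results (`n_imputed` per
protein) so heavily imputed proteins can be excluded in sensitivity
analyses. Differential expression reuses the moderated-t machinery on the
imputed log2 matrix.

Myosin isoform percentages use raw unique-peptide intensities (linear
scale), not normalized values, because the quantity is defined directly on
the quantifier's unique-intensity output; shared/razor peptides are
excluded to avoid cross-assignment. Percentages are scale-invariant per
sample and sum to 100 whenever the four-isoform grand total is positive; a
zero total flags the sample rather than erroring.

## Integration

Gene symbols are case-normalized; multi-gene probes ("A;B") contribute to
every named gene. The "top DMP" of a gene is its CpG with the smallest
adjusted p (ties toward larger |Δβ|) — a definition the source material
leaves open. Four methylation summaries (top CpG, gene mean, top robust
region, mean of robust regions) are correlated with protein log2FC by
Pearson r with df = n − 2. The beta scale (Δβ) is used for these effects by
default; the M-scale effect is available in the differential table for
anyone preferring it. Quadrant labels require significance in both layers
at adjusted p < 0.001 and classify by sign combination; counts always sum
to the number of links.

## Synthetic data

The generator is first-class, tested code. Defaults describe the study
conditions everything downstream is validated under:

| parameter | default | rationale |
|---|---|---|
| n_cpgs | 20,000 | enough for realistic FDR behaviour while keeping a full run in seconds |
| n_subjects | 12 | the paired-cohort scale of fibre-pool studies |
| n_dmp_true | 2,000 | placed in blocks of 4–8 adjacent CpGs (gaps 50–400 bp) so true regions exist; block signs split per `frac_hyper_in_TI` |
| delta_beta_range | (0.10, 0.40) | true effects start at the robust-call threshold |
| noise_precision | 624 | beta-distribution concentration; per-CpG SD ≈ 0.02 at β = 0.5, typical array noise |
| subject_sd_logit | 0.1 | per-subject random intercept on logit-beta, giving the paired structure something to remove |
| wm_other_fraction | 0 | core recovery tests are exact-support; non-zero values stress-test robustness against a uniform [0.2, 0.8] background profile |
| WM weights | w_TI ~ U(0.2, 0.8) | physiological spread of human vastus lateralis TI proportions; fixable via `wm_w_ti` |

Noise is beta-distributed around the true mean (concentration ν), keeping
observations in [0, 1] without clipping; ν = ∞ switches noise off, making
the WM mixture identity exact — the basis of several oracle tests. Sex
effects shift a disjoint set of CpGs in females only.

Protein tables get one TI and one TII sample per subject, true effects of
|log2FC| = 2 at 100 of 1,000 proteins, residual SD 0.3, and logistic MNAR
missingness (slope 0 degenerates to MCAR at the intercept rate, another
oracle). When the methylome truth is supplied, differential proteins are
the genes with the strongest true methylation differences, signed opposite
— emulating the canonical hypermethylation/down-regulation coupling so
integration has a known negative relationship to recover. Myosin peptide
intensities encode near-pure MYH7 composition for TI pools and
MYH2-dominant composition (with MYH1/MYH4 admixture) for TII pools, as
observed in real fibre pools.

**What the simulation does not emulate:** probe-specific biases and
spatially correlated noise, bimodal-boundary inflation at β ≈ 0 and 1,
batch effects, TIIx/hybrid fibres, peptide-level quantification error, and
a realistic non-fibre methylome (the uniform background is a stand-in, not
an estimate — the non-fibre nuclei profile is uncharacterised). Passing
tests therefore demonstrate correctness of the algorithms under the stated
generative model, not performance on any particular cohort.

## Numerical choices and degenerate inputs

* BH adjustment delegates to the standard step-up implementation with NA
  propagation (NAs excluded from the test count); a zero p-value in
  Fisher's combination warns and returns 0.
* Welch's test on identical constant groups returns (0, 0, 1) rather than
  NaN.
* Degenerate references (identical TI/TII profiles) and samples whose
  truncated coefficients are all zero are flagged, not silently guessed.
* Tie-breaks are deterministic everywhere (rank scores: smaller adjusted
  p, then probe id; k sweep: smallest k; top DMP: larger |Δβ|), so every
  output is reproducible byte-for-byte given a seed, and the run manifest
  deliberately contains no timestamps.

## Problem sizes

The default test and acceptance runs use 20,000 CpGs, 12–24 subjects,
1,000–2,000 proteins, and 5–10 simulation seeds per stochastic check —
sizes chosen so the full suite and the acceptance script each complete in
well under a minute on one CPU while leaving enough features for FDR and
hyperparameter estimation to behave as they would at array scale.

## Known limitations

* The gap-based DMR caller is not a reimplementation of kernel-smoothed
  region statistics; counts and boundaries will differ from kernel-based
  callers on the same data.
* The duplicate-correlation approximation is exact only for complete
  balanced pairs; unbalanced designs fall back to unpaired models with
  covariates rather than partial pooling.
* Deconvolution supports exactly two cell types; the constrained-projection
  closed form and the balanced-reference construction both assume it
  (the architecture would extend, the current interfaces do not).
* Quantile normalization of betas assumes comparable underlying
  distributions across samples within a design type; strong global
  methylation shifts would be partially normalized away.
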