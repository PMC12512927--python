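# fibretype

Analysis toolkit for fibre-type-resolved skeletal-muscle epigenomics and
proteomics. Human muscle is a mosaic of slow-twitch (Type I, MYH7-dominant)
and fast-twitch (Type II, MYH2-dominant) fibres whose DNA-methylation and
protein profiles differ substantially, so any whole-muscle (WM) measurement
is confounded by the sample's fibre-type composition. `fibretype` implements
the full computational workflow for dealing with this:

* **Differential methylation** on Infinium-array beta values: probe QC
  filtering, per-design-type quantile normalization, empirical-Bayes
  moderated t-statistics on M-values with Benjamini–Hochberg FDR, and
  region (DMR) calling by sign-consistent gap chaining scored with Fisher's
  p-value combination.
* **Reference-based deconvolution**: a balanced CpG reference matrix (equal
  numbers of CpGs hyper- and hypomethylated in Type I vs Type II, profiled
  as mean beta per fibre type) and per-sample estimation of fibre fractions
  by robust regression (RPC) or constrained projection (CP).
* **Label-free proteomics**: contaminant/observation filtering,
  median-centering, missing-not-at-random imputation from a left-shifted
  Gaussian, moderated differential expression, and myosin heavy-chain
  isoform percentages from isoform-unique peptide intensities.
* **Integration**: gene-level joining of both layers, correlation of
  methylation effects with protein fold changes, and quadrant
  classification (e.g. hypermethylated + down-regulated).
* **Synthetic data** with known ground truth (mixture weights, true
  differential CpGs/proteins), so every stage is testable without any
  download.

It is intended for muscle physiologists and epigeneticists who need to
estimate or correct for fibre-type proportions in WM methylation studies,
and for method developers who want a self-contained, fully simulated
test-bed for reference-based deconvolution.

## The models

**Moderated t.** For feature g with contrast effect $\hat\beta_g$, residual
variance $s_g^2$ on $d$ degrees of freedom, the variance is shrunk toward a
prior $s_0^2$ with prior weight $d_0$:

$$\tilde s_g^2 = \frac{d_0 s_0^2 + d\, s_g^2}{d_0 + d},\qquad
\tilde t_g = \frac{\hat\beta_g}{\tilde s_g\,c} \sim t_{d_0+d},$$

with $c$ the design-dependent standard-error scale. $(d_0, s_0^2)$ are
estimated by moment-matching the mean and variance of $\log s_g^2$ through
digamma/trigamma relations. Paired designs are resolved by within-subject
differencing. Methylation is tested on M-values
$M = \log_2\!\big(\beta/(1-\beta)\big)$, with the beta-scale group
difference $\Delta\beta$ reported alongside.

**Deconvolution.** Each WM sample's beta vector $y$ at the k reference CpGs
is modelled as $y \approx w_{\mathrm{TI}}\,\mu_{\mathrm{TI}} +
w_{\mathrm{TII}}\,\mu_{\mathrm{TII}}$. RPC fits a robust linear model
(Huber weights, $c = 1.345$, MAD scale, IRLS) with intercept, truncates
negative coefficients at zero and renormalizes to $\sum_i w_i = 1$; CP
solves the constrained least-squares problem exactly for two cell types.
Reference CpGs are chosen by the score
$|\Delta\beta| \times (-\log_{10} p_{\mathrm{adj}})$, half from each
direction stratum.

**Isoform percentages.** With unique-peptide intensities $u_{ij}$ for
isoform $i \in \{\mathrm{MYH1,MYH2,MYH4,MYH7}\}$,

$$\%\mathrm{MYH}_i = \frac{\sum_j u_{ij}}
{\sum_{k}\sum_j u_{kj}} \times 100 .$$

**MNAR imputation.** Missing log2 intensities are drawn from
$\mathcal N(\mu_{\mathrm{obs}} - 1.8\,\sigma_{\mathrm{obs}},\,
(0.3\,\sigma_{\mathrm{obs}})^2)$, where $\mu_{\mathrm{obs}},
\sigma_{\mathrm{obs}}$ summarize all observed values.

## Worked example

```python
import fibretype as ft

cfg = ft.SimConfig(seed=1)                      # 20,000 CpGs, 12 paired subjects
beta, sheet, truth = ft.simulate_fibre_methylomes(cfg)

m = ft.beta_to_m(beta)
design = ft.DesignSpec(contrast=("TI", "TII"), paired=True)
res = ft.ModeratedTModel(m.values, sheet, design, effect_endog=beta.values).fit()
print(res.summary())

ranked = ft.rank_reference_candidates(res.table)
ref = ft.build_reference_matrix(ranked, beta, sheet, k=10)
wm = sheet.index[sheet["group"] == "WM"]
est = ft.deconvolve_rpc(beta.subset_samples(wm), ref)
print(est.evaluate(truth.sample_props["w_TI"]))
```

prints

```
Moderated t-test results
======================================
contrast:        TI - TII
features:        20000
residual df:     11
prior df (d0):   4.63792
prior var (s0²): 0.08197
model:           within-subject differencing (duplicate-correlation approximation)
FDR < 0.05  : 2100 features
FDR < 0.005 : 2014 features
FDR < 0.001 : 2001 features

r = 0.982, RMSE = 0.026 (n = 12)
```

The simulation plants 2,000 truly differential CpGs; the moderated test
recovers almost exactly that set at FDR < 0.001. A 10-CpG balanced
reference then estimates the 12 unseen whole-muscle mixing weights with
r = 0.98 and an RMSE of 0.026 against the known simulated fractions.

The same workflow is available from the shell:

```bash
fibretype all --workdir run --seed 1        # simulate → QC → DMP/DMR →
                                            # reference → deconvolve → sweep-k →
                                            # proteome → isoforms → integrate
fibretype deconvolve --workdir wd \
    --beta-tsv user_betas.tsv --reference-csv reference.csv
```

Each stage appends to `manifest.jsonl` (parameters, seeds, row counts), and
re-running with the same seed reproduces every output byte-for-byte.

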