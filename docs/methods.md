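# Methods

This note documents the statistical model, the estimators' exact
conventions, the synthetic data-generating process, the numerical choices,
and the known limitations of `mrbiome`.

## Setting and assumptions

Two-sample summary-data Mendelian randomization: exposure (a gut-microbiome
taxon's abundance) and outcome (a case-control pancreatitis phenotype) are
measured in non-overlapping cohorts, and only per-SNP summary associations
are used. Identification rests on the three instrumental-variable
assumptions — instruments associate with the exposure, are independent of
confounders of the exposure-outcome relation, and affect the outcome only
through the exposure. The estimators differ in how far they relax the third
assumption: IVW requires all instruments valid (balanced pleiotropy at
most), MR-Egger allows directional pleiotropy under the InSIDE assumption,
the weighted median tolerates up to 50% invalid weight, the weighted mode
requires only a valid plurality, and MR-PRESSO detects and removes
individual violating SNPs. The analysis runs in both directions (taxa →
pancreatitis and pancreatitis → taxa) with identical machinery to probe
reverse causation.

## Instrument selection

The cascade runs in a fixed order: p-value screen → LD clumping →
confounder blacklist → weak-instrument filter. The order is logged and every
removal is audited `(rsid, filter, reason)`.

* **p screen**: strict `p < 1e-5` (the inclusive threshold appropriate for
  microbiome GWAS, where genome-wide-significant hits are scarce).
* **Clumping**: greedy; candidates in ascending-p order (ties broken
  lexicographically by rsid, which makes the output invariant to input row
  order), each index SNP removing same-chromosome SNPs within 10,000 kb with
  r² ≥ 0.001 against it. SNP pairs absent from the LD matrix are treated as
  r² = 0; reference panels are sparse and dropping such SNPs would silently
  discard instruments.
* **Blacklist**: a static table of rsids annotated with confounder traits
  (diabetes, cholestasis, alcohol use, ...). The packaged default uses
  synthetic rsids — it stands in for interactive variant-phenotype lookup
  services, which are out of scope; users supply their own table for real
  analyses.
* **Strength**: per-SNP F = β²/SE², excluding F < 10; per-SNP variance
  explained computed by the full form R² = 2f(1−f)β² / (2f(1−f)β² +
  2f(1−f)·n·SE²), which algebraically equals β²/(β² + n·SE²) (both forms are
  asserted to agree to 1e-12 in tests). The aggregate instrument strength is
  the standard multi-instrument F = (R²/(1−R²))·((n−k−1)/k). An
  algebraically inconsistent variant of this formula, (n−k−1)²/(1−R²),
  circulates in print; it is exposed behind `literal=True` for audit only
  and never used. The F < 10 exclusion is applied per SNP, not on the
  aggregate.

## Harmonization

Effect alleles are aligned per exposure SNP: identical pair → kept; swapped
pair → outcome beta negated and EAF complemented; complemented (strand-flip)
pair, with or without swap, reconciled likewise. Palindromic (A/T, C/G) SNPs
are removed unconditionally — no allele-frequency rescue window — because
strand ambiguity cannot be resolved reliably from summary data. Anything
else is an audited `allele_mismatch`; duplicated rsids on either side are
dropped entirely (no keep-first tie-break, which would be arbitrary).
Proxy-SNP lookup for instruments missing in the outcome is deliberately not
implemented. EAF consistency between studies is not enforced (informational
only). Note one numerical consequence: a double allele swap restores betas
bit-exactly but EAF only to machine precision (1−(1−f) ≠ f in floating
point).

## Estimators

All methods sort SNPs by rsid internally before any computation, including
bootstrap draws, so every fit — stochastic ones included — is bit-identical
under permutation of the input rows at a fixed seed.

* **Wald ratio** (J = 1): θ̂ = β̂_Y/β̂_X, SE = σ_Y/|β̂_X| (first-order delta
  method), normal inference.
* **IVW** (J ≥ 2, primary): precision-weighted mean of the ratios with
  first-order weights w_j = β̂²_Xj/σ²_Yj (no NOME correction — no
  second-order specification is adopted). Default inference is
  multiplicative random effects: SE inflated by φ = max(1, √(Q/(J−1))).
  This is conservative under heterogeneity and matches common toolchain
  practice; `ivw_model="fe"` gives the fixed-effect fit.
* **MR-Egger** (J ≥ 3): weighted regression with intercept, weights
  1/σ²_Yj, after flipping any SNP with negative exposure effect (required
  for the intercept to be interpretable as average directional pleiotropy).
  Slope inference uses t(J−2) with the multiplicative residual inflation
  bounded below by 1. The intercept uses the *exact* residual-scaled t
  inference without the floor: a numeric study during design showed that
  flooring the intercept SE drives the intercept test's null size to
  0.02–0.03, while the exact scaling is calibrated at 0.05; the floor is
  kept for the slope, where conservatism is the accepted convention.
* **Weighted median** (J ≥ 3): order statistics of θ̂_j interpolated at
  cumulative normalized weight 0.5. SE from a parametric bootstrap
  (default 5,000 draws) resampling θ*_j ~ N(θ̂_j, σ_Yj/|β̂_Xj|) with weights
  held fixed. Draws are taken on sign-canonicalized ratios so that negating
  every outcome effect leaves the SE and p-value unchanged (exact sign
  equivariance).
* **Weighted mode** (J ≥ 3): maximiser of the weighted Gaussian kernel
  density of the ratios. Bandwidth = `bandwidth_factor` ×
  0.9·min(sd, 1.4826·MAD)·J^(−1/5), the standard robust plug-in rule; a
  literal median-of-pairwise-deviations scale was rejected during design
  because contaminated instruments inflate it enough to wash out a clear
  majority cluster. The maximiser is located on a 1,024-point grid and
  refined by bounded scalar optimisation; as the bandwidth grows the
  estimate approaches the weighted mean (verified numerically). Bootstrap
  SE as for the median (coarser 256-point grid in the bootstrap, which only
  needs the spread).
* **MR-PRESSO** (J ≥ 4): the global statistic is the leave-one-out residual
  sum of squares RSS = Σ_j (β̂_Yj − θ̂_(−j)β̂_Xj)²/σ²_Yj, with θ̂_(−j) the
  fixed-effect IVW omitting SNP j, referenced against `n_sim` (default
  1,000) parametric simulations of both effect columns
  (β*_X ~ N(β̂_X, σ²_X), β*_Y ~ N(θ̂_(−j)β̂_X, σ²_Y)), recomputing the
  leave-one-out slopes within each simulation. Outcome-precision weights
  are used for the residuals because they live on the outcome-beta scale.
  Per-SNP outlier p-values are the upper-tail fractions of each SNP's
  simulated residual contribution, Bonferroni-multiplied by the active J.
  While the global p < 0.05 and some adjusted outlier p is below the 0.05
  threshold, the worst SNP is removed one at a time (iterating to
  exhaustion, never below 4 SNPs); empirical-p ties are broken by the
  larger observed residual, then lexicographically — empirical p-values
  are granular, and without the residual tie-break the removal order would
  be an artifact of rsid naming. The distortion test compares the
  pre/post-removal IVW difference (scaled by the pre-removal estimate)
  against 1,000 random same-size removals. The corrected estimate is IVW on
  the retained SNPs.

Confidence intervals use the normal 1.959964 multiplier except the Egger
slope and intercept (t(J−2)); odds ratios are exp(β) throughout.

`run_all_estimators` applies what the instrument count supports: J=1 Wald
ratio; J=2 IVW; J≥3 adds Egger, weighted median and mode; J≥4 adds
MR-PRESSO. The IVW (or single-SNP Wald) result carries the primary flag and
drives tier classification.

## Sensitivity analyses

Cochran's Q uses fixed-effect weights even when the headline IVW is
random-effects, because Q's χ²(J−1) null requires them; the same Q feeds the
IVW inflation factor (single source of truth). The Egger intercept test
flags pleiotropy at p < 0.05. Leave-one-out refits the headline IVW omitting
each SNP; the stability flag requires every omission to preserve the sign
of the full estimate and, when the full estimate is nominally significant,
its significance — a convenience summary of what is usually judged from a
forest plot.

## Multiplicity control and reporting

The Bonferroni divisor for a row is the count of analyzable (non-unknown)
taxa at the microbial trait's taxonomic level — with the packaged registry,
9 phyla, 16 classes, 20 orders, 32 families, 119 genera. Unknown groups are
excluded from the divisor because they are never analyzed; the class-level
worked example (raw p 0.0005 × 16 = 0.008) confirms the plain analyzable
count is the intended divisor rather than any correlation-adjusted
effective number. In the reverse direction the divisor comes from the
microbial *outcome*'s level, mirroring the forward rule. Benjamini–Hochberg
FDR runs within (direction × method × level × partner-trait) families.
Pairs with no surviving instruments are emitted as explicit skip records so
a full sweep remains auditable. Tiers: significant iff Bonferroni-adjusted
p < 0.05; suggestive iff only the raw p < 0.05; null otherwise.

## Synthetic data-generating process

Summary statistics are simulated directly at the summary level — two-sample
MR consumes nothing else, and it keeps every test sub-second. For SNP j with
MAF f_j ~ U(maf_range):

* σ_Xj = 1/√(2f_j(1−f_j)·n_X) for the quantitative exposure
  (n_X = 18,340);
* σ_Yj = 1/√(2f_j(1−f_j)·n_eff), n_eff = 4/(1/n_cases + 1/n_controls) —
  the effective-sample-size approximation for log-odds summary statistics;
* true effects γ_j with magnitude U(gamma_range) and random (or, optionally,
  all-positive "exposure-oriented") signs;
* β̂_Xj ~ N(γ_j, σ²_Xj); β̂_Yj ~ N(θγ_j + α_j + ω_j, σ²_Yj), with
  pleiotropy α_j ~ N(μ, τ²) on a configurable fraction of SNPs (μ = 0 under
  the balanced mode) and outlier shifts ω_j of magnitude 10× the median
  |θγ| (falling back to 10× median |γ| when θ = 0) on
  round(outlier_frac·J) SNPs drawn without replacement;
* p-values from two-sided Wald tests; LD optionally block-diagonal with
  blocks placed far apart relative to the clumping window.

Defaults are the study conditions: 15 instruments (microbiome taxa
typically yield roughly 5–25 at p < 1e-5; per-analysis counts are not
published, so 15 is a representative middle), γ magnitude 0.08–0.16 (z of
about 5–14 at n_X = 18,340, i.e. instruments that clear the screen without
being implausibly strong), MAF 0.1–0.5, and the acute-pancreatitis cohort
(3,022 cases / 195,144 controls) as the default outcome; the other three
cohort configurations (CP 1,737/195,144; AAP 457/218,335; ACP 977/217,815)
are available as `OUTCOME_COHORTS`.

What the generator does **not** emulate: real LD from a reference panel,
allele-frequency differences between cohorts, selection-induced winner's
curse (instruments are simulated as truly associated rather than selected
from a genome-wide scan), sample overlap, and any 16S-level abundance
structure. Passing tests therefore certify the pipeline's statistical
machinery under its stated model, not the biology of any real cohort.

## Calibration experiments (problem sizes)

`mrbiome.calibration` packages the replicated experiments used by the
acceptance suite and script:

* **Null calibration** — 1,000 replicates of the default null scenario
  (θ = 0, J = 15, AP-sized outcome); empirical type-I error of IVW, the
  Egger intercept test, Cochran's Q and the MR-PRESSO global test
  (600 simulations per replicate) at nominal 0.05.
* **Parameter recovery** — 500 replicates per θ ∈ {−0.5, 0, 0.3} with 10
  instruments of magnitude 0.1–0.2 against the AAP-sized outcome (the
  smallest cohort). With these conditions the Monte-Carlo SE of the mean
  (~0.0035) comfortably dominates the sub-percent weak-instrument
  attenuation that first-order ratio estimates carry by construction, so
  recovery is assessed cleanly; at much larger outcome sample sizes the
  attenuation term, not estimator error, would bound the achievable
  agreement.
* **Median robustness** — 200 replicates with 40% of instruments given a
  large directional pleiotropic effect (α ~ N(0.25, 0.02²),
  exposure-oriented γ): fraction of replicates where the weighted median is
  closer to θ = 0.3 than IVW.
* **Outlier recovery** — 200 replicates of 15 valid instruments plus one
  10×-effect outlier: fraction in which MR-PRESSO removes the true outlier
  first.

Child seeds for replicates derive from a single `SeedSequence`, kept below
2³¹.

## Numerical choices and degenerate inputs

Zero exposure beta is an undefined ratio (error at model construction);
zero outcome beta gives θ̂ = 0 with p = 1. A harmonized set that loses every
SNP produces a skip record, not an exception. Empty bootstrap spread
(se = 0) yields p = 1 rather than a division error. Simulated p-values are
clipped away from exact 0 to stay in (0, 1]. The weighted-mode bandwidth of
0 (all ratios identical) returns that common value. The duplicate-rsid rule
at read time drops *all* copies. LD matrices must be symmetric with unit
diagonal and entries in [0, 1] (validated on construction); TSV is the
interchange format.

## Limitations

* First-order weights mean ratio estimates are mildly attenuated toward
  zero for weak instruments; the F ≥ 10 filter bounds, but does not remove,
  this bias.
* The MR-PRESSO distortion test's permutation reference is approximate for
  very small J.
* The multiplicative-random-effects IVW is slightly conservative under
  exact homogeneity (null size ≈ 0.04 rather than 0.05) because φ is
  floored at 1.
* No Steiger directionality filtering, proxy-SNP lookup, multivariable MR,
  or liftover between genome builds.
* The packaged taxa registry reproduces the *composition* of the MiBioGen
  panel (counts per rank, unknown-group structure, and the taxa named in
  the reference tables); filler entries are plausible names, not a
  faithful roster.
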