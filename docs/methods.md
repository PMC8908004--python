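# Methods

## The genetic system

Maize knobs are large blocks of constitutive heterochromatin. At a given
chromosomal position a plant carries 0, 1 or 2 knob-presence alleles, and the
panel modelled here varies at four positions: K3L, K5L (long arms of
chromosomes 3 and 5) and K7S, K9S (short arms of 7 and 9). Inbred lines are
derived by nine generations of self-fertilisation from one heterozygous
seed, so they are effectively fixed (the chance a locus is still segregating
is 0.5⁹ ≈ 0.002); hybrids are F1 crosses between two lines and are
heterozygous wherever their parents disagree. The traits are days to male
and female flowering (MF, FF) and 2C genome size in picograms (GS).

## Synthetic-data generator

`simulate.GeneratorParams` encodes the study conditions. The defaults are:

| parameter | value | meaning |
|---|---|---|
| `n_self_generations` | 9 | selfing depth for line derivation |
| `design` | 8 lines × 3 reps + 35 hybrids × 5 reps | assay-1 completely randomised design (assay 2: 20 lines × 5) |
| `mu_mf_line, mu_ff_line` | 70, 72 d | line group means |
| `mu_mf_hybrid, mu_ff_hybrid` | 63, 64 d | hybrid group means (heterosis as an intercept shift) |
| `a_mf, a_ff` | −0.45, −0.51 d | additive effect per K9S presence allele |
| `d_mf, d_ff` | −1.40, −1.53 d | extra effect of K9S heterozygosity |
| `h2_mf, h2_ff, h2_gs` | 0.51, 0.41, 0.26 | entry-mean heritability targets |
| `rho_g` | 0.95 | genetic MF–FF correlation |
| `rho_e` | 0.65 | within-plant residual MF–FF correlation |
| `mu_gs_line, mu_gs_hybrid` | 5.4, 5.6 pg | 2C genome size group means |
| `gs_knob_effect` | 0 pg/allele | knobs do not move genome size by default |
| `sigma_e_ft, sigma_e_gs` | 2.5 d, 0.35 pg | plant-level residual SDs |

Two trait-order conventions circulate for the additive effects (−0.45 vs
−0.51 between MF and FF); the defaults follow the explicit running-text
order (MF −0.45, FF −0.51). K3L, K5L and K7S are strictly null.

An entry's genetic value is
`mu(type) + a·x(K9S) + d·1[x(K9S)=1] + u`, a plant adds an independent
Gaussian residual, and genome size follows the same scheme with a dosage
(0–8) slope instead of a single locus. The polygenic deviations
(u_MF, u_FF) are bivariate normal with correlation `rho_g`; flowering
residuals within one plant share correlation `rho_e` (both traits are
scored on the same plant). Hybrid crosses are ordered pairs of distinct
lines sampled without replacement — 8 parents yield only 28 unordered pairs,
so reciprocal crosses must be distinct to supply 35 hybrids.

**Variance calibration.** The heritability targets are for *total* genetic
variance, and the causal locus itself contributes. With presence frequency
1/2 (a segregating single seed), a fixed line has Var(x) = 1 and no
heterozygosity, while a hybrid of two independent lines has Var(x) = 0.5,
Var(het) = 0.25 and zero additive–dominance covariance. The generator
therefore solves

```
var(u) = max(0,  h² / (1 − h²) · σe² / r_eff  −  V_marker)
```

with `r_eff` the harmonic-mean replicate number of the design and
`V_marker` the entry-count-weighted causal variance above. If the requested
effects alone exceed the h²-implied genetic variance, `var(u)` floors at
zero with a warning. `rho_e` exists because the genetic correlation alone
cannot push the BLUE-level MF–FF Pearson to 0.95 once heritabilities are
below ~0.5 — replicate-mean noise caps it near 0.87 — and a shared
within-plant environment is the natural extra channel; 0.95/0.65 were fixed
by simulation before the defaults were frozen (mean Pearson over 200 panels:
0.95). The residual SDs (2.5 d, 0.35 pg) are typical for greenhouse
flowering scores and plant flow cytometry; only ratios matter for the
dimensionless outputs.

**What the generator does not emulate:** linkage (the four loci are on
different chromosomes and simulated independent), meiotic drive or biased
knob transmission, non-Gaussian residuals, spatial or temporal field trends,
genotype-by-year effects (the two assays are not connected), and
per-locus heterosis (a single group-mean shift stands in for it). Passing
tests show the estimators recover the parameters of *this* generating
model; real panels can violate any of these simplifications.

## Entry means and heritability

Under a completely randomised design with homoscedastic errors the BLUE of
an entry is its arithmetic replicate mean — there is no adjustment to make —
so `compute_blues` returns replicate means ordered to the genotype panel.
Heritability is estimated on plant-level records from the one-way
random-effects model fitted by REML, reported on the entry-mean basis
h² = σg²/(σg² + σe²/r_eff), r_eff the harmonic mean of per-entry replicate
counts. This is the basis that matches BLUEs as the association input. When
the panel mixes lines and hybrids the line/hybrid contrast enters as a fixed
effect: heterosis is treated as population structure, not genetic variance
(the ~7–8 d group gap would otherwise dominate σg² and push every h²
estimate toward 0.9). Whether the quoted heritabilities derive from one
assay or both pooled is not documented in the source design; estimates here
are per-panel.

Genome size from flow cytometry is the G0/G1 peak-mean ratio of sample to
internal standard times the standard's 2C value. The standard's 2C value is
a required argument, never hard-coded. Conversion to physical length uses
978 Mbp/pg with half-up rounding, which reproduces both reference pairs
(5.6 pg → 5477 Mbp, 5.4 pg → 5281 Mbp) exactly.

## Mixed-model scan

The marker matrix is stored biology-facing (presence counts); encodings are
derived per scan because the minor allele depends on panel composition. At a
frequency tie the absence allele is counted as minor. Monomorphic loci
(additive) and loci without heterozygotes (dominance) are excluded with
warnings. Reported effects are sign-normalised to *per presence allele*:
when the additive code counts absence copies the coefficient is negated, so
a protective knob always reports a negative effect no matter which allele is
minor. Under the dominance encoding the analogue of a minor-allele
frequency is the heterozygote frequency, and the `maf` column carries it.

Kinship is VanRaden method 1 on the centred count matrix, plus a ridge of
1e−6 × mean diagonal to guarantee positive semi-definiteness. With four
markers K has rank 4 (plus ridge): the polygenic term then competes directly
with each tested marker, which shrinks single-marker tests toward the null —
a feature of this marker-sparse design that the permutation threshold
compensates for, since permuted scans are shrunk the same way. An
identity-kinship mode exists for sensitivity analysis; the REML likelihood
is then flat in the variance ratio and a warning says so.

REML works in the eigenbasis of K: with δ = σg²/σe² the covariance is
diagonal, and the profiled criterion is maximised over δ on an 81-point
log grid (1e−8…1e8) refined by 80 fixed golden-section iterations. The fixed
iteration count makes the search branch-free and vectorisable across many
response vectors, so permutation scans use bit-for-bit the same path as the
single scan. By default variance components are re-estimated with the
marker in the model (`per_marker_exact`); `null_once` estimates them once on
the no-marker model and reuses the ratio for every marker, the usual
large-panel shortcut. Tests are Wald t with n − p residual degrees of
freedom (n ≤ 63 here, so a normal approximation would be anti-conservative);
p-values are clamped to the smallest positive float rather than zero.
Marker heritability is the variance-explained ratio
effect² · Var(code) / Var(y) — how that quantity was defined in the original
analysis is undocumented, so this definition is a documented choice.

Structure covariates: principal components of the centred counts
(deterministic signs; largest-magnitude loading positive) are available but
default to zero — the panel shares one genetic background. The line/hybrid
indicator is the default structure covariate in mixed panels, for a
structural reason: only hybrids can be heterozygous, so the dominance code
is confounded with heterosis, and no PC of the *additive* count matrix can
separate them (any linear function of 0/1/2 counts is blind to
heterozygosity). Without the indicator the dominance "effect" absorbs the
~7 d group gap.

## Permutation threshold

For each of `n_perm` permutations the BLUE vector is shuffled against the
fixed genotype/kinship/covariate structure (covariates stay with their
genotype rows — only the phenotype moves), the scan is re-run with variance
components re-estimated, and the minimum p across markers recorded. The
threshold is the type-7 (linear-interpolation) 5% quantile of those minima;
a marker is significant when p ≤ threshold, ties inclusive. The mirrored
historical procedure uses n_perm = 50, which makes a noisy 5% quantile — the
implementation warns below 100 and tests use several hundred. On fully
exchangeable nulls the procedure is calibrated (family-wise error ≈ 5%);
under the real design the 3-vs-5 replicate heteroscedasticity that y-only
shuffling scrambles leaves a mild upward drift (≈6% measured over 1000 null
panels), inherent to phenotype-only permutation. A Bonferroni line can be
drawn for plots, but the resampling threshold is the decision rule.

## Numerical choices and degenerate inputs

* Quantiles: type-7 everywhere (numpy default), documented for
  reproducibility; group summaries use the inclusive-median convention.
* Golden-section precision: bracket ~0.4 decades shrinks below 1e−12, so
  balanced-design REML matches the ANOVA method-of-moments closed form to
  ~1e−7 relative.
* σg² floors at zero (boundary estimates report h² = 0).
* Zero-variance marker codes, monomorphic kinship input, non-PSD kinship,
  rank-deficient designs, single-replicate-only panels and genotype/BLUE
  mismatches all raise informative errors; row/column coordinates are named
  in file-parsing errors.
* All randomness flows from one top-level seed through named substreams
  (panel, phenotypes), so every artifact is reproducible byte-for-byte;
  output tables are stamped with the tool version, a hash of the analysis
  configuration and the seed.

## Problem sizes

Simulation studies in the tests and the acceptance script use 200 panels
for parameter recovery (effects and heritabilities) and 500 panels × 200
permutations for the family-wise error check — sizes at which the binomial
and Monte-Carlo error of each check is several times smaller than its
tolerance.

## Known limitations

Single-marker tests only (no multi-locus or epistatic models); exactly two
alleles per locus, no missing calls, no knob-size quantification; BLUEs
assume homoscedastic replicate noise, though lines (3 reps) have noisier
means than hybrids (5) — the heritability and threshold machinery absorb
most but not all of this; the additive scan at n = 43 entries has modest
power for effects of ~0.5 d (the dominance scan, with triple the effect
size, is the sensitive one); and the dominance model cannot be fitted in
all-inbred panels, which contain no heterozygotes.
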