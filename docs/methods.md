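# Methods

This note records the statistical conventions the package implements,
the generative model behind the synthetic-data module, and the choices
made where the underlying procedures were open to interpretation.

## qPCR quantification

Standard curves are ordinary least squares of quantification cycle on
log10 copy number over a dilution series (typically five points).
Amplification efficiency is derived from the slope, never stored
independently: `E = 10^(−1/slope) − 1`, so a slope of −3.3219
cycles/decade is exact doubling (E = 100%). Efficiencies outside
90–110% raise a warning, not an error — acceptance bands are a reporting
convention and per-assay curve quality is the operator's call.

Sample cycles invert through `(cycle − intercept)/slope`, plus the log10
of the dilution × volume scaling, giving Log10 gene copies/mL. Values
outside the plausible [0, 12] range are clipped and flagged
(`out_of_range`), not discarded.

**Averaging domain.** Replicate means and SDs are computed on the Log10
scale (sample SD, n−1), because that is the scale on which such panels
are reported and compared. Linear-domain averaging exists behind an
explicit `linear_domain` flag and reports no SD, since a mixed-scale
dispersion would be misleading.

## Microbiota indicators

**F/B** is the ratio of the *mean Log10 loads* of Firmicutes to
Bacteroidetes — not of linear copy numbers. This is verified by
arithmetic on the bundled printed panel (7.37/6.41 = 1.15, matching the
printed cell) and holds for all ten printed conditions to ±0.01.
Interpretation bands: ≤1.5 eubiosis, >2 dysbiosis, otherwise
intermediate. A linear-domain mode exists behind a flag and is labelled
as such.

**qPI** sums four signed taxon-to-total terms (see README). Two
normalization modes are exposed side by side because the normalization
used upstream of the published index is under-specified:

- `raw_log` (default): each term is the taxon's mean Log10 load at the
  condition divided by the Eubacteria mean Log10 load there.
- `mean_centered`: the four numerator taxa are first mean-centered per
  taxon across all conditions in the table. The Eubacteria denominator
  is deliberately left on the raw scale: centering it too would put
  near-zero values in a denominator and make the index unbounded.
  Centering requires at least two conditions.

The published fold-differences between conditions of the index are not
reproducible from the printed panel under either mode, so no claim is
made about them; both modes are reported and the choice documented.

**Post hoc letters.** One engine serves taxa and volatiles: Tukey
pairwise p-values from the studentized-range distribution with the
Tukey–Kramer standard error (valid for unbalanced replication), and an
insert-and-absorb compact letter display. Letters are assigned in
descending-mean order ('a' = highest), and the construction guarantees
both directions: significant pairs share no letter, non-significant
pairs share at least one. When every group has zero within-group
variance the statistic is undefined; the engine falls back to
exact-equality grouping with a warning.

## Volatilome pipeline

Order of operations is fixed: ANOVA screen → mean centering → baseline
subtraction → Tukey letters.

- **Screen**: per-compound one-way ANOVA across all treatment × time
  groups at α = 0.05, unadjusted by default (the screen is a coarse
  filter, not an inference); BH-FDR is available behind a flag.
  Compounds constant everywhere get p = 1 and are never retained. An
  explicit exclusion list handles ad hoc minor-compound removal, since
  no objective criterion for it exists.
- **Centering** subtracts each compound's grand mean over all samples;
  the stored means make the operation exactly invertible.
- **Baseline subtraction**: the baseline is the pooled mean of all
  time-0 samples — it is a single pre-fermentation state of the fecal
  inoculum, not a per-treatment quantity. Deltas at the baseline row are
  identically 0.
- **Class bookkeeping** (percent change of per-class sums, per-compound
  percent shifts) operates on un-centered relative or absolute units.
  Class sums are invariant to splitting a compound into parts that sum
  to it. A class with zero baseline sum but non-zero endpoint is flagged
  *newly detected* rather than given an infinite percentage.

**Non-detects** carry an explicit flag, never a bare 0: sums, shifts and
the screen substitute 0 (flagged); ordination excludes them pairwise and
imputes at the column mean (= 0 after centering) with a warning. This
mirrors instruments that report below-detection rather than zero.

**Ordination** is PCA via SVD of the column-centered matrix. The sign
convention — the largest-magnitude loading of each component is made
positive — fixes the rotational sign ambiguity so scores are
reproducible across platforms.

**Internal-standard convention.** Absolute quantification follows the
usual internal-standard form, mg/kg = (peak area / IS area) × 4 mg/L
equivalent with response factor 1.0 unless supplied (2-pentanol,
4-methyl at 4 mg/L is the conventional IS for this matrix). This is a
declared convention for preparing inputs; the package itself consumes
already-quantified tables.

## Taxa–metabolite correlations

qPCR (triplicate) and GC-MS (duplicate) replication depths differ, so
pairing is at condition level: technical replicas are averaged within
each (treatment, time, experiment) and condition means are correlated —
24 paired points under the standard design. Spearman rho is the Pearson
correlation of midranks; p is exact (all n! pairings) for fewer than 10
points and the t approximation otherwise. Constant series give missing
rho, never 0. Cells with fewer than 4 pairs are reported missing.
Significance is starred at p < 0.05 without multiplicity correction, the
convention for exploratory correlation heatmaps; BH-FDR can be applied
downstream.

Two-way ordering clusters rho *profiles* (a taxon's correlations over
all compounds, and vice versa) under distance 1 − Pearson with complete
linkage. Labels are sorted lexicographically before linkage, which makes
tie-breaking deterministic and platform-independent. Missing rho is
imputed as 0 (no association) with a warning. Clustering on rho profiles
(rather than raw abundances) reproduces the expected bipartition of taxa
into a beneficial group (positively correlated with C2–C10 acids) and a
detrimental group (positively correlated with branched-chain acids and
skatole) on simulated data.

## Synthetic data generator

The generator emulates the standard batch-fermentation design: 3
substrates (fast reference / slow test fiber / blank) × time points
{0, 6, 18, 24} h × 2 independent runs, with qPCR triplicates and GC-MS
duplicates.

**Taxa.** Log10 loads follow a saturating Michaelis-type ramp,
`L(τ) = baseline + effect · τ/(τ + K) + ε`, ε ~ N(0, 0.15) Log10 units
per replicate (the dispersion scale of real sextuplicate panels). The
half-time K is 6 h for the fast substrate, 16 h for the slow one, 10 h
for blank drift — the saturating form with per-treatment K reproduces
the late-bloomer pattern of fibers whose antimicrobial essential-oil
fraction delays growth. Baselines are the published panel's baseline
column; effect sizes are the published 24 h deltas per treatment (the
blank control drifts toward enterobacteria, *E. coli* and *Clostridium*
group I while losing bifidobacteria — a stressed, substrate-starved
community).

**VOCs.** Concentrations couple to the noiseless mean taxa trajectories:
`C(τ) = baseline_v + Σ_t A[v,t] · (10^(effect_t·ramp) − 1) + ε`,
ε ~ N(0, 0.25) mg/kg, clipped at 0 with a non-detect flag. The coupling
matrix A (mg/kg per unit relative linear-load increase) places the
short- and medium-chain fatty acids on the saccharolytic guild
(bifidobacteria, lactobacilli, *F. prausnitzii*, Bacteroidetes) and the
proteolytic markers (branched-chain acids, indole, skatole) on
enterobacteria and *Clostridium* group I, with small magnitudes where
the linear increase spans orders of magnitude. Baseline concentrations
are typical of fecal fermentation supernatant (acetate ≫ propionate >
butyrate ≫ minor acids). Two strong single-taxon-dominated couplings
(butanoate–Lactobacillales, skatole–Enterobacteriaceae) are declared as
benchmarks in the ground-truth record for sign-recovery checks.

**What it does not emulate**: no cross-feeding dynamics, no pH/redox
coupling, no compositionality between VOC classes, no inter-donor
variability — noise is i.i.d. Gaussian per replicate. Passing calibration
tests therefore demonstrates the *analytics* behave correctly under the
stated model, not that the model captures all structure of real
fermentations.

**Noiseless limits.** With all effects, couplings and noise at zero,
every condition equals baseline, and F/B and qPI are constant — a
self-consistency check carried in the test suite. The `null` scenario
(effects and couplings zeroed, noise kept) calibrates type-I error:
the ANOVA screen retains ≈5% of 1000 pure-noise compounds at α = 0.05.

## Problem sizes and numerics

The Monte-Carlo checks run at 100 seeds (scenario recovery) and
20 seeds × 1000 compounds (screen calibration), sizes at which the
binomial uncertainty of the reported rates is a few percent — adequate
to confirm the ≥95/100 and ≥90/100 recovery targets without excess
computation. Exact Spearman permutation p is limited to n ≤ 9 (9! =
362,880 enumerated pairings); beyond that the t approximation is
accurate. Text output uses 17 significant digits so CSV round-trips are
bit-exact for float64.

## Known limitations

- Per-target qPCR curve parameters (primer pairs, efficiencies) must be
  user-supplied; no melting-curve or amplification-model analysis.
- The "super-normalization" sometimes applied to volatile panels beyond
  mean centering is not implemented — only mean centering is, as the
  one unambiguously specified normalization.
- Published inter-condition fold-differences of the qPI are not
  reproducible from printed panel means (normalization under-specified)
  and are deliberately out of scope.
- No raw chromatogram/spectra parsing; compound identification is
  assumed done upstream.
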