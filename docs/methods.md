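# Methods

This note documents the models, assumptions, parameter choices, and numerical
decisions behind each stage of `coraltrace`, and what the synthetic-data
generator does and does not emulate.

## Natural-abundance correction

**Model.** Correction is carbon-only. For a metabolite with *n* carbons, a
molecule carrying *j* tracer (¹³C) labels is observed at mass shift
*k = j + B*, *B ~ Binomial(n − j, p)*, with *p* the natural ¹³C abundance
(default 0.0107, IUPAC; configurable through `NaturalAbundanceModel`). The
(n+1)×(n+1) matrix *C* with columns given by these shifted binomial pmfs is
column-stochastic by construction.

**Inversion.** The observed intensity vector is normalized to proportions and
the system `observed = C @ true` is solved by non-negative least squares
(`scipy.optimize.nnls`), then renormalized to sum 1. NNLS rather than
`C⁻¹ @ observed` because direct inversion yields negative fractions under
measurement noise; the non-negativity constraint is the physically meaningful
prior. Consequences worth knowing:

- noise-free round trips are exact to machine precision (the round-trip check
  demonstrates ≲1e−15 at n ≤ 10, p ≤ 0.2);
- under noise, truncation at zero biases small fractions slightly upward.
  For an unlabeled metabolite at intensity noise CV 0.15 the corrected
  enrichment floor is ~0.001 — the same order as dark-incubation enrichment
  values in real tracing data, so the floor is treated as part of the
  measurement model rather than removed.

**Extension hook.** Multi-element correction (H/N/O/S, resolution-dependent
merging) would replace `build_correction_matrix` by a product over
element-wise matrices; the rest of the pipeline only consumes the corrected
fractions and would be unchanged. The tracer metrics implemented here concern
carbon only, so this is deliberately out of scope.

## Response variables

- **Pool size**: total ion count over isotopologues, per metabolite per
  sample. Normalization divides each sample by its own median across
  metabolites (biomass correction; the normalized sample median is exactly 1),
  followed by ln(x+1). Natural log is used; since the transform is monotone
  and feeds distance-based tests, the base affects distances only by a global
  scale and leaves PERMANOVA statistics and p-values unchanged.
- **Enrichment**: Σ i·fᵢ / n from corrected fractions (correction happens
  before any enrichment computation). Enrichment matrices are analyzed on the
  raw proportion scale — proportions in [0,1] need no variance-stabilizing
  renormalization for Euclidean distances at these magnitudes.
- **Fold change**: relative difference (mean_high − mean_ambient)/mean_ambient
  on median-normalized (pre-log) pools and on raw enrichment proportions, so
  fc = 0.10 reads directly as "10% higher at high temperature". The log2-ratio
  convention was rejected because the framework's percent annotations
  (e.g. "+10%") are relative differences.

## PERMANOVA

Gower-centered distance matrix G = −½ J D² J; sequential (Type I) sums of
squares via nested hat-matrix differences for up to two factors plus
interaction; pseudo-F per term against the full-model residual; whole-sample
free permutation; p = (#{F\* ≥ F} + 1)/(n_perm + 1), never zero. This mirrors
the defaults of the standard distance-based ANOVA implementation used in
community ecology. Seeds are mandatory and logged. Default 999 permutations
(p-granularity 0.001); simulation studies use 199 to keep run times short,
which only coarsens p-granularity, not calibration (type-I error on null data
sits inside the exact binomial 95% band at α = 0.05).

## PLS-DA and VIP

NIPALS PLS2 on column-centered, unit-variance (autoscaled) X against the
centered one-hot class coding; X deflated by loadings per component, giving
mutually orthogonal scores; the start vector is the first Y-residual column,
so fits are deterministic. Autoscaling is the default of the multivariate
metabolomics ecosystem and is configurable. Two components are fitted —
matching the two X-variates on which results are reported — and both feed
VIP: VIP_j = √(p · Σ_a SSY_a ŵ²_aj / Σ_a SSY_a), where SSY_a is the Y sum of
squares captured by component a. Mean VIP² = 1 identically, so VIP ≥ 1 means
"above average importance"; ties at exactly 1.0 are selected (≥). A
`transform` method exposes the W(P′W)⁻¹ rotation for projecting held-out
samples.

**Selection gate.** The supervised VIP selection is only applied when the
unsupervised PERMANOVA for the same metric is significant (α = 0.05 default;
`require_global_significance=False` disables). Rationale: PLS-DA at n ≪ p
overfits any labeling, and VIP's mean-square-1 normalization forces roughly
half the variables above 1 even for pure noise — the sequential
PERMANOVA-then-PLS-DA workflow is what makes VIP ≥ 1 interpretable.

## Quadrant classification

A metric's state is *high* (selected, fc > 0), *low* (selected, fc < 0) or
*stable* (not selected). No numeric fc threshold is applied beyond the sign —
selection carries the evidence. Mapping: high/high → ii, high pool with
non-high enrichment → iv, high enrichment with non-high pool → i, both stable
→ no call, every remaining combination involving a low → iii. A selected
metric with fc exactly 0 (possible only in degenerate data) is demoted to
stable with a warning. Quadrant axes use median-normalized pools; whether raw
or normalized pools should define the pool axis is underdetermined, and
normalized pools were chosen for consistency with every other pool-size
statistic in the pipeline.

The shipped pathway table covers glycolysis/central carbon, pentose
phosphate, TCA, ammonium assimilation (GS-GOGAT), urea cycle and dipeptide
synthesis; metabolites may belong to several pathways (pyruvate). Users can
substitute their own table (`pathway_csv`); pathway inference from compound
databases is out of scope.

## Control analyses

- **Isotope control**: two-factor PERMANOVA (isotope × temperature, with
  interaction) of pool size over all light samples — the label itself should
  not modulate the temperature response.
- **Light/dark validation**: per-metabolite percent excess
  (light − dark)/light × 100 with the light mean as denominator (the dark
  denominator diverges as dark → 0); p-values from pooled-variance cell-mean
  contrasts within the metabolite × condition factorial, BH-FDR-adjusted
  across metabolites. A non-positive light mean flags the row rather than
  producing a misleading percent.
- **Label saturation**: the contiguous pair of sampled times bracketing the
  maximum mean enrichment, bracketing toward the larger neighbor; monotone
  series return the terminal window flagged `no_interior_peak`, constant
  series are flagged degenerate.
- **Factorial ANOVA** uses Type II sums of squares (balanced designs
  reproduce the classical table exactly; verified against a projection-matrix
  oracle). Marginal-means contrasts use the pooled residual variance; the
  family-wise adjustment within each stratum defaults to Tukey's studentized
  range (collapsing to the plain t-test when the contrast factor has two
  levels, where there is no family), with Sidak/Bonferroni/none available.
- **FDR**: Benjamini–Hochberg step-up with enforced monotonicity.

## Respirometry

`extract_rate` enumerates every contiguous window covering ≥ ⌈α·n⌉ points
(α = 0.4 default, the standard setting for larval-scale traces; stride
configurable for very long traces) and fits each by OLS. Windows are ranked
by the equally weighted (configurable) percentile ranks of three criteria:
|skewness| of residuals (linearity), slope CI width relative to |slope|
(precision), and negated window length (data usage); ties break toward longer
windows. The three criteria and equal weighting reconstruct the published
local-linear-regression ranking method that is cited for this analysis only
by name and α; weights are exposed for sensitivity analysis. All window
statistics are computed from prefix sums (globally centered for
conditioning), so cost is O(windows), not O(windows × length).

Conventions: raw slopes are negative for consumption; respiration is reported
as the positive magnitude. Normalization: (raw − blank) × well volume /
individuals, µmol→nmol (nmol O₂ ind⁻¹ min⁻¹), then / mean larval volume
(nmol O₂ mm⁻³ min⁻¹). Blanks are averaged per plate. Gross photosynthesis =
net P + R; P:R = gross/R, flagged undefined at R = 0.

Scalar calculators: chlorophyll a = (11.43·E₆₆₃ − 0.64·E₆₃₀)/0.584 and
c₂ = (27.09·E₆₃₀ − 3.63·E₆₆₃)/0.584 (dinoflagellate equations, 96-well path
correction); larval volume V = (4/3)π·a·b² with a = width/2, b = length/2
(the source formula's typography is ambiguous about which semi-axis is
squared; the printed reading a·b² is implemented — note the two agree for the
equal-axis case used to estimate measurement uncertainty); settlement
proportion; larvae-per-ml density.

## Synthetic-data generator

The generator defines the study conditions the validation studies run under.

**Labeling model.** Molecules are a two-population mixture: a fraction
`labeled_fraction` newly synthesized from photosynthetically fixed carbon,
each carbon independently ¹³C with probability `p_atom`; the rest unlabeled.
True enrichment is therefore `labeled_fraction × p_atom` exactly. The
mixture pmf is convolved with the natural-abundance matrix, scaled by a
per-sample lognormal pool, and each isotopologue intensity receives
multiplicative lognormal noise (both lognormals mean-corrected so expected
values equal the configured ones). Dark and ¹²C samples have
`labeled_fraction = 0`.

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| design | 6 labeled-light + 6 unlabeled-light + 2 dark vials per temperature | the experimental design being emulated |
| `p_atom` | 0.4 | with `labeled_fraction` 0.5 puts baseline enrichment at 0.2, the level of translocated glucose |
| `labeled_fraction` | 0.5 | half the pool turned over during a 4.5 h pulse |
| `pool_log_sigma` | 0.10 | within-treatment pool CV ~10%; vials pool ~200 larvae, and selection of a 10% pool fold change as discriminating is only possible at this precision |
| `pool_between_metabolite_sigma` | 1.0 | metabolite baselines span orders of magnitude, as LC-MS ion counts do |
| `noise_cv` | 0.15 | typical multiplicative LC-MS intensity noise |
| carbons | uniform 2–10 | range of the measured panel |

**Scenario configurations** (`scenario_config`) place a focal effect
(enrichment-only → quadrant i; pool-only → iv; both → ii; default relative
effect 0.5, the midpoint of the fold-change magnitudes the framework is
applied to) on top of a fixed backdrop: 19 of 60 metabolites respond to
temperature with mixed-sign effects of magnitude 0.1–1.0. The backdrop
reproduces the regime in which the selection rule operates — a broad
treatment response where roughly a third of the panel discriminates — which
matters because VIP is relative: against an all-null backdrop the global
tests have no power and the VIP threshold loses meaning.

**What the generator does not emulate**, hence what passing validation does
and does not show: no chromatographic co-elution or peak-picking errors, no
missing values or detection limits, no correlation between metabolites beyond
the shared treatment effect (real metabolic networks induce strong
correlation structure), no batch or tank effects, no multi-element isotope
interference, and identical `p_atom` across metabolites (real precursor pools
differ). Passing shows the statistical machinery is correct and calibrated
under its stated model; it does not certify performance under real matrix
effects.

**Oxygen traces**: linear decline + optional exponential equilibration head
(time constant one third of the head duration, so the artifact is negligible
past it) + Gaussian noise (default 0.5 µmol L⁻¹ at 15 s cadence over 30 min).

## Validation studies (what `scripts/acceptance.py` recomputes)

All studies are seeded from the single `--seed`. Problem sizes were chosen as
the smallest that make the checks statistically meaningful: 200 round-trip
vectors; 30 samples per labeling probability; 200 null PERMANOVA datasets of
12 vs 12 samples × 50 metabolites at 199 permutations (type-I error compared
against the exact binomial 95% band); 20 random PLS-DA fits for the VIP
identity; 50 pipeline replicates per quadrant scenario; 100 oxygen traces;
20 random formula inputs.

## Known limitations

- Carbon-only correction; high-resolution merging effects are not modeled.
- PERMANOVA supports at most two crossed factors; no nested/random effects
  (mixed-model variants are deliberately out of scope — fixed-effects ANOVA
  is used throughout).
- The VIP gate makes selection conditional on a global test; studies with
  very sparse signals (one affected metabolite in a large panel) will
  correctly report "no multivariate separation" rather than hunting for the
  single variable — use univariate contrasts for that question.
- `marginal_means_contrasts` operates on cell means with pooled variance; it
  does not handle continuous covariates.
- Enrichment fold changes are undefined for metabolites with zero ambient
  enrichment; such metabolites are excluded from quadrant calls.
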