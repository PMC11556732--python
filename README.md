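# coraltrace

¹³C stable-isotope tracing metabolomics and physiology pipeline for symbiotic
coral larvae.

## The scientific problem

Reef-building corals receive most of their energy as fixed-carbon
photosynthates (chiefly glucose) translocated from their intracellular algal
symbionts (Symbiodiniaceae). Thermal stress can break this nutritional
exchange — the root of coral bleaching. A direct way to measure the exchange
is a ¹³C bicarbonate pulse: the symbiont fixes labeled inorganic carbon
through photosynthesis, and labeled metabolites appearing in host tissue trace
translocation and downstream metabolism. `coraltrace` implements the complete
analysis of such an experiment for coral larvae reared at ambient versus
elevated (+2.5 °C) temperature, from raw isotopologue ion counts to pathway-
level interpretation, plus the accompanying respirometry and physiology
calculations.

The package is aimed at researchers analyzing MAVEN-style LC-MS isotopologue
exports (long-format CSV), oxygen-microplate respirometry traces, and scalar
physiological assays — with a synthetic-data generator so every stage can be
exercised and validated without any experimental download.

## The quantities at the core

For a metabolite with *n* carbons, the observed spectrum of mass shifts
M+0…M+n is the true labeled-carbon-count distribution blurred by natural
abundance: a molecule with *j* tracer labels is seen at shift *k ≥ j* with
probability C(n−j, k−j)·p^(k−j)·(1−p)^(n−k), p = 0.0107. `coraltrace` inverts
this by non-negative least squares, yielding corrected fractions *f₀…fₙ*,
from which three response variables follow:

- **pool size** — total ion count, median-normalized per sample and
  ln(x+1)-transformed;
- **¹³C enrichment** — Σᵢ i·fᵢ / n, the labeled fraction of all carbon atoms;
- **carbon-specific enrichment** — fᵢ, the fraction of molecules with exactly
  *i* labels.

Treatment effects are tested with Euclidean-distance PERMANOVA (sequential
sums of squares, 999 free permutations, p = (#{F\* ≥ F} + 1)/(n_perm + 1)),
then decomposed per metabolite with a two-group NIPALS PLS-DA;
VIP_j = √(p·Σ_a SSY_a w²_aj / Σ_a SSY_a) with selection at VIP ≥ 1. Selected
metabolites are classified on the pool-size × enrichment plane: raised
enrichment at stable pool = rapid **turnover** (quadrant i); raised pool at
stable enrichment = **accumulation** from reduced downstream use (iv); both
raised = synthesis outpacing consumption (ii); both reduced = suppressed
biosynthesis (iii). Methodological controls (¹²C vs ¹³C pools, light vs dark
enrichment, label-saturation series) use factorial ANOVA, estimated-marginal-
means contrasts, and Benjamini–Hochberg FDR.

Respirometry slopes come from exhaustive local linear regressions ranked by
the percentile-rank combination of residual skewness, relative slope-CI width,
and window length (α = 0.4 minimum window fraction), then blank-corrected and
normalized per individual and per mm³ larval volume.

## Worked example

```sh
coraltrace simulate --seed 4 --n-metabolites 6 \
    --out-spectra spectra.csv --out-metadata metadata.csv
coraltrace run-all spectra.csv metadata.csv --seed 4 --out-dir results/
```

prints (stderr shows the seed; stdout the run summary):

```json
{
  "version": "0.1.0",
  "seed": 4,
  "n_samples": 28,
  "n_metabolites": 6,
  "permanova_pool_p": 0.61,
  "permanova_enrichment_p": 0.753,
  "n_pool_vips": 0,
  "n_enrichment_vips": 0
}
```

This simulated dataset has no treatment effect, and the pipeline says so: the
pool-size PERMANOVA p-value (0.61) and the enrichment p-value (0.753) are
both above 0.05, so no metabolite is reported as discriminating (zero VIPs
selected) — the supervised PLS-DA step is only trusted when the unsupervised
test shows real multivariate separation. `results/` contains tidy CSVs
(enrichment, normalized pools, PERMANOVA tables, VIP tables with fold
changes, quadrant calls, light-vs-dark control) and `run_report.json`
recording the seed and every setting in force.

The same analyses are available as a library:

```python
import coraltrace as ct

spectra, metadata, truth = ct.simulate_isotopologue_dataset(
    ct.SimulationConfig(seed=4, n_metabolites=6))
result = ct.run_pipeline(spectra, metadata, ct.RunConfig(seed=4))
print(result.quadrant_calls)
```

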