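"""Simulation studies validating the pipeline end to end.

Each routine generates its own inputs from a seed, runs the package's public
surface, and returns the measured quantity; they power both the acceptance
checks and ad-hoc method validation at the console.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .isotope import (
    IsotopologueSpectrum,
    NaturalAbundanceModel,
    convolve_natural_abundance,
    correct_natural_abundance,
    enrichment,
)
from .multivariate import euclidean_distances, permanova, plsda_fit, vip_scores
from .physiology import (
    chlorophyll,
    extract_rate,
    larval_volume,
    normalize_rate,
    photosynthesis_metrics,
)
from .pipeline import RunConfig, run_pipeline
from .synth import scenario_config, simulate_isotopologue_dataset, simulate_oxygen_trace

__all__ = [
    "deconvolution_roundtrip_error",
    "enrichment_calibration",
    "permanova_null_rejection_rate",
    "vip_normalization_deviation",
    "quadrant_recovery_rate",
    "rate_extraction_error",
    "formula_oracle_error",
]


def deconvolution_roundtrip_error(n_vectors: int = 200, seed: int = 0,
                                  max_carbons: int = 10) -> float:
    """Max abs error recovering random true isotopologue vectors after
    convolving with the natural-abundance matrix and deconvolving."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, max_carbons + 1))
        true = rng.dirichlet(np.ones(n + 1))
        model = NaturalAbundanceModel(float(rng.uniform(0.001, 0.2)))
        observed = convolve_natural_abundance(true, model)
        sp = IsotopologueSpectrum("m", n, tuple(observed), "s")
        got = np.asarray(correct_natural_abundance(sp, model).fractions)
        worst = max(worst, float(np.abs(got - true).max()))
    return worst


def enrichment_calibration(qs=(0.0, 0.1, 0.2, 0.5, 1.0), n_samples: int = 30,
                           n_carbons: int = 6, noise_cv: float = 0.15,
                           seed: int = 0) -> pd.DataFrame:
    """Mean corrected enrichment (with SE) of Binomial(n, q)-labeled spectra
    under multiplicative intensity noise, per atom-labeling probability q."""
    rng = np.random.default_rng(seed)
    rows = []
    for q in qs:
        pmf = stats.binom.pmf(np.arange(n_carbons + 1), n_carbons, q)
        vals = []
        for _ in range(n_samples):
            noise = np.exp(rng.normal(0.0, noise_cv, n_carbons + 1))
            observed = convolve_natural_abundance(pmf) * noise
            sp = IsotopologueSpectrum("m", n_carbons, tuple(observed), "s")
            vals.append(enrichment(correct_natural_abundance(sp)).enrichment)
        vals = np.asarray(vals)
        rows.append({"q": q, "mean": vals.mean(),
                     "se": vals.std(ddof=1) / np.sqrt(len(vals))})
    return pd.DataFrame(rows)


def permanova_null_rejection_rate(n_datasets: int = 200, n_per_group: int = 12,
                                  n_metabolites: int = 50, n_perm: int = 199,
                                  alpha: float = 0.05, seed: int = 0) -> float:
    """Type-I error of the treatment PERMANOVA on pure-noise data."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    rejections = 0
    for i in range(n_datasets):
        X = pd.DataFrame(rng.normal(size=(n, n_metabolites)),
                         index=[f"s{j}" for j in range(n)])
        design = pd.DataFrame({"g": ["a"] * n_per_group + ["b"] * n_per_group},
                              index=X.index)
        res = permanova(euclidean_distances(X), design, factors=["g"],
                        n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.terms[0].p <= alpha
    return rejections / n_datasets


def vip_normalization_deviation(n_models: int = 20, seed: int = 0) -> float:
    """Max |mean(VIP^2) - 1| over PLS-DA fits to random two-group data."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_models):
        n = int(rng.integers(10, 30)) * 2
        p = int(rng.integers(5, 40))
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         index=[f"s{i}" for i in range(n)])
        labels = pd.Series(["a"] * (n // 2) + ["b"] * (n // 2), index=X.index)
        X.iloc[n // 2:, 0] += rng.uniform(0, 2)
        table = vip_scores(plsda_fit(X, labels))
        worst = max(worst, abs(float((table["vip"] ** 2).mean()) - 1.0))
    return worst


def quadrant_recovery_rate(kind: str, n_replicates: int = 50, seed: int = 0,
                           n_perm: int = 199, effect: float = 0.5) -> float:
    """Fraction of seeded replicates in which the full pipeline classifies the
    focal metabolite of a named scenario into its expected quadrant."""
    expected = {"turnover": "i", "accumulation": "iv", "both": "ii"}[kind]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        sim_seed = int(rng.integers(2**31))
        cfg = scenario_config(kind, seed=sim_seed, effect=effect)
        spectra, metadata, _ = simulate_isotopologue_dataset(cfg)
        run = RunConfig(seed=int(rng.integers(2**31)), n_permutations=n_perm)
        result = run_pipeline(spectra, metadata, run)
        call = result.quadrant_calls.set_index("metabolite_id").loc["met00", "quadrant"]
        hits += call == expected
    return hits / n_replicates


def rate_extraction_error(n_traces: int = 100, true_slope: float = -0.5,
                          noise_sd: float = 0.5, equilibration_fraction: float = 0.2,
                          seed: int = 0) -> float:
    """Mean absolute relative slope error over simulated oxygen traces with
    equilibration artifacts."""
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_traces):
        tr = simulate_oxygen_trace(true_slope, noise_sd=noise_sd,
                                   equilibration_fraction=equilibration_fraction,
                                   seed=int(rng.integers(2**31)))
        est = extract_rate(tr)
        errs.append(abs(est.slope - true_slope) / abs(true_slope))
    return float(np.mean(errs))


def formula_oracle_error(n_inputs: int = 20, seed: int = 0) -> float:
    """Max relative error of the scalar calculators against independent
    hand-written evaluations at random inputs."""
    rng = np.random.default_rng(seed)
    worst = 0.0

    def rel(a, b):
        return abs(a - b) / max(abs(b), 1e-12)

    for _ in range(n_inputs):
        e663, e630 = rng.uniform(0.0, 1.5, 2)
        out = chlorophyll(e663, e630)
        worst = max(worst, rel(out["chl_a"], (11.43 * e663 - 0.64 * e630) / 0.584))
        worst = max(worst, rel(out["chl_c2"], (27.09 * e630 - 3.63 * e663) / 0.584))

        length, width = rng.uniform(0.05, 0.5, 2)
        worst = max(worst, rel(larval_volume(length, width),
                               4.0 / 3.0 * np.pi * (width / 2) * (length / 2) ** 2))

        net_p, resp = rng.uniform(0.0, 2.0, 2)
        out = photosynthesis_metrics(net_p, resp)
        worst = max(worst, rel(out["gross_p"], net_p + resp))
        worst = max(worst, rel(out["p_to_r"], (net_p + resp) / resp))

        raw, blank = -rng.uniform(0.1, 1.0), -rng.uniform(0.0, 0.2)
        vol, n_ind = rng.uniform(50e-6, 100e-6), int(rng.integers(1, 10))
        got = normalize_rate(raw, blank, vol, n_ind)["per_individual_nmol_min"]
        worst = max(worst, rel(got, (raw - blank) * vol / n_ind * 1000.0))
    return worst
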