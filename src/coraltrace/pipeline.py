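"""End-to-end orchestration of the tracing analysis.

Order of operations mirrors the study workflow: natural-abundance correction of
every spectrum; enrichment and pool-size tables; median normalization and
log(x+1); PERMANOVA of treatment separation for pool size and enrichment
(labeled light samples); PLS-DA with VIP selection and fold changes for both
metrics; four-quadrant classification and pathway summary; methodological
controls (isotope x temperature PERMANOVA on pools, light-vs-dark enrichment
validation) when control samples are present.

VIP-based selection is applied only when the corresponding global PERMANOVA is
significant — the supervised model is fitted conditional on evidence of
multivariate separation, so a null metric yields no selected metabolites.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .controls import fdr_adjust, light_dark_validation, two_way_anova
from .flux import classify_table, load_pathways, pathway_report
from .io import spectra_from_frame, write_tidy_csv
from .isotope import (DEFAULT_P13C, NaturalAbundanceModel,
                      correct_natural_abundance, enrichment)
from .multivariate import euclidean_distances, permanova, plsda_fit, vip_scores
from .pools import PoolMatrix, fold_change_table, log1p_transform, median_normalize

logger = logging.getLogger("coraltrace")

__all__ = ["RunConfig", "PipelineResult", "correct_dataset", "corrected_fractions",
           "carbon_specific_analysis", "analyze_treatment_effects", "run_pipeline"]


@dataclass
class RunConfig:
    """Settings for a full pipeline run; defaults match the study's analysis
    settings (VIP >= 1, Euclidean distances with 999 permutations,
    natural-abundance 0.0107)."""

    seed: int
    vip_threshold: float = 1.0
    n_permutations: int = 999
    p13c: float = DEFAULT_P13C
    significance_alpha: float = 0.05
    require_global_significance: bool = True
    n_components: int = 2
    output_dir: str | None = None
    pathway_csv: str | None = None


@dataclass
class PipelineResult:
    enrichment: pd.DataFrame
    pool_raw: PoolMatrix
    pool_log: PoolMatrix
    permanova_pool: pd.DataFrame
    permanova_enrichment: pd.DataFrame
    vip_pool: pd.DataFrame
    vip_enrichment: pd.DataFrame
    quadrant_calls: pd.DataFrame
    pathway_summary: pd.DataFrame
    carbon_specific: pd.DataFrame | None = None
    controls: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def correct_dataset(
    spectra_frame: pd.DataFrame, p13c: float = DEFAULT_P13C
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correct every spectrum; return (enrichment tidy frame, pool wide frame).

    Pool size is the total ion count across isotopologues per metabolite per
    sample. Enrichment comes from the corrected fractions.
    """
    model = NaturalAbundanceModel(p13c)
    spectra = spectra_from_frame(spectra_frame)
    enr_rows = []
    for sp in spectra:
        dist = correct_natural_abundance(sp, model)
        ev = enrichment(dist)
        enr_rows.append({"metabolite": sp.metabolite_id, "sample": sp.sample_id,
                         "enrichment": ev.enrichment, "pool": sp.total})
    tidy = pd.DataFrame(enr_rows)
    pools = tidy.pivot(index="sample", columns="metabolite", values="pool")
    return tidy[["metabolite", "sample", "enrichment"]], pools


def corrected_fractions(
    spectra_frame: pd.DataFrame, p13c: float = DEFAULT_P13C
) -> pd.DataFrame:
    """Tidy carbon-specific enrichment: one row per (metabolite, sample,
    labeled-carbon count) with the corrected fraction."""
    model = NaturalAbundanceModel(p13c)
    rows = []
    for sp in spectra_from_frame(spectra_frame):
        dist = correct_natural_abundance(sp, model)
        for i, f in enumerate(dist.fractions):
            rows.append({"metabolite": sp.metabolite_id, "sample": sp.sample_id,
                         "carbons_labeled": i, "fraction": f})
    return pd.DataFrame(rows)


def carbon_specific_analysis(
    fractions: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-metabolite factorial ANOVA of carbon-specific enrichment.

    Tests, for each metabolite of the labeled light samples, whether the
    distribution of labeled-carbon counts shifts between treatments: two-way
    ANOVA with labeled-carbon count and treatment as main effects plus their
    interaction (the interaction is the question of interest), p-values
    BH-FDR-adjusted across metabolites.
    """
    labeled = metadata[(metadata["isotope"] == "13C") & (metadata["light"] == "light")]
    sub = fractions[fractions["sample"].isin(labeled.index)].copy()
    sub["treatment"] = labeled.loc[sub["sample"], "treatment"].to_numpy()
    rows = []
    for met, grp in sub.groupby("metabolite"):
        table = two_way_anova(grp["fraction"], grp["carbons_labeled"],
                              grp["treatment"], interaction=True,
                              names=("carbons", "treatment"))
        terms = table.terms.set_index("term")
        rows.append({
            "metabolite": met,
            "p_carbons": terms.loc["carbons", "p"],
            "p_treatment": terms.loc["treatment", "p"],
            "p_interaction": terms.loc["carbons:treatment", "p"],
        })
    out = pd.DataFrame(rows)
    for col in ("p_carbons", "p_treatment", "p_interaction"):
        out[f"{col}_adj"] = fdr_adjust(out[col].to_numpy())
    return out


def _vip_with_gate(
    X: pd.DataFrame, labels: pd.Series, config: RunConfig, permanova_p: float
) -> pd.DataFrame:
    model = plsda_fit(X, labels, n_components=config.n_components)
    table = vip_scores(model, threshold=config.vip_threshold)
    gated = (not config.require_global_significance) or permanova_p <= config.significance_alpha
    if not gated:
        table["selected"] = False
    table.attrs["explained_x_variance"] = model.explained_x_variance.tolist()
    table.attrs["globally_significant"] = bool(gated)
    return table


def analyze_treatment_effects(
    enrichment_tidy: pd.DataFrame,
    pools_raw: pd.DataFrame,
    metadata: pd.DataFrame,
    config: RunConfig,
) -> PipelineResult:
    """Treatment comparison on labeled light samples + quadrant classification."""
    labeled = metadata[(metadata["isotope"] == "13C") & (metadata["light"] == "light")]
    if labeled["treatment"].nunique() != 2:
        raise ValueError("treatment comparison requires two treatment levels")
    samples = [s for s in pools_raw.index if s in labeled.index]

    pool_raw = PoolMatrix(pools_raw.loc[samples])
    pool_norm = median_normalize(pool_raw)
    pool_log = log1p_transform(pool_norm)
    enr_wide = (enrichment_tidy.pivot(index="sample", columns="metabolite",
                                      values="enrichment").loc[samples])
    labels = labeled.loc[samples, "treatment"]

    perm_pool = permanova(euclidean_distances(pool_log), labeled.loc[samples],
                          factors=["treatment"], n_perm=config.n_permutations,
                          seed=config.seed)
    perm_enr = permanova(euclidean_distances(enr_wide), labeled.loc[samples],
                         factors=["treatment"], n_perm=config.n_permutations,
                         seed=config.seed + 1)

    vip_pool = _vip_with_gate(pool_log.values, labels, config,
                              perm_pool.terms[0].p)
    vip_enr = _vip_with_gate(enr_wide, labels, config, perm_enr.terms[0].p)

    # fold changes on median-normalized pools and raw enrichment proportions
    fc_pool = fold_change_table(pool_norm.values, labels)
    fc_enr_vals = {}
    for met in enr_wide.columns:
        amb = enr_wide.loc[labels == "ambient", met].mean()
        high = enr_wide.loc[labels == "high", met].mean()
        fc_enr_vals[met] = (high - amb) / amb if amb > 0 else np.nan
    fc_enr = pd.Series(fc_enr_vals)

    finite = [m for m in enr_wide.columns if np.isfinite(fc_enr[m])]
    calls = classify_table(
        vip_pool[vip_pool["metabolite"].isin(finite)], fc_pool,
        vip_enr[vip_enr["metabolite"].isin(finite)], fc_enr,
    )
    annotations = load_pathways(config.pathway_csv)
    annotated = calls[calls["metabolite_id"].isin(annotations["metabolite"])]
    summary = pathway_report(annotated, annotations) if len(annotated) else pd.DataFrame()

    vip_pool = vip_pool.merge(fc_pool.rename("fold_change"), left_on="metabolite",
                              right_index=True)
    vip_enr = vip_enr.merge(fc_enr.rename("fold_change"), left_on="metabolite",
                            right_index=True)

    return PipelineResult(
        enrichment=enrichment_tidy,
        pool_raw=pool_raw,
        pool_log=pool_log,
        permanova_pool=perm_pool.to_frame(),
        permanova_enrichment=perm_enr.to_frame(),
        vip_pool=vip_pool,
        vip_enrichment=vip_enr,
        quadrant_calls=calls,
        pathway_summary=summary,
    )


def run_pipeline(
    spectra_frame: pd.DataFrame,
    metadata: pd.DataFrame,
    config: RunConfig,
) -> PipelineResult:
    """Full analysis from a long-format isotopologue table + metadata.

    Deterministic given ``config.seed``. When ``config.output_dir`` is set,
    tidy CSVs and a JSON run report are written there.
    """
    orphans = sorted(set(spectra_frame["sample"]) - set(metadata.index))
    if orphans:
        raise ValueError(f"samples present in data but not in metadata: {orphans}")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate failures with the stage name
            raise type(exc)(f"[stage: {name}] {exc}") from exc

    enr_tidy, pools = stage("correction", correct_dataset, spectra_frame, config.p13c)
    result = stage("treatment-analysis", analyze_treatment_effects,
                   enr_tidy, pools, metadata, config)
    fractions = stage("carbon-specific", corrected_fractions, spectra_frame, config.p13c)
    result.carbon_specific = stage("carbon-specific", carbon_specific_analysis,
                                   fractions, metadata)

    controls: dict = {}
    has_12c = (metadata["isotope"] == "12C").any()
    has_dark = (metadata["light"] == "dark").any()
    if has_12c:
        light = metadata[metadata["light"] == "light"]
        samples = [s for s in pools.index if s in light.index]
        pool_log = log1p_transform(median_normalize(PoolMatrix(pools.loc[samples])))
        controls["permanova_isotope_temperature"] = stage(
            "isotope-control", permanova,
            euclidean_distances(pool_log), light.loc[samples],
            factors=["isotope", "treatment"], interaction=True,
            n_perm=config.n_permutations, seed=config.seed + 2,
        ).to_frame()
    if has_dark:
        labeled = metadata[metadata["isotope"] == "13C"]
        sub = enr_tidy[enr_tidy["sample"].isin(labeled.index)]
        controls["light_dark"] = stage("light-dark", light_dark_validation, sub, labeled)
    result.controls = controls

    result.report = {
        "version": __version__,
        "seed": config.seed,
        "settings": asdict(config),
        "n_samples": int(metadata.shape[0]),
        "n_metabolites": int(pools.shape[1]),
        "permanova_pool_p": float(result.permanova_pool.iloc[0]["p"]),
        "permanova_enrichment_p": float(result.permanova_enrichment.iloc[0]["p"]),
        "n_pool_vips": int(result.vip_pool["selected"].sum()),
        "n_enrichment_vips": int(result.vip_enrichment["selected"].sum()),
        "design_decisions": [
            "carbon-only binomial natural-abundance correction (NNLS deconvolution)",
            "median normalization per sample, natural-log(x+1) transform",
            "fold change = relative difference (high - ambient) / ambient",
            "sequential-SS PERMANOVA, free permutations, +1 p correction",
            "NIPALS PLS-DA on autoscaled X, 2 components, VIP >= threshold",
            "VIP selection gated on global PERMANOVA significance",
        ],
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tidy_csv(result.enrichment, out / "enrichment.csv")
        write_tidy_csv(result.pool_log.values.reset_index(names="sample"),
                       out / "pool_log.csv")
        write_tidy_csv(result.permanova_pool, out / "permanova_pool.csv")
        write_tidy_csv(result.permanova_enrichment, out / "permanova_enrichment.csv")
        write_tidy_csv(result.vip_pool, out / "vip_pool.csv")
        write_tidy_csv(result.vip_enrichment, out / "vip_enrichment.csv")
        write_tidy_csv(result.quadrant_calls, out / "quadrant_calls.csv")
        write_tidy_csv(result.pathway_summary, out / "pathway_summary.csv")
        write_tidy_csv(result.carbon_specific, out / "carbon_specific_anova.csv")
        for name, frame in controls.items():
            write_tidy_csv(frame, out / f"control_{name}.csv")
        with open(out / "run_report.json", "w") as fh:
            json.dump(result.report, fh, indent=2, default=str)
        logger.info("pipeline outputs written to %s", out)
    return result
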