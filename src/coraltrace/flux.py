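"""Joint pool-size / enrichment interpretation: the four-quadrant turnover
framework and pathway summaries.

A metabolite whose pool grows without a matching rise in tracer enrichment is
accumulating because downstream consumption slowed; one whose enrichment rises
at stable pool size is turning over rapidly (synthesis matched by consumption).
Crossing the two axes gives four interpretable quadrants:

==========  =========  ===========  =============================================
quadrant    pool       enrichment   interpretation
==========  =========  ===========  =============================================
i           low/stable high         turnover
ii          high       high         synthesis exceeding downstream use
iii         low        low/stable   low biosynthesis and low downstream metabolism
iv          high       low/stable   accumulation from reduced downstream metabolism
==========  =========  ===========  =============================================

"high"/"low" are gated on VIP selection (VIP >= 1) plus the sign of the
between-treatment fold change; a metric that is not selected is treated as
stable. No numeric fold-change threshold is applied beyond the sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

QUADRANT_LABELS = {
    "i": "turnover",
    "ii": "synthesis exceeding downstream use",
    "iii": "low biosynthesis and low downstream metabolism",
    "iv": "accumulation from reduced downstream metabolism",
    "null_call": "no treatment effect detected",
}

PATHWAYS = (
    "glycolysis_central_carbon",
    "pentose_phosphate",
    "tca",
    "ammonium_assimilation",
    "urea_cycle",
    "dipeptide",
)

__all__ = ["QuadrantCall", "QUADRANT_LABELS", "PATHWAYS", "classify_quadrant",
           "classify_table", "load_pathways", "pathway_report"]


@dataclass(frozen=True)
class QuadrantCall:
    metabolite_id: str
    pool_fc: float
    pool_selected: bool
    enr_fc: float
    enr_selected: bool
    quadrant: str
    label: str


def _direction(fc: float, selected: bool, metabolite_id: str, metric: str) -> str:
    if not selected:
        return "stable"
    if fc > 0:
        return "high"
    if fc < 0:
        return "low"
    warnings.warn(
        f"{metabolite_id}: {metric} selected but fold change is exactly 0; "
        "treated as stable",
        stacklevel=3,
    )
    return "stable"


def classify_quadrant(
    metabolite_id: str,
    pool_fc: float,
    pool_selected: bool,
    enr_fc: float,
    enr_selected: bool,
) -> QuadrantCall:
    """Classify one metabolite into the four-quadrant framework.

    Total over all nine (pool, enrichment) direction states:
    both stable -> null_call; high/high -> ii; high with low-or-stable
    enrichment -> iv; high enrichment with low-or-stable pool -> i; every
    remaining combination involving a "low" call -> iii.
    """
    for name, fc in (("pool", pool_fc), ("enrichment", enr_fc)):
        if not pd.notna(fc) or fc in (float("inf"), float("-inf")):
            raise ValueError(f"{metabolite_id}: non-finite {name} fold change")
    pool = _direction(pool_fc, pool_selected, metabolite_id, "pool size")
    enr = _direction(enr_fc, enr_selected, metabolite_id, "enrichment")
    if pool == "stable" and enr == "stable":
        quadrant = "null_call"
    elif pool == "high" and enr == "high":
        quadrant = "ii"
    elif pool == "high":
        quadrant = "iv"
    elif enr == "high":
        quadrant = "i"
    else:
        quadrant = "iii"
    return QuadrantCall(
        metabolite_id=metabolite_id,
        pool_fc=float(pool_fc),
        pool_selected=bool(pool_selected),
        enr_fc=float(enr_fc),
        enr_selected=bool(enr_selected),
        quadrant=quadrant,
        label=QUADRANT_LABELS[quadrant],
    )


def classify_table(
    pool_vip: pd.DataFrame,
    pool_fc: pd.Series,
    enr_vip: pd.DataFrame,
    enr_fc: pd.Series,
) -> pd.DataFrame:
    """Vectorized quadrant calls from VIP tables (metabolite, vip, selected)
    and per-metabolite fold-change series. Metabolites present in both the
    pool and enrichment tables are classified."""
    pool_vip = pool_vip.set_index("metabolite")
    enr_vip = enr_vip.set_index("metabolite")
    common = [m for m in pool_vip.index if m in enr_vip.index]
    calls = [
        classify_quadrant(
            m,
            float(pool_fc[m]),
            bool(pool_vip.loc[m, "selected"]),
            float(enr_fc[m]),
            bool(enr_vip.loc[m, "selected"]),
        )
        for m in common
    ]
    return pd.DataFrame([c.__dict__ for c in calls])


def load_pathways(path: str | None = None) -> pd.DataFrame:
    """Pathway membership table (metabolite, pathway). Ships with the carbon
    and nitrogen pathways of interest; pass ``path`` to use a custom table.
    A metabolite may belong to several pathways (e.g. pyruvate)."""
    if path is not None:
        table = pd.read_csv(path)
    else:
        with resources.files("coraltrace.data").joinpath("pathways.csv").open() as fh:
            table = pd.read_csv(fh)
    missing = {"metabolite", "pathway"} - set(table.columns)
    if missing:
        raise ValueError(f"pathway table missing columns: {sorted(missing)}")
    return table


def _percent(fc: float, selected: bool) -> str:
    if not selected:
        return ""
    return f"{fc * 100:+.0f}%"


def pathway_report(calls: pd.DataFrame, annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-pathway summary: one row per (metabolite, pathway) with direction
    (high / low / stable, relative to the elevated treatment) and signed percent
    change for each metric. Metabolites without a pathway annotation are
    excluded with a warning."""
    annotations = annotations if annotations is not None else load_pathways()
    merged = calls.merge(annotations, left_on="metabolite_id", right_on="metabolite", how="left")
    orphans = sorted(merged.loc[merged["pathway"].isna(), "metabolite_id"].unique())
    if orphans:
        warnings.warn(f"metabolites without pathway annotation excluded: {orphans}", stacklevel=2)
        merged = merged.dropna(subset=["pathway"])
    rows = []
    for _, r in merged.iterrows():
        pool_dir = _direction(r.pool_fc, r.pool_selected, r.metabolite_id, "pool size")
        enr_dir = _direction(r.enr_fc, r.enr_selected, r.metabolite_id, "enrichment")
        rows.append({
            "pathway": r.pathway,
            "metabolite": r.metabolite_id,
            "pool_direction": pool_dir,
            "pool_percent": _percent(r.pool_fc, pool_dir != "stable"),
            "enrichment_direction": enr_dir,
            "enrichment_percent": _percent(r.enr_fc, enr_dir != "stable"),
            "quadrant": r.quadrant,
        })
    return pd.DataFrame(rows, columns=["pathway", "metabolite", "pool_direction",
                                       "pool_percent", "enrichment_direction",
                                       "enrichment_percent", "quadrant"])
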