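"""Methodological-control statistics: factorial ANOVA, marginal-means
contrasts, FDR adjustment, light-vs-dark enrichment validation, and the
label-saturation time series.

The tracing design carries three internal controls: (1) unlabeled (12C) light
incubations confirm the label itself does not perturb pool sizes; (2) dark
labeled incubations confirm that enrichment requires photosynthesis — carbon
fixed by the symbiont and translocated to the host — rather than passive
uptake; (3) a 1-24 h saturation series confirms that the incubation time sits
at peak label incorporation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaTable",
    "ContrastResult",
    "two_way_anova",
    "marginal_means_contrasts",
    "fdr_adjust",
    "light_dark_validation",
    "label_saturation",
]


@dataclass(frozen=True)
class AnovaTable:
    """Factorial ANOVA summary: one row per term plus the residual."""

    terms: pd.DataFrame  # columns: term, df, ss, ms, F, p
    residual_df: int
    residual_ss: float

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df


def _balanced(frame: pd.DataFrame, interaction: bool) -> None:
    cells = frame.groupby(["_a", "_b"], observed=True).size()
    n_a = frame["_a"].nunique()
    n_b = frame["_b"].nunique()
    if interaction and len(cells) < n_a * n_b:
        raise ValueError("empty factor cell with interaction requested")


def two_way_anova(
    response: np.ndarray | pd.Series,
    factor_a: np.ndarray | pd.Series,
    factor_b: np.ndarray | pd.Series,
    interaction: bool = True,
    names: tuple[str, str] = ("a", "b"),
) -> AnovaTable:
    """Least-squares factorial ANOVA with Type II sums of squares.

    Balanced designs reproduce the classical decomposition (Types I/II/III
    coincide). Residual df must be positive.
    """
    frame = pd.DataFrame({
        "_y": np.asarray(response, dtype=float),
        "_a": pd.Categorical(np.asarray(factor_a).astype(str)),
        "_b": pd.Categorical(np.asarray(factor_b).astype(str)),
    })
    if frame["_y"].isna().any():
        raise ValueError("response contains missing values")
    _balanced(frame, interaction)
    formula = "_y ~ C(_a) * C(_b)" if interaction else "_y ~ C(_a) + C(_b)"
    fit = smf.ols(formula, data=frame).fit()
    if fit.df_resid < 1:
        raise ValueError("residual degrees of freedom must be positive")
    table = sm.stats.anova_lm(fit, typ=2)
    rename = {"C(_a)": names[0], "C(_b)": names[1], "C(_a):C(_b)": f"{names[0]}:{names[1]}"}
    rows = []
    for idx, row in table.iterrows():
        if idx == "Residual":
            continue
        rows.append({
            "term": rename.get(idx, idx),
            "df": int(row["df"]),
            "ss": float(row["sum_sq"]),
            "ms": float(row["sum_sq"] / row["df"]),
            "F": float(row["F"]),
            "p": float(row["PR(>F)"]),
        })
    resid = table.loc["Residual"]
    return AnovaTable(pd.DataFrame(rows), int(resid["df"]), float(resid["sum_sq"]))


@dataclass(frozen=True)
class ContrastResult:
    by_level: str
    level_pair: tuple[str, str]
    estimate: float
    se: float
    t: float
    df: int
    p: float
    p_adj: float
    estimable: bool = True


def marginal_means_contrasts(
    response: np.ndarray | pd.Series,
    factor_by: np.ndarray | pd.Series,
    factor_contrast: np.ndarray | pd.Series,
    adjust: str = "tukey",
) -> list[ContrastResult]:
    """Cell-mean contrasts of the contrast factor within each level of the
    "by" factor, with pooled-variance standard errors from the full factorial
    fit and t-based p-values.

    ``adjust``: "tukey" (studentized range over the contrast-factor family
    within each by level), "sidak", "bonferroni", or "none". Contrasts touching
    an empty cell are returned flagged (``estimable=False``) rather than
    silently dropped.
    """
    if adjust not in ("tukey", "sidak", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    frame = pd.DataFrame({
        "y": np.asarray(response, dtype=float),
        "by": np.asarray(factor_by).astype(str),
        "con": np.asarray(factor_contrast).astype(str),
    })
    cells = frame.groupby(["by", "con"])["y"].agg(["mean", "count"])
    n_total = len(frame)
    n_cells = len(cells)
    ss_within = float(((frame["y"] - frame.groupby(["by", "con"])["y"].transform("mean")) ** 2).sum())
    df_resid = n_total - n_cells
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for pooled variance")
    mse = ss_within / df_resid
    con_levels = sorted(frame["con"].unique())
    k = len(con_levels)
    results: list[ContrastResult] = []
    for by_level in sorted(frame["by"].unique()):
        n_pairs = k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                pair = (con_levels[i], con_levels[j])
                try:
                    m1, n1 = cells.loc[(by_level, pair[0])]
                    m2, n2 = cells.loc[(by_level, pair[1])]
                except KeyError:
                    results.append(ContrastResult(by_level, pair, np.nan, np.nan,
                                                  np.nan, df_resid, np.nan, np.nan,
                                                  estimable=False))
                    continue
                est = float(m1 - m2)
                se = float(np.sqrt(mse * (1 / n1 + 1 / n2)))
                if se == 0:
                    t_stat = 0.0 if est == 0 else np.inf * np.sign(est)
                else:
                    t_stat = est / se
                p = float(2 * stats.t.sf(abs(t_stat), df_resid))
                if adjust == "tukey" and k > 2:
                    p_adj = float(stats.studentized_range.sf(abs(t_stat) * np.sqrt(2), k, df_resid))
                elif adjust == "sidak":
                    p_adj = float(1 - (1 - p) ** n_pairs)
                elif adjust == "bonferroni":
                    p_adj = float(min(1.0, p * n_pairs))
                else:  # "none", or tukey with a single pair (no family)
                    p_adj = p
                p_adj = max(p_adj, p) if np.isfinite(p_adj) else p
                results.append(ContrastResult(by_level, pair, est, se, float(t_stat),
                                              df_resid, p, min(p_adj, 1.0)))
    return results


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def light_dark_validation(
    enrichment: pd.DataFrame,
    metadata: pd.DataFrame,
    light_col: str = "light",
    light_value: str = "light",
    dark_value: str = "dark",
) -> pd.DataFrame:
    """Per-metabolite light-vs-dark enrichment comparison.

    ``enrichment``: tidy frame (metabolite, sample, enrichment) of labeled
    samples; ``metadata`` indexed by sample with a light/dark column. Returns,
    per metabolite, the light and dark means, the percent excess
    ``(light - dark) / light * 100`` (NaN-flagged when the light mean is not
    positive), and the contrast p-value FDR-adjusted across metabolites.
    """
    merged = enrichment.merge(
        metadata[[light_col]], left_on="sample", right_index=True, how="left"
    )
    if merged[light_col].isna().any():
        orphans = sorted(merged.loc[merged[light_col].isna(), "sample"].unique())
        raise ValueError(f"samples without light/dark metadata: {orphans}")
    merged = merged[merged[light_col].isin([light_value, dark_value])]
    present = merged.groupby(light_col, observed=True)["sample"].nunique()
    if present.get(light_value, 0) == 0 or present.get(dark_value, 0) == 0:
        raise ValueError("both light and dark samples are required")

    contrasts = marginal_means_contrasts(
        merged["enrichment"], merged["metabolite"], merged[light_col], adjust="none"
    )
    pmap = {c.by_level: c.p for c in contrasts if c.estimable}

    rows = []
    for met, sub in merged.groupby("metabolite"):
        light_mean = sub.loc[sub[light_col] == light_value, "enrichment"].mean()
        dark_mean = sub.loc[sub[light_col] == dark_value, "enrichment"].mean()
        if light_mean > 0:
            pct = (light_mean - dark_mean) / light_mean * 100.0
            flagged = False
        else:
            pct, flagged = np.nan, True
        rows.append({"metabolite": met, "light_mean": light_mean, "dark_mean": dark_mean,
                     "percent_excess": pct, "p": pmap.get(met, np.nan), "flagged": flagged})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["p_adj"] = np.nan
    if valid.any():
        out.loc[valid, "p_adj"] = fdr_adjust(out.loc[valid, "p"].to_numpy())
    return out


def label_saturation(
    times: np.ndarray | list[float],
    enrichment: pd.DataFrame,
) -> pd.DataFrame:
    """Peak label-incorporation window per metabolite from a time series.

    ``enrichment``: tidy frame (metabolite, time, enrichment); ``times`` lists
    the sampled time points (hours). Returns per metabolite the contiguous pair
    of sampled times bracketing the maximum mean enrichment, flagging monotone
    series (peak at a boundary, no interior maximum) and constant series.
    """
    times = np.asarray(sorted(times), dtype=float)
    if len(times) < 3:
        raise ValueError("at least 3 time points are required")
    rows = []
    for met, sub in enrichment.groupby("metabolite"):
        means = sub.groupby("time")["enrichment"].mean().reindex(times)
        if means.isna().any():
            raise ValueError(f"{met}: missing enrichment at some time points")
        vals = means.to_numpy()
        if np.ptp(vals) == 0:
            rows.append({"metabolite": met, "t_lo": times[0], "t_hi": times[1],
                         "flag": "degenerate_constant"})
            continue
        i = int(np.argmax(vals))
        if i == 0:
            rows.append({"metabolite": met, "t_lo": times[0], "t_hi": times[1],
                         "flag": "no_interior_peak"})
        elif i == len(times) - 1:
            rows.append({"metabolite": met, "t_lo": times[-2], "t_hi": times[-1],
                         "flag": "no_interior_peak"})
        else:
            # bracket on the side of the larger neighbor
            if vals[i - 1] >= vals[i + 1]:
                lo, hi = times[i - 1], times[i]
            else:
                lo, hi = times[i], times[i + 1]
            rows.append({"metabolite": met, "t_lo": lo, "t_hi": hi, "flag": ""})
    return pd.DataFrame(rows)
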