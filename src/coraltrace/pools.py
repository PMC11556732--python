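"""Metabolite pool sizes: normalization, transformation, group summaries.

Pool size is the total ion count of a metabolite in a sample (relative
abundance). Before between-treatment comparison each sample's intensities are
divided by that sample's median intensity across metabolites (compensating for
biomass differences between larval pools), then transformed as ln(x + 1).
Between-treatment differences are expressed as relative-difference fold change,
(high - ambient) / ambient, so fc = 0.10 reads as a 10% increase at high
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError

RAW = "raw"
MEDIAN_NORMALIZED = "median_normalized"
LOG1P = "log1p"

__all__ = [
    "PoolMatrix",
    "median_normalize",
    "log1p_transform",
    "fold_change",
    "fold_change_table",
    "group_means",
]


@dataclass(frozen=True)
class PoolMatrix:
    """Samples x metabolites pool-size matrix with a normalization state.

    ``values`` is a DataFrame indexed by sample id with metabolite-id columns.
    State transitions are one-way: raw -> median_normalized -> log1p.
    """

    values: pd.DataFrame
    state: str = RAW

    def __post_init__(self) -> None:
        if self.state not in (RAW, MEDIAN_NORMALIZED, LOG1P):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state in (RAW, MEDIAN_NORMALIZED) and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative pool values in state {self.state!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)


def median_normalize(pool: PoolMatrix) -> PoolMatrix:
    """Divide each sample's intensities by that sample's median across metabolites."""
    if pool.state != RAW:
        raise ValueError(f"median_normalize expects raw state, got {pool.state!r}")
    medians = pool.values.median(axis=1)
    zero = medians[medians <= 0]
    if len(zero):
        raise DegenerateDataError(
            f"zero or negative median intensity in sample(s): {', '.join(map(str, zero.index))}"
        )
    return PoolMatrix(pool.values.div(medians, axis=0), state=MEDIAN_NORMALIZED)


def log1p_transform(pool: PoolMatrix) -> PoolMatrix:
    """ln(x + 1) transform of a median-normalized matrix."""
    if pool.state != MEDIAN_NORMALIZED:
        raise ValueError(f"log1p_transform expects median_normalized state, got {pool.state!r}")
    if (pool.values.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log1p-transformed")
    return PoolMatrix(np.log1p(pool.values), state=LOG1P)


def fold_change(mean_ambient: float, mean_high: float) -> float:
    """Relative difference (high - ambient) / ambient; fc = 0.10 is a 10% increase."""
    if mean_ambient < 0 or mean_high < 0:
        raise ValueError("group means must be non-negative")
    if mean_ambient == 0:
        raise DegenerateDataError("ambient mean is zero; fold change undefined")
    return (mean_high - mean_ambient) / mean_ambient


def fold_change_table(
    values: pd.DataFrame,
    groups: pd.Series,
    baseline: str = "ambient",
    elevated: str = "high",
) -> pd.Series:
    """Per-metabolite fold change between two group means.

    ``values``: samples x metabolites; ``groups``: sample -> group level.
    """
    groups = groups.reindex(values.index)
    if groups.isna().any():
        missing = list(values.index[groups.isna()])
        raise ValueError(f"samples without group metadata: {missing}")
    mean_base = values.loc[groups == baseline].mean(axis=0)
    mean_elev = values.loc[groups == elevated].mean(axis=0)
    return pd.Series(
        [fold_change(a, h) for a, h in zip(mean_base, mean_elev)],
        index=values.columns,
        name="fold_change",
    )


def group_means(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Mean and standard error per metabolite per group level.

    Returns a tidy frame (metabolite, level, n, mean, se); se is NaN for
    single-observation levels.
    """
    groups = groups.reindex(values.index)
    if groups.isna().any():
        missing = list(values.index[groups.isna()])
        raise ValueError(f"samples without group metadata: {missing}")
    rows = []
    for level, sub in values.groupby(groups):
        n = len(sub)
        means = sub.mean(axis=0)
        se = sub.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else pd.Series(np.nan, index=values.columns)
        for met in values.columns:
            rows.append(
                {"metabolite": met, "level": level, "n": n,
                 "mean": float(means[met]), "se": float(se[met])}
            )
    return pd.DataFrame(rows)
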