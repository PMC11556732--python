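"""Respirometry rate extraction and scalar physiology calculators.

``extract_rate`` reproduces the local-linear-regression approach used for
sealed-well oxygen traces: every contiguous window covering at least a fraction
``alpha`` of the trace is fitted by ordinary least squares and windows are
ranked by the percentile-rank combination of three criteria — residual
skewness (linearity), relative width of the slope's 95% confidence interval
(precision), and window length (data usage). The best-ranked window's slope is
the metabolic rate. This discards equilibration artifacts at the start of a
trace without a hand-picked cutoff.

Rates are normalized to the well volume, blank-corrected, divided by the
number of individuals (nmol O2 individual^-1 min^-1), and optionally divided
by mean larval volume (nmol O2 mm^-3 min^-1). Oxygen consumption appears as a
negative raw slope; respiration is conventionally reported as the positive
magnitude of consumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "OxygenTrace",
    "RateEstimate",
    "extract_rate",
    "normalize_rate",
    "photosynthesis_metrics",
    "chlorophyll",
    "larval_volume",
    "settlement_proportion",
    "survival_density",
]


@dataclass(frozen=True)
class OxygenTrace:
    """Timestamped O2 concentrations for one well.

    times in minutes (strictly increasing), o2 in umol L^-1; n_individuals = 0
    marks a blank well.
    """

    times: np.ndarray
    o2: np.ndarray
    well_volume_l: float = 80e-6
    n_individuals: int = 0
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.o2, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and o2 must be 1-d arrays of equal length")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "o2", y)


@dataclass(frozen=True)
class RateEstimate:
    slope: float                 # umol L^-1 min^-1
    intercept: float
    window: tuple[int, int]      # (start index, stop index exclusive)
    diagnostics: dict
    degenerate: bool = False


def _window_stats(
    t: np.ndarray, y: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS over many contiguous windows via prefix sums.

    Returns (slope, intercept, slope SE, |residual skewness|) arrays. Residual
    second and third moments are polynomial in windowed sums of t^a * y^b, so
    every window is evaluated in O(1) after one pass over the trace. Inputs are
    centered globally first to keep the moment cancellations well conditioned.
    """
    t0 = t - t.mean()
    y0 = y - y.mean()

    def prefix(v: np.ndarray) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(v)])

    P = {key: prefix(val) for key, val in {
        "t": t0, "y": y0, "tt": t0 * t0, "ty": t0 * y0, "yy": y0 * y0,
        "ttt": t0**3, "tty": t0 * t0 * y0, "tyy": t0 * y0 * y0, "yyy": y0**3,
    }.items()}

    def S(key: str) -> np.ndarray:
        return P[key][ends] - P[key][starts]

    n = (ends - starts).astype(float)
    mt, my = S("t") / n, S("y") / n
    ctt = S("tt") - n * mt * mt
    cty = S("ty") - n * mt * my
    cyy = S("yy") - n * my * my
    slope = cty / ctt
    # window means on the original scale undo the global centering
    intercept = (my + y.mean()) - slope * (mt + t.mean())
    sse = np.maximum(cyy - slope * cty, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / np.maximum(n - 2, 1) / ctt)
    # third central moments for residual skewness
    dy3 = S("yyy") - 3 * my * S("yy") + 3 * my**2 * S("y") - n * my**3
    dy2dt = (S("tyy") - mt * S("yy") - 2 * my * S("ty")
             + 2 * my * mt * S("y") + my**2 * S("t") - n * my**2 * mt)
    dydt2 = (S("tty") - my * S("tt") - 2 * mt * S("ty")
             + 2 * mt * my * S("t") + mt**2 * S("y") - n * mt**2 * my)
    dt3 = S("ttt") - 3 * mt * S("tt") + 3 * mt**2 * S("t") - n * mt**3
    m3 = (dy3 - 3 * slope * dy2dt + 3 * slope**2 * dydt2 - slope**3 * dt3) / n
    m2 = sse / n
    skew = np.where(m2 > 1e-18, np.abs(m3) / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
    return slope, intercept, se, skew


def extract_rate(
    trace: OxygenTrace,
    alpha: float = 0.4,
    stride: int = 1,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> RateEstimate:
    """Select the most linear, most precise, longest-supported local regression.

    All contiguous windows of length >= ceil(alpha * n) (stepped by ``stride``)
    are fitted by OLS. Each is scored by the equally weighted (configurable)
    percentile ranks of |residual skewness|, the slope CI width relative to the
    slope magnitude, and the negated window length; the lowest combined rank
    wins, with ties broken toward longer windows.
    """
    t, y = trace.times, trace.o2
    n = len(t)
    if n < 10:
        raise ValueError(f"rate extraction requires >= 10 points, got {n}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if np.ptp(y) == 0:
        return RateEstimate(0.0, float(y[0]), (0, n), {"reason": "constant trace"},
                            degenerate=True)
    min_len = math.ceil(alpha * n)
    starts = np.array([
        s for L in range(min_len, n + 1) for s in range(0, n - L + 1, stride)
    ])
    ends = np.array([
        s + L for L in range(min_len, n + 1) for s in range(0, n - L + 1, stride)
    ])
    slopes, intercepts, ses, skews = _window_stats(t, y, starts, ends)
    lengths = (ends - starts).astype(float)
    tcrit = stats.t.ppf(0.975, np.maximum(lengths - 2, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_ci = np.where(slopes != 0, 2 * tcrit * ses / np.abs(slopes), np.inf)
    m = len(starts)
    score = (
        weights[0] * stats.rankdata(skews) / m
        + weights[1] * stats.rankdata(rel_ci) / m
        + weights[2] * stats.rankdata(-lengths) / m
    )
    # break ties toward the longest window
    order = np.lexsort((-lengths, score))
    best = order[0]
    s, e = int(starts[best]), int(ends[best])
    return RateEstimate(
        slope=float(slopes[best]),
        intercept=float(intercepts[best]),
        window=(s, e),
        diagnostics={
            "residual_skewness": float(skews[best]),
            "relative_ci_width": float(rel_ci[best]),
            "window_fraction": float((e - s) / n),
            "n_windows": m,
        },
    )


def normalize_rate(
    raw_slope: float,
    blank_slope: float,
    well_volume_l: float,
    n_individuals: int,
    mean_size_mm3: float | None = None,
) -> dict:
    """Blank-correct and normalize a raw well slope.

    per_individual = (raw - blank) * well_volume / n, converted umol -> nmol,
    in nmol O2 individual^-1 min^-1; size_normalized divides by mean larval
    volume for nmol O2 mm^-3 min^-1.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1 (blanks are not normalized)")
    if well_volume_l <= 0:
        raise ValueError("well volume must be positive")
    per_individual = (raw_slope - blank_slope) * well_volume_l / n_individuals * 1e3
    out = {"per_individual_nmol_min": per_individual}
    if mean_size_mm3 is not None:
        if mean_size_mm3 <= 0:
            raise ValueError("mean larval size must be positive")
        out["size_normalized_nmol_mm3_min"] = per_individual / mean_size_mm3
    return out


def photosynthesis_metrics(net_p: float, respiration: float) -> dict:
    """Gross photosynthesis (net P + R) and the P:R ratio.

    ``respiration`` is the positive magnitude of oxygen consumption. A zero
    respiration rate leaves P:R undefined (NaN, flagged).
    """
    if respiration < 0:
        raise ValueError("respiration must be a non-negative consumption magnitude")
    gross = net_p + respiration
    if respiration == 0:
        return {"gross_p": gross, "p_to_r": math.nan, "flagged": True}
    return {"gross_p": gross, "p_to_r": gross / respiration, "flagged": False}


def chlorophyll(e663: float, e630: float, path_correction: float = 0.584) -> dict:
    """Chlorophyll a and c2 from acetone-extract absorbances (dinoflagellate
    equations), divided by the well path-length correction."""
    if e663 < 0 or e630 < 0:
        raise ValueError("absorbances must be non-negative")
    chl_a = (11.43 * e663 - 0.64 * e630) / path_correction
    chl_c2 = (27.09 * e630 - 3.63 * e663) / path_correction
    return {"chl_a": chl_a, "chl_c2": chl_c2, "total": chl_a + chl_c2}


def larval_volume(length_mm: float, width_mm: float) -> float:
    """Elliptical-sphere larval volume V = (4/3) * pi * a * b^2 with
    a = width / 2 and b = length / 2, in mm^3."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("larval dimensions must be positive")
    a = width_mm / 2.0
    b = length_mm / 2.0
    return (4.0 / 3.0) * math.pi * a * b**2


def settlement_proportion(n_settled: int, n_start: int) -> float:
    """Primary polyps as a proportion of starting larvae."""
    if n_start <= 0:
        raise ValueError("n_start must be positive")
    if n_settled < 0 or n_settled > n_start:
        raise ValueError("n_settled must lie in [0, n_start]")
    return n_settled / n_start


def survival_density(counts, aliquot_volume_ml: float) -> float:
    """Mean larvae per ml across replicate aliquot counts."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if aliquot_volume_ml <= 0:
        raise ValueError("aliquot volume must be positive")
    return float(counts.mean() / aliquot_volume_ml)
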