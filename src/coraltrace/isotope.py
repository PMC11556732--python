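"""Isotopologue data model, natural-abundance correction, and enrichment metrics.

An LC-MS isotopologue spectrum for a metabolite with ``n`` carbon atoms is the
vector of ion counts at mass shifts M+0 ... M+n. Because ~1.07% of carbon is
naturally :sup:`13`C, the observed mass-shift distribution is a blurred version
of the true labeled-carbon-count distribution: a molecule with ``j`` tracer
labels is observed at shift ``k >= j`` whenever ``k - j`` of its remaining
``n - j`` carbons happen to be heavy at natural abundance. Correction inverts
that binomial convolution so that downstream enrichment metrics reflect tracer
incorporation only.

Two enrichment metrics are derived from the corrected distribution:

* **enrichment** — the fraction of all carbon atoms in the metabolite pool that
  are labeled, ``sum(i * f_i) / n``;
* **carbon-specific enrichment** — the fraction ``f_i`` of molecules carrying
  exactly ``i`` labeled carbons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateDataError

#: IUPAC natural abundance of carbon-13.
DEFAULT_P13C = 0.0107

__all__ = [
    "DEFAULT_P13C",
    "NaturalAbundanceModel",
    "IsotopologueSpectrum",
    "CorrectedDistribution",
    "EnrichmentValue",
    "build_correction_matrix",
    "convolve_natural_abundance",
    "correct_natural_abundance",
    "enrichment",
    "carbon_specific_enrichment",
]


@dataclass(frozen=True)
class NaturalAbundanceModel:
    """Single-element isotope model: probability that a carbon is 13C at
    natural abundance. Carbon-only by design; the tracer metrics implemented
    here concern carbon labeling exclusively. Extending to multi-element
    correction would replace :func:`build_correction_matrix` with a Kronecker
    product over element-wise matrices."""

    p13c: float = DEFAULT_P13C

    def __post_init__(self) -> None:
        if not 0.0 < self.p13c < 0.5:
            raise ValueError(
                f"p13c must lie in (0, 0.5); got {self.p13c!r} "
                "(at p13c >= 0.5 the correction system is ill-conditioned)"
            )


@dataclass(frozen=True)
class IsotopologueSpectrum:
    """Raw M+0..M+n ion intensities for one metabolite in one sample."""

    metabolite_id: str
    n_carbons: int
    intensities: tuple[float, ...]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"n_carbons must be >= 1; got {self.n_carbons}")
        object.__setattr__(self, "intensities", tuple(float(x) for x in self.intensities))
        if len(self.intensities) != self.n_carbons + 1:
            raise ValueError(
                f"{self.metabolite_id}/{self.sample_id}: expected "
                f"{self.n_carbons + 1} intensities (M+0..M+{self.n_carbons}), "
                f"got {len(self.intensities)}"
            )
        if any(x < 0 for x in self.intensities):
            raise ValueError(f"{self.metabolite_id}/{self.sample_id}: negative intensity")

    @property
    def total(self) -> float:
        return float(sum(self.intensities))


@dataclass(frozen=True)
class CorrectedDistribution:
    """Natural-abundance-corrected labeled-carbon-count fractions, summing to 1."""

    metabolite_id: str
    n_carbons: int
    fractions: tuple[float, ...]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"n_carbons must be >= 1; got {self.n_carbons}")
        object.__setattr__(self, "fractions", tuple(float(x) for x in self.fractions))
        if len(self.fractions) != self.n_carbons + 1:
            raise ValueError(
                f"{self.metabolite_id}: expected {self.n_carbons + 1} fractions, "
                f"got {len(self.fractions)}"
            )
        if any(f < -1e-12 or f > 1 + 1e-12 for f in self.fractions):
            raise ValueError(f"{self.metabolite_id}: fractions outside [0, 1]")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"{self.metabolite_id}: fractions sum to {sum(self.fractions)!r}, not 1"
            )


@dataclass(frozen=True)
class EnrichmentValue:
    metabolite_id: str
    sample_id: str
    enrichment: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.enrichment <= 1 + 1e-12:
            raise ValueError(f"enrichment outside [0, 1]: {self.enrichment!r}")


def build_correction_matrix(
    n_carbons: int, model: NaturalAbundanceModel | None = None
) -> np.ndarray:
    """Column-stochastic matrix C with C[k, j] = P(observed shift k | true count j).

    A molecule with ``j`` tracer-labeled carbons has ``n - j`` carbons that may
    each be heavy at natural abundance, so the observed shift is
    ``j + Binomial(n - j, p13c)``::

        C[k, j] = C(n - j, k - j) * p**(k - j) * (1 - p)**(n - k)   for k >= j

    Every column sums to 1 exactly (it is a binomial pmf shifted by j).
    """
    if n_carbons < 1:
        raise ValueError(f"n_carbons must be >= 1; got {n_carbons}")
    model = model or NaturalAbundanceModel()
    n = n_carbons
    C = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        C[j:, j] = stats.binom.pmf(np.arange(n - j + 1), n - j, model.p13c)
    return C


def convolve_natural_abundance(
    fractions: np.ndarray, model: NaturalAbundanceModel | None = None
) -> np.ndarray:
    """Forward model: blur a true labeled-count distribution into the observed
    mass-shift distribution. Used by the simulator and as the round-trip oracle."""
    fractions = np.asarray(fractions, dtype=float)
    return build_correction_matrix(len(fractions) - 1, model) @ fractions


def correct_natural_abundance(
    spectrum: IsotopologueSpectrum, model: NaturalAbundanceModel | None = None
) -> CorrectedDistribution:
    """Deconvolve natural abundance from an observed spectrum.

    Solves ``observed = C @ true`` for the true fraction vector by non-negative
    least squares, then renormalizes to sum 1. NNLS rather than a direct matrix
    inverse keeps fractions non-negative under measurement noise.
    """
    model = model or NaturalAbundanceModel()
    if spectrum.total == 0:
        raise DegenerateDataError(
            f"{spectrum.metabolite_id}/{spectrum.sample_id}: all-zero spectrum"
        )
    observed = np.asarray(spectrum.intensities, dtype=float) / spectrum.total
    C = build_correction_matrix(spectrum.n_carbons, model)
    x, _ = optimize.nnls(C, observed)
    total = x.sum()
    if total <= 0:
        raise DegenerateDataError(
            f"{spectrum.metabolite_id}/{spectrum.sample_id}: correction produced "
            "an all-zero solution"
        )
    x = x / total
    # clip tiny negatives from floating point and renormalize once more
    x = np.clip(x, 0.0, 1.0)
    x = x / x.sum()
    return CorrectedDistribution(
        metabolite_id=spectrum.metabolite_id,
        n_carbons=spectrum.n_carbons,
        fractions=tuple(x),
        sample_id=spectrum.sample_id,
    )


def enrichment(dist: CorrectedDistribution) -> EnrichmentValue:
    """Fraction of 13C atoms among all carbon atoms: sum(i * f_i) / n."""
    f = np.asarray(dist.fractions)
    value = float(np.arange(dist.n_carbons + 1) @ f / dist.n_carbons)
    value = min(max(value, 0.0), 1.0)
    return EnrichmentValue(dist.metabolite_id, dist.sample_id, value)


def carbon_specific_enrichment(dist: CorrectedDistribution, i: int) -> float:
    """Fraction of molecules carrying exactly ``i`` labeled carbons."""
    if not 0 <= i <= dist.n_carbons:
        raise ValueError(
            f"label count {i} out of range 0..{dist.n_carbons} for {dist.metabolite_id}"
        )
    return dist.fractions[i]
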