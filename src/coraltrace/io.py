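"""CSV readers and writers for the long-format tables the pipeline consumes.

Formats
-------
isotopologue CSV (MAVEN-style long export)
    columns: metabolite, n_carbons, isotopologue (integer mass shift),
    sample, intensity
metadata CSV
    columns: sample, treatment, isotope, light (+ any extra columns kept)
oxygen CSV
    columns: well, time_min, o2 (+ optional well_volume_l, n_individuals and
    grouping columns, constant within well)
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import SchemaError
from .isotope import IsotopologueSpectrum
from .physiology import OxygenTrace

logger = logging.getLogger("coraltrace")

ISOTOPOLOGUE_COLUMNS = ("metabolite", "n_carbons", "isotopologue", "sample", "intensity")
METADATA_COLUMNS = ("sample", "treatment", "isotope", "light")
OXYGEN_COLUMNS = ("well", "time_min", "o2")

__all__ = [
    "read_isotopologue_csv",
    "spectra_from_frame",
    "read_metadata_csv",
    "read_oxygen_csv",
    "write_tidy_csv",
]


def _require(frame: pd.DataFrame, columns: tuple[str, ...], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {missing}")


def spectra_from_frame(frame: pd.DataFrame) -> list[IsotopologueSpectrum]:
    """Validate a long-format isotopologue frame and build spectrum objects.

    Each (metabolite, sample) group must cover mass shifts 0..n_carbons exactly.
    """
    _require(frame, ISOTOPOLOGUE_COLUMNS, "isotopologue")
    spectra = []
    for (met, sample), sub in frame.groupby(["metabolite", "sample"], sort=True):
        n_carbons = sub["n_carbons"].unique()
        if len(n_carbons) != 1:
            raise SchemaError(f"{met}/{sample}: conflicting n_carbons values {n_carbons}")
        n = int(n_carbons[0])
        shifts = sorted(sub["isotopologue"].astype(int))
        if shifts != list(range(n + 1)):
            raise SchemaError(
                f"{met}/{sample}: isotopologue rows {shifts} do not cover 0..{n} "
                f"declared by n_carbons={n}"
            )
        ordered = sub.sort_values("isotopologue")
        spectra.append(IsotopologueSpectrum(
            metabolite_id=str(met), n_carbons=n,
            intensities=tuple(ordered["intensity"].astype(float)),
            sample_id=str(sample),
        ))
    return spectra


def read_isotopologue_csv(path) -> tuple[list[IsotopologueSpectrum], pd.DataFrame]:
    frame = pd.read_csv(path)
    spectra = spectra_from_frame(frame)
    logger.info("read %d isotopologue rows, %d spectra from %s", len(frame), len(spectra), path)
    return spectra, frame


def read_metadata_csv(path, samples: list[str] | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require(frame, METADATA_COLUMNS, "metadata")
    if frame["sample"].duplicated().any():
        dupes = sorted(frame.loc[frame["sample"].duplicated(), "sample"].unique())
        raise SchemaError(f"duplicate sample rows in metadata: {dupes}")
    meta = frame.set_index("sample")
    if samples is not None:
        orphans = sorted(set(samples) - set(meta.index))
        if orphans:
            raise SchemaError(f"samples present in data but not in metadata: {orphans}")
        logger.info("metadata covers all %d data samples", len(samples))
    return meta


def read_oxygen_csv(path) -> list[OxygenTrace]:
    frame = pd.read_csv(path)
    _require(frame, OXYGEN_COLUMNS, "oxygen")
    traces = []
    label_cols = [c for c in frame.columns if c not in OXYGEN_COLUMNS]
    for well, sub in frame.groupby("well", sort=True):
        sub = sub.sort_values("time_min")
        labels = {"well": well}
        kwargs = {}
        for c in label_cols:
            vals = sub[c].unique()
            if len(vals) != 1:
                raise SchemaError(f"well {well}: column {c!r} is not constant within well")
            if c == "well_volume_l":
                kwargs["well_volume_l"] = float(vals[0])
            elif c == "n_individuals":
                kwargs["n_individuals"] = int(vals[0])
            else:
                labels[c] = vals[0]
        traces.append(OxygenTrace(
            times=sub["time_min"].to_numpy(float),
            o2=sub["o2"].to_numpy(float),
            labels=labels, **kwargs,
        ))
    logger.info("read %d oxygen traces from %s", len(traces), path)
    return traces


def write_tidy_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
    logger.info("wrote %d rows to %s", len(frame), path)
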