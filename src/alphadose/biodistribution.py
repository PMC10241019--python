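"""Organ-uptake (biodistribution) data model and I/O.

Biodistribution studies report the decay-corrected percentage of the injected
activity found per gram of tissue (%IA/g) for each organ at a series of times
after injection. Samples are gamma-counted at secular equilibrium against a
standard representing a known fraction of the injected dose; when sample and
standard are counted at different times, the count ratio is corrected for the
parent's physical decay in between. This module converts raw count records to
%IA/g, summarizes per-(organ, time) replicates as mean ± SD, and reads/writes
the package's single CSV dialect.

CSV schema (UTF-8, '.' decimal separator)
-----------------------------------------
Sample files: ``subject_id, organ, time_h, pct_ia_per_g[, organ_mass_g]``.
Summary files: ``organ, time_h, pct_ia_per_g, sd, n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import InputError, SchemaError
from .decay_chain import Nuclide, physical_decay_factor

logger = logging.getLogger(__name__)

__all__ = [
    "BiodistributionSample",
    "BiodistributionSeries",
    "pct_ia_per_gram",
    "summarize",
    "read_biodistribution_csv",
    "write_samples_csv",
    "write_series_csv",
    "read_series_csv",
]

SAMPLE_COLUMNS = ["subject_id", "organ", "time_h", "pct_ia_per_g"]
SERIES_COLUMNS = ["organ", "time_h", "pct_ia_per_g", "sd", "n"]


@dataclass(frozen=True)
class BiodistributionSample:
    """%IA/g in one organ of one subject at one time post-injection."""

    subject_id: str
    organ: str
    time_h: float
    pct_ia_per_g: float
    organ_mass_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise InputError(f"{self.subject_id}/{self.organ}: time must be >= 0")
        if self.pct_ia_per_g < 0:
            raise InputError(f"{self.subject_id}/{self.organ}: %IA/g must be >= 0")
        if self.organ_mass_g is not None and not self.organ_mass_g > 0:
            raise InputError(f"{self.subject_id}/{self.organ}: organ mass must be > 0")


@dataclass(frozen=True)
class BiodistributionSeries:
    """Per-organ mean ± SD %IA/g over time.

    ``data`` has columns organ, time_h, pct_ia_per_g (mean), sd, n; organs
    sorted lexicographically, times strictly ascending within each organ.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SERIES_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"series missing columns: {missing}")
        for organ, grp in self.data.groupby("organ"):
            t = grp["time_h"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise InputError(f"{organ}: times must be strictly increasing")
        if (self.data["n"] < 1).any() or (self.data["sd"] < 0).any():
            raise InputError("series requires n >= 1 and sd >= 0")

    @property
    def organs(self) -> list[str]:
        return sorted(self.data["organ"].unique())

    def for_organ(self, organ: str) -> pd.DataFrame:
        sub = self.data[self.data["organ"] == organ]
        if sub.empty:
            raise KeyError(organ)
        return sub.reset_index(drop=True)

    def scaled(self, factor: float) -> "BiodistributionSeries":
        out = self.data.copy()
        out["pct_ia_per_g"] = out["pct_ia_per_g"] * factor
        out["sd"] = out["sd"] * factor
        return BiodistributionSeries(out)


def pct_ia_per_gram(
    sample_counts: float,
    standard_counts: float,
    standard_fraction_of_injected: float,
    organ_mass: float,
    count_delay: float = 0.0,
    nuclide: Nuclide | None = None,
) -> float:
    """Convert gamma counts to decay-corrected %IA/g.

    ``standard_counts`` is the count rate of a standard containing
    ``standard_fraction_of_injected`` of the injected activity; ``count_delay``
    is the time (s) the sample was counted after the standard, corrected using
    the parent's physical decay. Both sample and standard are assumed counted
    at secular equilibrium, so no daughter-ingrowth correction applies.
    """
    if sample_counts < 0:
        raise InputError("sample counts must be >= 0")
    if not standard_counts > 0:
        raise InputError("standard counts must be > 0")
    if not 0 < standard_fraction_of_injected <= 1:
        raise InputError("standard fraction must be in (0, 1]")
    if not organ_mass > 0:
        raise InputError("organ mass must be > 0")
    value = 100.0 * (sample_counts / standard_counts) * standard_fraction_of_injected / organ_mass
    if count_delay != 0.0:
        if nuclide is None:
            raise InputError("a nuclide is required to decay-correct a nonzero count delay")
        value /= physical_decay_factor(nuclide, count_delay)
    return value


def summarize(samples: Iterable[BiodistributionSample]) -> BiodistributionSeries:
    """Collapse raw samples to per-(organ, time) mean, sample SD (n−1), and n.

    Groups with a single sample report sd = 0 and are logged rather than
    rejected (small-n femur/marrow groups are common in practice).
    """
    samples = list(samples)
    if not samples:
        raise InputError("no samples to summarize")
    df = pd.DataFrame(
        {
            "organ": [s.organ for s in samples],
            "time_h": [s.time_h for s in samples],
            "value": [s.pct_ia_per_g for s in samples],
        }
    )
    rows = []
    for (organ, t), grp in df.groupby(["organ", "time_h"], sort=True):
        n = len(grp)
        if n == 1:
            logger.warning("single sample for %s at %g h; sd reported as 0", organ, t)
        sd = float(grp["value"].std(ddof=1)) if n > 1 else 0.0
        rows.append((organ, t, float(grp["value"].mean()), sd, n))
    out = pd.DataFrame(rows, columns=SERIES_COLUMNS)
    return BiodistributionSeries(out)


def read_biodistribution_csv(path) -> list[BiodistributionSample]:
    """Read raw samples; schema errors name the offending row and column."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: header-only file, no samples", path)
        return []
    out = []
    for idx, row in df.iterrows():
        for col in ("time_h", "pct_ia_per_g"):
            if row[col] < 0:
                raise SchemaError(f"{path}: negative {col} at row {idx + 2}")
        mass = row.get("organ_mass_g")
        mass = None if mass is None or pd.isna(mass) else float(mass)
        out.append(
            BiodistributionSample(
                subject_id=str(row["subject_id"]),
                organ=str(row["organ"]),
                time_h=float(row["time_h"]),
                pct_ia_per_g=float(row["pct_ia_per_g"]),
                organ_mass_g=mass,
            )
        )
    return out


def write_samples_csv(samples: Sequence[BiodistributionSample], path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in samples],
            "organ": [s.organ for s in samples],
            "time_h": [s.time_h for s in samples],
            "pct_ia_per_g": [s.pct_ia_per_g for s in samples],
            "organ_mass_g": [s.organ_mass_g for s in samples],
        }
    )
    df.to_csv(path, index=False)


def write_series_csv(series: BiodistributionSeries, path) -> None:
    series.data.to_csv(path, index=False)


def read_series_csv(path) -> BiodistributionSeries:
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return BiodistributionSeries(df)


def series_to_json(series: BiodistributionSeries) -> dict:
    """Summary series as a JSON-ready mapping organ -> records."""
    out: dict[str, list] = {}
    for organ in series.organs:
        sub = series.for_organ(organ)
        out[organ] = sub[["time_h", "pct_ia_per_g", "sd", "n"]].to_dict(orient="records")
    return out
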