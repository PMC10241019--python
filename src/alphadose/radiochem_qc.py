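"""Radiochemistry quality-control arithmetic.

Specific activity (MBq/mg of antibody), radiochemical yield/purity fractions
from bound vs. free counts, and mean chelates per antibody from intact-mass
shifts. All quantities are measured at secular equilibrium of the ²²⁵Ac chain,
so no ingrowth correction enters the arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

from ._errors import InputError

__all__ = [
    "ReactionRecord",
    "specific_activity",
    "radiochemical_purity",
    "chelates_per_antibody",
    "qc_report",
]


@dataclass(frozen=True)
class ReactionRecord:
    """One labeling reaction: inputs and QC measurements."""

    input_activity_mbq: float
    antibody_mass_mg: float
    radiochemical_yield: float
    bound_counts: float
    free_counts: float
    conjugate_mass_da: Optional[float] = None
    native_mass_da: Optional[float] = None
    adduct_mass_da: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.input_activity_mbq > 0 or not self.antibody_mass_mg > 0:
            raise InputError("activity and antibody mass must be > 0")
        if not 0 <= self.radiochemical_yield <= 1:
            raise InputError("radiochemical yield must be in [0,1]")
        if self.bound_counts < 0 or self.free_counts < 0:
            raise InputError("counts must be >= 0")
        if (
            self.conjugate_mass_da is not None
            and self.native_mass_da is not None
            and self.conjugate_mass_da < self.native_mass_da
        ):
            raise InputError("conjugate mass must be >= native antibody mass")


def specific_activity(
    input_activity_mbq: float, antibody_mass_mg: float, radiochemical_yield: float
) -> float:
    """Product activity per mg of antibody: input × yield / mass (MBq/mg)."""
    if not antibody_mass_mg > 0:
        raise InputError("antibody mass must be > 0")
    if not 0 <= radiochemical_yield <= 1:
        raise InputError("radiochemical yield must be in [0,1]")
    return input_activity_mbq * radiochemical_yield / antibody_mass_mg


def radiochemical_purity(bound_counts: float, free_counts: float) -> float:
    """Fraction of activity bound to the antibody: bound / (bound + free)."""
    total = bound_counts + free_counts
    if not total > 0:
        raise InputError("bound + free counts must be > 0")
    return bound_counts / total


def chelates_per_antibody(
    conjugate_mass_da: float, native_mass_da: float, adduct_mass_da: float
) -> float:
    """Mean chelator count from the intact-mass shift, rounded to one decimal.

    The DOTA adduct mass added per conjugation event is a parameter (it
    depends on the coupling chemistry), not a packaged constant.
    """
    if not adduct_mass_da > 0:
        raise InputError("adduct mass must be > 0")
    if conjugate_mass_da < native_mass_da:
        raise InputError("conjugate mass must be >= native antibody mass")
    return round((conjugate_mass_da - native_mass_da) / adduct_mass_da, 1)


def qc_report(record: ReactionRecord) -> dict:
    """All QC quantities computable from one reaction record, JSON-ready."""
    out = dict(asdict(record))
    out["specific_activity_mbq_per_mg"] = specific_activity(
        record.input_activity_mbq, record.antibody_mass_mg, record.radiochemical_yield
    )
    if record.bound_counts + record.free_counts > 0:
        out["radiochemical_purity"] = radiochemical_purity(
            record.bound_counts, record.free_counts
        )
    if None not in (record.conjugate_mass_da, record.native_mass_da, record.adduct_mass_da):
        out["chelates_per_antibody"] = chelates_per_antibody(
            record.conjugate_mass_da, record.native_mass_da, record.adduct_mass_da
        )
    return out


def load_reaction_record(path) -> ReactionRecord:
    with open(path, encoding="utf-8") as fh:
        return ReactionRecord(**json.load(fh))
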