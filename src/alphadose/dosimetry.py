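"""Biodistribution → absorbed/equivalent dose, MIRD-style, for alpha emitters.

The pipeline follows the MIRD formalism for an alpha emitter whose daughters
decay in situ at secular equilibrium:

1. Decay-corrected %IA/g measurements are scaled from mouse to human by
   relative organ-mass scaling (each organ's share of the injected activity
   relative to its fractional body mass is preserved; algebraically the
   per-gram concentration scales by the mouse/human body-mass ratio).
2. The %IA/g series is converted back to the *actual* activity concentration
   a(t) in Bq/kg per MBq injected by undoing the decay correction.
3. The cumulated activity concentration Ã = ∫a(t)dt is integrated by the
   trapezoidal rule, with a constant head segment before the first sample and
   an analytic physical-decay tail a_last/λ after the last sample — the
   maximally conservative extrapolation to infinity (biological retention is
   frozen; only physical decay removes activity).
4. Absorbed dose D = Ã × Δ × ϕ, with Δ the branch-weighted alpha energy per
   parent transformation and ϕ = 1 (alphas deposit locally). Equivalent dose
   applies an alpha RBE (default 5); effective-dose scalars apply tissue
   weighting factors under the older (effective dose equivalent) and newer
   (effective dose) schemes.

Beta and photon energy is excluded throughout; only the alpha component of
the ²²⁵Ac chain contributes to Δ.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ._errors import ConfigError, InputError, MappingError
from .biodistribution import BiodistributionSeries
from .decay_chain import DecayChain, Nuclide, mean_alpha_energy_per_decay, physical_decay_factor

__all__ = [
    "TimeActivityCurve",
    "CumulatedActivity",
    "Phantom",
    "DoseConfig",
    "OrganDoseTable",
    "load_default_phantoms",
    "load_tissue_weights",
    "canonical_organ",
    "tac_from_series",
    "cumulated_activity",
    "scale_series_to_human",
    "organ_absorbed_dose",
    "equivalent_dose",
    "effective_dose",
    "dose_table",
]

# controlled vocabulary: free-text organ labels -> canonical names used by
# phantoms and tissue-weight tables
ORGAN_ALIASES = {
    "marrow, red": "marrow",
    "red marrow": "marrow",
    "bone marrow": "marrow",
    "kidneys": "kidney",
    "lungs": "lung",
    "bladder wall": "bladder",
    "urinary bladder": "bladder",
    "stomach wall": "stomach",
    "heart wall": "heart",
    "intestine, large, lower": "colon",
    "intestine, large, upper": "colon",
    "large intestine": "colon",
    "intestine, small": "small_intestine",
    "ovaries": "ovaries",
    "ovary": "ovaries",
}

# organs whose equivalent dose never enters the effective-dose sums
EFFECTIVE_DOSE_EXCLUDED = {"blood"}

# canonical organs mapped onto weighting-scheme keys
WEIGHT_KEY_ALIASES = {
    "marrow": "marrow",
    "ovaries": "gonads",
    "bone": "bone_surface",
    "femur": "bone_surface",
}


def canonical_organ(name: str) -> str:
    key = name.strip().lower()
    return ORGAN_ALIASES.get(key, key)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Actual (non-decay-corrected) activity concentration vs. time.

    ``activity_concentration`` is in Bq/kg per MBq injected; times in seconds.
    """

    organ: str
    times: np.ndarray
    activity_concentration: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.activity_concentration, dtype=float)
        if t.size == 0:
            raise InputError(f"{self.organ}: empty time-activity curve")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InputError(f"{self.organ}: times must be strictly increasing")
        if np.any(a < 0) or np.any(t < 0):
            raise InputError(f"{self.organ}: negative time or activity")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "activity_concentration", a)


@dataclass(frozen=True)
class CumulatedActivity:
    """Ã = ∫a(t)dt in Bq·s/kg per MBq injected, plus the tail's share."""

    organ: str
    a_tilde: float
    tail_fraction: float

    def __post_init__(self) -> None:
        if self.a_tilde < 0:
            raise InputError(f"{self.organ}: cumulated activity must be >= 0")
        if not 0 <= self.tail_fraction <= 1:
            raise InputError(f"{self.organ}: tail fraction must be in [0,1]")


@dataclass(frozen=True)
class Phantom:
    """Species body mass and per-organ masses, grams."""

    species: str
    body_mass_g: float
    organ_masses_g: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.body_mass_g > 0:
            raise InputError("body mass must be > 0")
        for organ, m in self.organ_masses_g.items():
            if not m > 0:
                raise InputError(f"{self.species}/{organ}: organ mass must be > 0")
        if sum(self.organ_masses_g.values()) > self.body_mass_g:
            raise InputError(f"{self.species}: organ masses exceed body mass")

    def organ_mass(self, organ: str) -> float:
        key = canonical_organ(organ)
        if key not in self.organ_masses_g:
            raise MappingError(f"organ '{organ}' not in {self.species} phantom")
        return self.organ_masses_g[key]


@dataclass(frozen=True)
class DoseConfig:
    """Dose-calculation knobs: absorbed fraction ϕ, alpha RBE, tissue weights.

    ``phi`` defaults to 1 (alphas deposit all energy locally); ``rbe`` to 5,
    the conventional alpha value for sievert conversion in this setting.
    ``head_policy`` controls the pre-first-sample segment of Ã ("constant"
    holds the first sample's value; "linear" ramps from zero).
    """

    phi: float = 1.0
    rbe: float = 5.0
    head_policy: str = "constant"
    tissue_weights: Optional[Mapping[str, Mapping[str, float]]] = None

    def __post_init__(self) -> None:
        if not 0 < self.phi <= 1:
            raise InputError("phi must be in (0,1]")
        if not self.rbe > 0:
            raise InputError("rbe must be > 0")
        if self.head_policy not in ("constant", "linear"):
            raise ConfigError(f"unknown head policy '{self.head_policy}'")
        if self.tissue_weights is None:
            object.__setattr__(self, "tissue_weights", load_tissue_weights())
        for scheme, weights in self.tissue_weights.items():
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(f"{scheme}: tissue weights sum to {total}, expected 1")

    def weights_for(self, scheme: str) -> Mapping[str, float]:
        if scheme not in self.tissue_weights:
            raise ConfigError(f"no tissue weights for scheme '{scheme}'")
        return self.tissue_weights[scheme]


@dataclass(frozen=True)
class OrganDoseTable:
    """Per-organ absorbed (mGy/MBq) and equivalent (mSv/MBq) doses.

    ``data`` columns: organ, absorbed_mgy_per_mbq, equivalent_msv_per_mbq.
    The two effective-dose scalars are tissue-weighted sums of the organ
    equivalent doses under the newer and older weighting schemes.
    """

    data: pd.DataFrame
    effective_dose_msv_per_mbq: float
    effective_dose_equivalent_msv_per_mbq: float
    audit: dict = field(default_factory=dict)

    def equivalent_dose_of(self, organ: str) -> float:
        sub = self.data[self.data["organ"] == organ]
        if sub.empty:
            raise KeyError(organ)
        return float(sub["equivalent_msv_per_mbq"].iloc[0])


def _load_packaged(name: str) -> dict:
    ref = resources.files("alphadose.data").joinpath(name)
    with ref.open(encoding="utf-8") as fh:
        return json.load(fh)


def load_default_phantoms() -> tuple[Phantom, Phantom]:
    """(mouse, adult female human) default phantoms."""
    doc = _load_packaged("phantoms.json")
    out = []
    for key in ("mouse", "human_female"):
        rec = doc[key]
        out.append(
            Phantom(
                species=rec["species"],
                body_mass_g=rec["body_mass_g"],
                organ_masses_g=dict(rec["organ_masses_g"]),
            )
        )
    return out[0], out[1]


def load_tissue_weights() -> dict[str, dict[str, float]]:
    doc = _load_packaged("tissue_weights.json")
    return {k: dict(v) for k, v in doc.items() if k != "description"}


def tac_from_series(series: BiodistributionSeries, nuclide: Nuclide) -> list[TimeActivityCurve]:
    """Decay-corrected %IA/g → actual activity concentration per MBq injected.

    %IA/g is referenced to injection time; multiplying by e^(−λt) restores
    the activity actually present when the animal was sampled. 1 %IA/g per
    MBq injected is 0.01 × 1e6 Bq/g = 1e7 Bq/kg at t = 0.
    """
    if series.data.empty:
        raise InputError("empty biodistribution series")
    curves = []
    for organ in series.organs:
        sub = series.for_organ(organ)
        t_s = sub["time_h"].to_numpy() * 3600.0
        decay = np.array([physical_decay_factor(nuclide, t) for t in t_s])
        conc = sub["pct_ia_per_g"].to_numpy() / 100.0 * 1e6 * 1000.0 * decay
        curves.append(TimeActivityCurve(organ=organ, times=t_s, activity_concentration=conc))
    return curves


def cumulated_activity(
    tac: TimeActivityCurve, nuclide: Nuclide, head_policy: str = "constant"
) -> CumulatedActivity:
    """Integrate a time–activity curve to infinity.

    Head: from t = 0 to the first sample the concentration is held at the
    first sample's value ("constant", the conservative default) or ramped
    linearly from zero ("linear"). Body: trapezoidal rule over the samples.
    Tail: after the last sample biological retention is frozen and only
    physical decay proceeds, contributing a_last/λ — the maximally
    conservative extrapolation.
    """
    t = tac.times
    a = tac.activity_concentration
    if head_policy not in ("constant", "linear"):
        raise ConfigError(f"unknown head policy '{head_policy}'")
    head = a[0] * t[0] if head_policy == "constant" else 0.5 * a[0] * t[0]
    body = float(np.trapezoid(a, t)) if len(t) > 1 else 0.0
    lam = nuclide.decay_constant
    if lam <= 0:
        raise InputError("cumulated activity requires a radioactive parent")
    tail = a[-1] / lam
    a_tilde = head + body + tail
    tail_fraction = tail / a_tilde if a_tilde > 0 else 0.0
    return CumulatedActivity(organ=tac.organ, a_tilde=a_tilde, tail_fraction=tail_fraction)


def scale_series_to_human(
    series: BiodistributionSeries, mouse: Phantom, human: Phantom
) -> BiodistributionSeries:
    """Relative organ-mass scaling of a murine %IA/g series to a human phantom.

    Each organ's %IA is scaled by the ratio of fractional organ masses
    (human organ/body over mouse organ/body) and reconverted to per-gram
    concentration; the organ masses cancel, leaving human %IA/g =
    mouse %IA/g × (mouse body mass / human body mass) for every organ. Both
    phantoms must map every organ in the series.
    """
    parts = []
    for organ in series.organs:
        m_org_mouse = mouse.organ_mass(organ)
        m_org_human = human.organ_mass(organ)
        sub = series.for_organ(organ).copy()
        pct_ia_organ = sub["pct_ia_per_g"] * m_org_mouse  # %IA in the whole organ
        scale = (m_org_human / human.body_mass_g) / (m_org_mouse / mouse.body_mass_g)
        sub["pct_ia_per_g"] = pct_ia_organ * scale / m_org_human
        sub["sd"] = sub["sd"] * m_org_mouse * scale / m_org_human
        parts.append(sub)
    return BiodistributionSeries(pd.concat(parts, ignore_index=True))


def organ_absorbed_dose(a_tilde: CumulatedActivity, delta: float, config: DoseConfig) -> float:
    """D = Ã × Δ × ϕ, in Gy per MBq injected."""
    if delta < 0:
        raise InputError("delta must be >= 0")
    return a_tilde.a_tilde * delta * config.phi


def equivalent_dose(absorbed_gy: float, config: DoseConfig) -> float:
    """Absorbed dose (Gy) → equivalent dose (mSv) via the alpha RBE."""
    if absorbed_gy < 0:
        raise InputError("absorbed dose must be >= 0")
    return absorbed_gy * config.rbe * 1000.0


def _weight_key(organ: str) -> str:
    key = canonical_organ(organ)
    return WEIGHT_KEY_ALIASES.get(key, key)


def effective_dose(table: OrganDoseTable, config: DoseConfig, scheme: str = "icrp60_ed") -> float:
    """Tissue-weighted sum of organ equivalent doses, mSv/MBq.

    Organs without an explicit weight in the scheme share the scheme's
    remainder weight uniformly; blood is reported in dose tables but never
    enters the sum.
    """
    weights = config.weights_for(scheme)
    rows = [
        (organ, dose)
        for organ, dose in zip(table.data["organ"], table.data["equivalent_msv_per_mbq"])
        if canonical_organ(organ) not in EFFECTIVE_DOSE_EXCLUDED
    ]
    if not rows:
        return 0.0
    explicit = [(o, d) for o, d in rows if _weight_key(o) in weights]
    remainder = [(o, d) for o, d in rows if _weight_key(o) not in weights]
    total = sum(d * weights[_weight_key(o)] for o, d in explicit)
    if remainder:
        w_rem = weights.get("remainder", 0.0) / len(remainder)
        total += sum(d * w_rem for _, d in remainder)
    return total


def dose_table(
    series: BiodistributionSeries,
    chain: DecayChain,
    mouse: Phantom,
    human: Phantom,
    config: DoseConfig | None = None,
) -> OrganDoseTable:
    """Full pipeline: murine %IA/g series → human organ dose table.

    Composes human scaling, time–activity conversion, cumulated-activity
    integration, D = Ã × Δ × ϕ with the chain's branch-weighted alpha energy
    per decay, RBE conversion, and both effective-dose scalars. The returned
    table's ``audit`` carries per-stage intermediates (Ã, tail fractions).
    """
    config = config or DoseConfig()
    delta = mean_alpha_energy_per_decay(chain)
    human_series = scale_series_to_human(series, mouse, human)
    curves = tac_from_series(human_series, chain.parent)
    rows, audit_rows = [], []
    for tac in curves:
        cum = cumulated_activity(tac, chain.parent, head_policy=config.head_policy)
        absorbed_gy = organ_absorbed_dose(cum, delta, config)
        equiv_msv = equivalent_dose(absorbed_gy, config)
        rows.append((tac.organ, absorbed_gy * 1000.0, equiv_msv))
        audit_rows.append(
            {
                "organ": tac.organ,
                "a_tilde_bq_s_per_kg": cum.a_tilde,
                "tail_fraction": cum.tail_fraction,
                "times_s": tac.times.tolist(),
                "activity_concentration_bq_per_kg": tac.activity_concentration.tolist(),
            }
        )
    df = pd.DataFrame(rows, columns=["organ", "absorbed_mgy_per_mbq", "equivalent_msv_per_mbq"])
    table = OrganDoseTable(
        data=df,
        effective_dose_msv_per_mbq=0.0,
        effective_dose_equivalent_msv_per_mbq=0.0,
        audit={"delta_j_per_bq_s": delta, "organs": audit_rows},
    )
    ed = effective_dose(table, config, scheme="icrp60_ed")
    ede = effective_dose(table, config, scheme="icrp26_ede")
    return OrganDoseTable(
        data=df,
        effective_dose_msv_per_mbq=ed,
        effective_dose_equivalent_msv_per_mbq=ede,
        audit=table.audit,
    )


def write_dose_table_csv(table: OrganDoseTable, path) -> None:
    df = table.data.copy()
    scalars = pd.DataFrame(
        [
            ("Effective dose", math.nan, table.effective_dose_msv_per_mbq),
            ("Effective dose equivalent", math.nan, table.effective_dose_equivalent_msv_per_mbq),
        ],
        columns=df.columns,
    )
    pd.concat([df, scalars], ignore_index=True).to_csv(path, index=False)


def dose_table_to_json(table: OrganDoseTable) -> dict:
    return {
        "organs": table.data.to_dict(orient="records"),
        "effective_dose_msv_per_mbq": table.effective_dose_msv_per_mbq,
        "effective_dose_equivalent_msv_per_mbq": table.effective_dose_equivalent_msv_per_mbq,
        "audit": table.audit,
    }
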