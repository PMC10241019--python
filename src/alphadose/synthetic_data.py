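"""Synthetic study inputs: murine biodistribution and therapy cohorts.

Real preclinical inputs for this kind of study are an organ × timepoint
%IA/g table from sacrificed animals and per-animal survival / BLI / weight
series from a therapy experiment. These generators emulate both so the
dosimetry and statistics modules are exercisable end to end without animal
data.

The wild-type biodistribution model follows intact-antibody pharmacokinetics
in the mouse: blood is bi-exponential (fast distribution, slow elimination),
calibrated so the cohort mean is ≈43 %IA/g at 4 h falling to ≈15 %IA/g at
12 d; well-perfused organs (kidney 8–11, liver 10–15 %IA/g) rise quickly and
wash out slowly; marrow declines from ≈12 to ≈6 %IA/g. A tumor-bearing
scenario reproduces the high-uptake pattern seen with CD20-targeted antibody
in lymphoma xenografts (tumor ≈28, spleen ≈31, liver ≈7 %IA/g at 7 d).
Measurement noise is multiplicative log-normal (organ data are strictly
positive), mean-preserving, with a default CV matching reported ±SD spreads.

The therapy simulator is phenomenological: exponential tumor growth measured
as BLI flux, an instantaneous dose-dependent log-kill at the treatment day,
optional stochastic regrowth (relapse), and humane-endpoint events when the
burden crosses a hind-limb-paralysis threshold or weight drops more than
20%. Untreated animals are calibrated to reach the endpoint at a median of
roughly 20 days, the typical time course of a disseminated lymphoma model.
It exercises the statistics, not alpha-particle radiobiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from ._errors import ConfigError, InputError
from .biodistribution import BiodistributionSample, summarize, write_samples_csv
from .study_analysis import SubjectRecord, records_to_frames

__all__ = [
    "OrganPK",
    "PKParams",
    "TherapySimParams",
    "CohortEffect",
    "default_wildtype_params",
    "default_tumor_params",
    "default_therapy_params",
    "simulate_biodistribution",
    "simulate_therapy_cohort",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class OrganPK:
    """Mean %IA/g model for one organ.

    ``biexp`` organs (blood): C(t) = A·e^(−αt) + B·e^(−βt), t in hours.
    ``uptake`` organs: C(t) = peak·(1 − e^(−k_up·t))·e^(−k_w·t) with
    k_up = 3/time-to-peak, so the organ is within 5% of peak at t_peak.
    """

    kind: str  # "biexp" | "uptake"
    A: float = 0.0
    B: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    peak: float = 0.0
    t_peak_h: float = 1.0
    washout_per_h: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("biexp", "uptake"):
            raise InputError(f"unknown organ PK kind '{self.kind}'")
        if min(self.A, self.B, self.peak) < 0:
            raise InputError("amplitudes and peaks must be >= 0")
        if min(self.alpha, self.beta, self.washout_per_h) < 0:
            raise InputError("rates must be >= 0")
        if self.kind == "biexp" and self.alpha < self.beta:
            raise InputError("distribution rate alpha must be >= elimination rate beta")
        if self.kind == "uptake" and not self.t_peak_h > 0:
            raise InputError("time to peak must be > 0")

    def mean(self, t_h: float) -> float:
        if self.kind == "biexp":
            return self.A * math.exp(-self.alpha * t_h) + self.B * math.exp(-self.beta * t_h)
        k_up = 3.0 / self.t_peak_h
        return self.peak * (1.0 - math.exp(-k_up * t_h)) * math.exp(-self.washout_per_h * t_h)


@dataclass(frozen=True)
class PKParams:
    """Generator settings for one biodistribution scenario."""

    organ_models: Mapping[str, OrganPK]
    noise_sd_log: float = 0.14  # SD of log %IA/g; CV ~ 14%, matching ±6 on 43
    n_per_timepoint: int = 4
    seed: int = 20230

    def __post_init__(self) -> None:
        if self.noise_sd_log < 0:
            raise InputError("noise sd must be >= 0")
        if self.n_per_timepoint < 1:
            raise InputError("n per timepoint must be >= 1")


#: default sampling schedule for wild-type studies: 4 h then 1–12 d
DEFAULT_TIMES_H = (4.0, 24.0, 48.0, 96.0, 168.0, 240.0, 288.0)

_WILDTYPE_ORGANS: dict[str, OrganPK] = {
    # 43 %IA/g at 4 h, ~15 %IA/g at 288 h
    "blood": OrganPK(kind="biexp", A=8.0, B=38.0, alpha=0.0937, beta=0.003228),
    "kidney": OrganPK(kind="uptake", peak=10.0, t_peak_h=4.0, washout_per_h=0.0002),
    "liver": OrganPK(kind="uptake", peak=14.0, t_peak_h=4.0, washout_per_h=0.001),
    "marrow": OrganPK(kind="uptake", peak=12.0, t_peak_h=2.0, washout_per_h=0.00213),
    "bladder": OrganPK(kind="uptake", peak=8.0, t_peak_h=4.0, washout_per_h=0.0012),
    "spleen": OrganPK(kind="uptake", peak=6.0, t_peak_h=4.0, washout_per_h=0.0005),
    "lung": OrganPK(kind="uptake", peak=9.0, t_peak_h=2.0, washout_per_h=0.001),
    "heart": OrganPK(kind="uptake", peak=7.0, t_peak_h=2.0, washout_per_h=0.0008),
    "femur": OrganPK(kind="uptake", peak=4.0, t_peak_h=24.0, washout_per_h=0.0002),
    "bone": OrganPK(kind="uptake", peak=3.0, t_peak_h=24.0, washout_per_h=0.0001),
}

_TUMOR_ORGANS: dict[str, OrganPK] = {
    "blood": OrganPK(kind="biexp", A=10.0, B=25.0, alpha=0.09, beta=0.003),
    "tumor": OrganPK(kind="uptake", peak=28.2, t_peak_h=96.0, washout_per_h=0.0),
    "spleen": OrganPK(kind="uptake", peak=31.6, t_peak_h=48.0, washout_per_h=0.0001),
    "liver": OrganPK(kind="uptake", peak=7.1, t_peak_h=24.0, washout_per_h=0.0001),
    "marrow": OrganPK(kind="uptake", peak=7.2, t_peak_h=24.0, washout_per_h=0.0002),
    "femur": OrganPK(kind="uptake", peak=5.1, t_peak_h=48.0, washout_per_h=0.0001),
    "kidney": OrganPK(kind="uptake", peak=9.0, t_peak_h=4.0, washout_per_h=0.0002),
}


def default_wildtype_params(**overrides) -> PKParams:
    return replace(PKParams(organ_models=dict(_WILDTYPE_ORGANS)), **overrides)


def default_tumor_params(**overrides) -> PKParams:
    return replace(PKParams(organ_models=dict(_TUMOR_ORGANS)), **overrides)


def simulate_biodistribution(
    params: Optional[PKParams] = None,
    organs: Optional[Sequence[str]] = None,
    times_h: Sequence[float] = DEFAULT_TIMES_H,
    scenario: str = "wildtype",
    seed: Optional[int] = None,
) -> list[BiodistributionSample]:
    """Draw a destructive-sampling biodistribution study.

    Each (organ, timepoint) gets ``n_per_timepoint`` animals; every animal
    contributes all organs at its sacrifice time. Noise is mean-preserving
    log-normal: value = mean(t) · exp(σZ − σ²/2), so cohort means converge
    to the deterministic model. Same seed → identical output.
    """
    if params is None:
        if scenario == "wildtype":
            params = default_wildtype_params()
        elif scenario == "tumor_bearing":
            params = default_tumor_params()
        else:
            raise ConfigError(f"unknown scenario '{scenario}'")
    organs = list(organs) if organs is not None else sorted(params.organ_models)
    unknown = [o for o in organs if o not in params.organ_models]
    if unknown:
        raise ConfigError(f"no PK model for organ(s): {unknown}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    sigma = params.noise_sd_log
    samples: list[BiodistributionSample] = []
    for t in times_h:
        for i in range(params.n_per_timepoint):
            sid = f"{scenario}-t{t:07.1f}h-{i + 1:02d}"
            for organ in organs:
                mu = params.organ_models[organ].mean(t)
                noise = math.exp(sigma * rng.standard_normal() - 0.5 * sigma**2)
                samples.append(
                    BiodistributionSample(
                        subject_id=sid,
                        organ=organ,
                        time_h=float(t),
                        pct_ia_per_g=mu * noise,
                    )
                )
    return samples


# ---------------------------------------------------------------------------
# therapy cohorts


@dataclass(frozen=True)
class CohortEffect:
    """Treatment effect of one arm: instantaneous log10 cell kill at the
    treatment day and the probability that residual disease regrows."""

    kill_log10: float
    regrowth_prob: float
    toxicity_dip: float = 0.0  # fractional transient weight dip (nadir ~d27)

    def __post_init__(self) -> None:
        if self.kill_log10 < 0 or not 0 <= self.regrowth_prob <= 1:
            raise InputError("kill must be >= 0 and regrowth probability in [0,1]")


DEFAULT_COHORT_EFFECTS: dict[str, CohortEffect] = {
    "untreated": CohortEffect(0.0, 1.0),
    "ofatumumab": CohortEffect(0.0, 1.0),
    "igg_low": CohortEffect(0.3, 1.0),
    "igg_high": CohortEffect(0.5, 1.0),
    "ac_ofa_low": CohortEffect(4.8, 0.5, toxicity_dip=0.03),
    "ac_ofa_high": CohortEffect(6.5, 0.1, toxicity_dip=0.065),
}


@dataclass(frozen=True)
class TherapySimParams:
    """Disseminated-model simulation settings.

    Defaults: 1e6 cells injected, growth 0.44/day (≈1.6 d doubling), flux
    1 photon/s per cell, hind-limb-paralysis threshold at 1e10 cells —
    untreated animals cross at ≈20–21 d, matching the typical 19–21 d
    time-to-endpoint of this model. Treatment on day 8; study ends day 200.
    """

    initial_cells: float = 1.0e6
    growth_per_day: float = 0.44
    flux_per_cell: float = 1.0
    treatment_day: float = 8.0
    hlp_threshold_cells: float = 1.0e10
    clearance_per_day: float = 0.5  # decay of killed, non-regrowing burden
    termination_day: float = 200.0
    n_per_cohort: int = 10
    growth_sd_log: float = 0.06
    burden_sd_log: float = 0.2
    bli_noise_sd_log: float = 0.115
    baseline_weight_g: float = 20.0
    weight_gain_per_day: float = 0.015
    weight_loss_event_fraction: float = 0.2
    cohort_effects: Mapping[str, CohortEffect] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_EFFECTS)
    )
    seed: int = 20230

    def __post_init__(self) -> None:
        if not self.termination_day > self.treatment_day >= 0:
            raise InputError("need termination day > treatment day >= 0")
        if min(self.initial_cells, self.hlp_threshold_cells, self.flux_per_cell) <= 0:
            raise InputError("cell counts, threshold, and flux per cell must be > 0")
        if self.growth_per_day < 0:
            raise InputError("growth rate must be >= 0")


def default_therapy_params(**overrides) -> TherapySimParams:
    return TherapySimParams(**overrides)


#: imaging schedule: twice weekly through day 27, then weekly
def _imaging_days(termination: float) -> list[float]:
    days = [3.0, 6.0, 10.0, 13.0, 17.0, 20.0, 24.0, 27.0]
    d = 34.0
    while d <= termination:
        days.append(d)
        d += 7.0
    return days


def _burden(t: float, n0: float, g: float, t_treat: float,
            regrows: bool, clearance: float, kill: float) -> float:
    """Tumor-cell burden at day t under grow → kill → regrow-or-clear."""
    if t <= t_treat:
        return n0 * math.exp(g * t)
    n_at_treat = n0 * math.exp(g * t_treat) * 10.0 ** (-kill)
    if regrows:
        return n_at_treat * math.exp(g * (t - t_treat))
    n = n_at_treat * math.exp(-clearance * (t - t_treat))
    return n if n >= 1.0 else 0.0


def simulate_therapy_cohort(
    params: Optional[TherapySimParams] = None,
    cohort_labels: Sequence[str] = ("untreated",),
    seed: Optional[int] = None,
) -> list[SubjectRecord]:
    """Simulate per-animal outcomes for the requested arms.

    Events: the first day the burden crosses the hind-limb-paralysis
    threshold (censor cause HLP) or weight falls more than 20% below
    baseline (weight_loss); animals alive at the termination day are
    censored for study_termination. Complete eradication (infinite kill, no
    regrowth) leaves every treated animal disease-free with zero final flux.
    """
    params = params or default_therapy_params()
    unknown = [c for c in cohort_labels if c not in params.cohort_effects]
    if unknown:
        raise ConfigError(f"no dose mapping for cohort(s): {unknown}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    records: list[SubjectRecord] = []
    for label in cohort_labels:
        eff = params.cohort_effects[label]
        for i in range(params.n_per_cohort):
            records.append(
                _simulate_subject(f"{label}-{i + 1:02d}", label, eff, params, rng)
            )
    return records


def _simulate_subject(
    sid: str, label: str, eff: CohortEffect, p: TherapySimParams, rng
) -> SubjectRecord:
    g = p.growth_per_day * math.exp(p.growth_sd_log * rng.standard_normal())
    n0 = p.initial_cells * math.exp(p.burden_sd_log * rng.standard_normal())
    regrows = bool(rng.random() < eff.regrowth_prob) and not math.isinf(eff.kill_log10)
    kill = eff.kill_log10
    w0 = p.baseline_weight_g * math.exp(0.05 * rng.standard_normal())

    def burden(t: float) -> float:
        return _burden(t, n0, g, p.treatment_day, regrows, p.clearance_per_day, kill)

    def weight(t: float) -> float:
        w = w0 + p.weight_gain_per_day * t
        frac = min(burden(t) / p.hlp_threshold_cells, 1.0)
        w *= 1.0 - 0.25 * frac**1.5  # cachexia as the endpoint nears
        if eff.toxicity_dip > 0 and t >= p.treatment_day:
            w *= 1.0 - eff.toxicity_dip * math.exp(-(((t - 27.0) / 15.0) ** 2))
        return w

    # daily scan for the first endpoint crossing
    event_day, cause = None, None
    for day in range(1, int(p.termination_day) + 1):
        t = float(day)
        if burden(t) >= p.hlp_threshold_cells:
            event_day, cause = t, "HLP"
            break
        if weight(t) <= (1.0 - p.weight_loss_event_fraction) * w0:
            event_day, cause = t, "weight_loss"
            break
    if event_day is None:
        event_day, cause = p.termination_day, "study_termination"

    bli = []
    for d in _imaging_days(p.termination_day):
        if d > event_day:
            break
        n = burden(d)
        if n <= 0:
            bli.append((d, 0.0))
        else:
            noise = math.exp(p.bli_noise_sd_log * rng.standard_normal())
            bli.append((d, n * p.flux_per_cell * noise))
    weights = []
    for d in range(0, int(event_day) + 1, 3):
        weights.append((float(d), weight(float(d)) * math.exp(0.01 * rng.standard_normal())))

    return SubjectRecord(
        subject_id=sid,
        cohort=label,
        event_day=event_day,
        event_type="censored",
        censor_cause=cause,
        bli=tuple(bli),
        weight=tuple(weights),
    )


def write_fixture_bundle(out_dir, seed: int = 20230) -> dict[str, Path]:
    """Emit the CSV fixture set consumed by the other modules' readers.

    Files: biodistribution.csv (raw wild-type samples),
    biodistribution_summary.csv, cohorts.csv, bli.csv, weights.csv. Output is
    deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    samples = simulate_biodistribution(default_wildtype_params(seed=seed))
    paths["biodistribution"] = out_dir / "biodistribution.csv"
    write_samples_csv(samples, paths["biodistribution"])
    series = summarize(samples)
    paths["biodistribution_summary"] = out_dir / "biodistribution_summary.csv"
    series.data.to_csv(paths["biodistribution_summary"], index=False)

    records = simulate_therapy_cohort(
        default_therapy_params(seed=seed),
        cohort_labels=("untreated", "ofatumumab", "igg_low", "igg_high", "ac_ofa_low", "ac_ofa_high"),
    )
    cohort, bli, weight = records_to_frames(records)
    for name, df in (("cohorts", cohort), ("bli", bli), ("weights", weight)):
        paths[name] = out_dir / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    return paths
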