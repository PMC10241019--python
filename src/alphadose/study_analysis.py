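"""Therapy-efficacy statistics for preclinical cohorts.

Kaplan–Meier survival with cause-aware censoring, Mantel–Cox (log-rank)
cohort comparison, bioluminescence (BLI) normalization and log-linear
growth-rate estimation, slope comparison by one-way ANOVA, and per-day
weight comparisons between arms.

Censoring convention: animals euthanized for disease-attributable humane
endpoints (hind-limb paralysis, >20% weight loss, morbidity) count as
events; scheduled study termination and deaths unrelated to disease are
censored. The set of disease-attributable causes is configurable per
analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from ._errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord",
    "SurvivalCurve",
    "DISEASE_CAUSES",
    "km_curve",
    "logrank_test",
    "bli_normalize",
    "log_growth_slope",
    "compare_slopes",
    "weight_compare",
]

CENSOR_CAUSES = {"HLP", "weight_loss", "morbidity", "study_termination", "other", "none"}
DISEASE_CAUSES = frozenset({"HLP", "weight_loss", "morbidity"})


@dataclass(frozen=True)
class SubjectRecord:
    """One animal: cohort, outcome, and its BLI / weight time series.

    ``event_type`` is "death" for spontaneous deaths and "censored" for
    euthanasias and scheduled termination, with ``censor_cause`` naming the
    reason; whether a euthanasia counts as an event is decided at analysis
    time (see ``DISEASE_CAUSES``). ``bli`` is a list of (day, total flux in
    photons/s); ``weight`` a list of (day, grams).
    """

    subject_id: str
    cohort: str
    event_day: float
    event_type: str  # "death" | "censored"
    censor_cause: str = "none"
    bli: tuple[tuple[float, float], ...] = ()
    weight: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.event_day < 0:
            raise InputError(f"{self.subject_id}: event day must be >= 0")
        if self.event_type not in ("death", "censored"):
            raise InputError(f"{self.subject_id}: unknown event type '{self.event_type}'")
        if self.censor_cause not in CENSOR_CAUSES:
            raise InputError(f"{self.subject_id}: unknown censor cause '{self.censor_cause}'")
        if (self.censor_cause == "none") != (self.event_type == "death"):
            raise InputError(f"{self.subject_id}: censor_cause must be 'none' iff death")
        for name, series in (("bli", self.bli), ("weight", self.weight)):
            days = [d for d, _ in series]
            if any(b <= a for a, b in zip(days, days[1:])):
                raise InputError(f"{self.subject_id}: {name} days must be ascending")
        if any(f < 0 for _, f in self.bli):
            raise InputError(f"{self.subject_id}: flux must be >= 0")
        if any(w <= 0 for _, w in self.weight):
            raise InputError(f"{self.subject_id}: weight must be > 0")

    def is_event(self, disease_causes: frozenset[str] = DISEASE_CAUSES) -> bool:
        if self.event_type == "death":
            return True
        return self.censor_cause in disease_causes


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: step times, S(t), numbers at risk, median."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: Optional[float]  # None when S never reaches 0.5

    def survival_at(self, day: float) -> float:
        idx = np.searchsorted(self.times, day, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _durations_events(
    cohort: Sequence[SubjectRecord], disease_causes: frozenset[str]
) -> tuple[np.ndarray, np.ndarray]:
    if not cohort:
        raise InputError("empty cohort")
    durations = np.array([r.event_day for r in cohort], dtype=float)
    events = np.array([r.is_event(disease_causes) for r in cohort], dtype=bool)
    return durations, events


def km_curve(
    cohort: Sequence[SubjectRecord], disease_causes: frozenset[str] = DISEASE_CAUSES
) -> SurvivalCurve:
    """Kaplan–Meier product-limit curve with right censoring.

    Ties are handled the standard way (deaths precede censorings at the same
    time). The median is the first time S(t) ≤ 0.5, or None ("not
    determinable") when fewer than half the subjects have events.
    """
    durations, events = _durations_events(cohort, disease_causes)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    event_times = table.index[table["observed"] > 0].to_numpy(dtype=float)
    surv = np.array([float(kmf.predict(t)) for t in event_times])
    at_risk = table.loc[table["observed"] > 0, "at_risk"].to_numpy(dtype=float)
    median = kmf.median_survival_time_
    median = None if np.isinf(median) else float(median)
    return SurvivalCurve(times=event_times, survival=surv, at_risk=at_risk, median=median)


def logrank_test(
    a: Sequence[SubjectRecord],
    b: Sequence[SubjectRecord],
    disease_causes: frozenset[str] = DISEASE_CAUSES,
) -> tuple[float, float]:
    """Mantel–Cox log-rank comparison of two cohorts: (chi-square, p)."""
    da, ea = _durations_events(a, disease_causes)
    db, eb = _durations_events(b, disease_causes)
    if not (ea.any() or eb.any()) and np.all(da == 0) and np.all(db == 0):
        raise InputError("all subjects censored at time 0; log-rank undefined")
    res = _ll_logrank(da, db, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def bli_normalize(record: SubjectRecord) -> list[tuple[float, float]]:
    """Flux series divided by the first imaging time point's flux."""
    if not record.bli:
        raise InputError(f"{record.subject_id}: no BLI points")
    first = record.bli[0][1]
    if not first > 0:
        raise InputError(f"{record.subject_id}: first BLI point must have positive flux")
    return [(day, flux / first) for day, flux in record.bli]


def log_growth_slope(record: SubjectRecord, window: tuple[float, float] = (10.0, 20.0)) -> float:
    """OLS slope of log10(flux) vs. day inside the half-open window [start, end).

    The slope is the tumor-burden growth rate in log10 photons/s per day;
    doubling every 2 days gives log10(2)/2 ≈ 0.1505. Points with zero flux
    carry no burden signal on the log scale and are excluded.
    """
    start, end = window
    pts = [(d, f) for d, f in record.bli if start <= d < end and f > 0]
    if len(pts) < 2:
        raise InputError(
            f"{record.subject_id}: need >= 2 positive BLI points in [{start}, {end})"
        )
    days = np.array([d for d, _ in pts])
    logf = np.log10([f for _, f in pts])
    if np.all(days == days[0]):
        raise InputError(f"{record.subject_id}: all BLI points at one day")
    return float(stats.linregress(days, logf).slope)


def cohort_slopes(
    records: Iterable[SubjectRecord], window: tuple[float, float] = (10.0, 20.0)
) -> dict[str, list[float]]:
    """Per-subject growth slopes grouped by cohort; subjects without enough
    usable points are skipped with a log message."""
    out: dict[str, list[float]] = {}
    for rec in records:
        try:
            slope = log_growth_slope(rec, window)
        except InputError as exc:
            logger.warning("skipping %s: %s", rec.subject_id, exc)
            continue
        out.setdefault(rec.cohort, []).append(slope)
    return out


def compare_slopes(
    cohorts: Mapping[str, Sequence[float]],
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across cohort slope sets, plus pairwise t contrasts.

    Cohorts with fewer than two slopes are excluded with a warning. Returns
    (F, p, pairwise) where ``pairwise`` has columns cohort_a, cohort_b, t, p.
    """
    usable = {}
    for label, slopes in cohorts.items():
        if len(slopes) < 2:
            warnings.warn(f"cohort '{label}' has < 2 slopes; excluded from ANOVA")
            continue
        usable[label] = np.asarray(slopes, dtype=float)
    if len(usable) < 2:
        raise InputError("need >= 2 cohorts with >= 2 slopes each")
    groups = list(usable.values())
    if np.ptp(np.concatenate(groups)) == 0:  # no variance anywhere -> F = 0
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*groups)
        f_stat, p = float(f_stat), float(p)
    labels = list(usable)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            t, tp = stats.ttest_ind(usable[la], usable[lb])
            rows.append((la, lb, float(t), float(tp)))
    pairwise = pd.DataFrame(rows, columns=["cohort_a", "cohort_b", "t", "p"])
    return f_stat, p, pairwise


def weight_compare(
    cohort_a: Sequence[SubjectRecord],
    cohort_b: Sequence[SubjectRecord],
    days: Optional[Sequence[float]] = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-day Welch comparison of body weights between two arms.

    Only days present in both cohorts are compared (optionally restricted to
    ``days``). No multiplicity correction by default, matching per-timepoint
    reporting conventions; ``holm=True`` adds Holm-adjusted p-values.
    Returns columns day, mean_a, mean_b, mean_diff, t, p [, p_holm].
    """

    def by_day(cohort):
        out: dict[float, list[float]] = {}
        for rec in cohort:
            for day, w in rec.weight:
                out.setdefault(day, []).append(w)
        return out

    wa, wb = by_day(cohort_a), by_day(cohort_b)
    common = sorted(set(wa) & set(wb))
    if days is not None:
        common = [d for d in common if d in set(days)]
    if not common:
        raise InputError("no overlapping measurement days")
    rows = []
    for day in common:
        xa, xb = np.asarray(wa[day]), np.asarray(wb[day])
        if len(xa) > 1 and len(xb) > 1 and (np.ptp(xa) > 0 or np.ptp(xb) > 0):
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
        else:
            t, p = (0.0, 1.0) if np.mean(xa) == np.mean(xb) else (np.inf, 0.0)
        rows.append((day, xa.mean(), xb.mean(), xa.mean() - xb.mean(), float(t), float(p)))
    df = pd.DataFrame(rows, columns=["day", "mean_a", "mean_b", "mean_diff", "t", "p"])
    if holm:
        from statsmodels.stats.multitest import multipletests

        df["p_holm"] = multipletests(df["p"].to_numpy(), method="holm")[1]
    return df


# ---------------------------------------------------------------------------
# CSV I/O for cohort records


def records_to_frames(records: Sequence[SubjectRecord]):
    """(cohort, bli, weight) DataFrames in the documented CSV schemas."""
    cohort = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "cohort": [r.cohort for r in records],
            "event_day": [r.event_day for r in records],
            "event_type": [r.event_type for r in records],
            "censor_cause": [r.censor_cause for r in records],
        }
    )
    bli = pd.DataFrame(
        [(r.subject_id, d, f) for r in records for d, f in r.bli],
        columns=["subject_id", "day", "total_flux"],
    )
    weight = pd.DataFrame(
        [(r.subject_id, d, w) for r in records for d, w in r.weight],
        columns=["subject_id", "day", "weight_g"],
    )
    return cohort, bli, weight


def records_from_frames(
    cohort: pd.DataFrame, bli: Optional[pd.DataFrame] = None, weight: Optional[pd.DataFrame] = None
) -> list[SubjectRecord]:
    def series_for(df, sid, value_col):
        if df is None or df.empty:
            return ()
        sub = df[df["subject_id"] == sid].sort_values("day")
        return tuple(zip(sub["day"].astype(float), sub[value_col].astype(float)))

    out = []
    for _, row in cohort.iterrows():
        sid = str(row["subject_id"])
        out.append(
            SubjectRecord(
                subject_id=sid,
                cohort=str(row["cohort"]),
                event_day=float(row["event_day"]),
                event_type=str(row["event_type"]),
                censor_cause=str(row["censor_cause"]),
                bli=series_for(bli, sid, "total_flux"),
                weight=series_for(weight, sid, "weight_g"),
            )
        )
    return out
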