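"""Nuclear data model for the ²²⁵Ac decay chain.

²²⁵Ac (t½ 9.92 d) decays through a short serial chain — ²²¹Fr, ²¹⁷At, ²¹³Bi,
and either ²¹³Po (98%, beta then alpha) or ²⁰⁹Tl (2%, alpha then beta) — to
²⁰⁹Pb and finally stable ²⁰⁹Bi, emitting four net alpha particles per parent
decay. Because every alpha-emitting daughter is far shorter-lived than the
parent, the chain reaches secular equilibrium within hours and the total
alpha energy released per parent transformation can be summed with simple
branch weighting. This module holds the nuclide data, computes that per-decay
alpha energy (the MIRD mean energy per transformation, Δ), and provides an
analytic branch-weighted Bateman solver used to verify the equilibrium
assumption numerically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import InputError

MEV_TO_J = 1.602176634e-13

__all__ = [
    "Nuclide",
    "DecayChain",
    "build_ac225_chain",
    "load_chain",
    "mean_alpha_energy_per_decay",
    "bateman_activities",
    "physical_decay_factor",
    "MEV_TO_J",
]


@dataclass(frozen=True)
class Branch:
    daughter: str
    fraction: float
    mode: str  # "alpha" or "beta"


@dataclass(frozen=True)
class Nuclide:
    """One chain member: decay constants and its mean alpha energy per decay.

    ``mean_alpha_energy`` is the alpha energy emitted per decay of this
    nuclide in MeV, already averaged over its branches (so for ²¹³Bi it is
    the 2% alpha branch's energy times 0.02). ``half_life`` is in seconds;
    stable nuclides carry ``half_life = inf`` and ``decay_constant = 0``.
    """

    name: str
    half_life: float
    mean_alpha_energy: float = 0.0
    branches: tuple[Branch, ...] = ()

    @property
    def decay_constant(self) -> float:
        return 0.0 if math.isinf(self.half_life) else math.log(2.0) / self.half_life

    @property
    def stable(self) -> bool:
        return math.isinf(self.half_life)

    def __post_init__(self) -> None:
        if not (self.half_life > 0):
            raise InputError(f"{self.name}: half-life must be positive")
        if self.mean_alpha_energy < 0:
            raise InputError(f"{self.name}: mean alpha energy must be >= 0")
        has_alpha = any(b.mode == "alpha" for b in self.branches)
        if (self.mean_alpha_energy > 0) != has_alpha:
            raise InputError(
                f"{self.name}: mean_alpha_energy > 0 requires an alpha branch (and vice versa)"
            )
        if self.branches:
            total = sum(b.fraction for b in self.branches)
            if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
                raise InputError(f"{self.name}: branch fractions sum to {total}, expected 1")
            for b in self.branches:
                if not (0.0 <= b.fraction <= 1.0):
                    raise InputError(f"{self.name}: branch fraction {b.fraction} outside [0,1]")


@dataclass(frozen=True)
class DecayChain:
    """A topologically ordered decay chain rooted at ``parent``.

    ``path_weight`` maps each member to the cumulative branching fraction of
    reaching it from the parent (summed over all decay paths when branches
    re-merge, as ²¹³Po and ²⁰⁹Tl do at ²⁰⁹Pb).
    """

    members: tuple[Nuclide, ...]
    path_weight: dict[str, float] = field(default_factory=dict)

    @property
    def parent(self) -> Nuclide:
        return self.members[0]

    def __post_init__(self) -> None:
        names = [n.name for n in self.members]
        if len(set(names)) != len(names):
            raise InputError("duplicate nuclide in chain")
        seen: set[str] = set()
        for nuc in self.members:
            for b in nuc.branches:
                if b.daughter in seen:
                    raise InputError(f"chain is not topologically ordered at {b.daughter}")
            seen.add(nuc.name)
        if not self.path_weight:
            object.__setattr__(self, "path_weight", _path_weights(self.members))
        for name, w in self.path_weight.items():
            if not (0.0 < w <= 1.0):
                raise InputError(f"path weight of {name} is {w}, outside (0,1]")

    def __getitem__(self, name: str) -> Nuclide:
        for nuc in self.members:
            if nuc.name == name:
                return nuc
        raise KeyError(name)

    def alpha_branch_weight(self, name: str) -> float:
        """Cumulative probability that ``name`` is reached *and* decays by alpha."""
        nuc = self[name]
        alpha = sum(b.fraction for b in nuc.branches if b.mode == "alpha")
        return self.path_weight[name] * alpha


def _path_weights(members: Sequence[Nuclide]) -> dict[str, float]:
    weights = {members[0].name: 1.0}
    for nuc in members:
        for b in nuc.branches:
            weights[b.daughter] = weights.get(b.daughter, 0.0) + weights[nuc.name] * b.fraction
    return {n.name: weights[n.name] for n in members if n.name in weights}


def load_chain(source) -> DecayChain:
    """Build a chain from a JSON document (path, file object, or parsed dict)."""
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    members = []
    for rec in doc["nuclides"]:
        hl = rec["half_life_s"]
        members.append(
            Nuclide(
                name=rec["name"],
                half_life=math.inf if hl is None else float(hl),
                mean_alpha_energy=float(rec["mean_alpha_energy_mev"]),
                branches=tuple(Branch(d, float(f), m) for d, f, m in rec["branches"]),
            )
        )
    return DecayChain(members=tuple(members))


def build_ac225_chain() -> DecayChain:
    """The packaged ²²⁵Ac → ²⁰⁹Bi chain (ICRP Publication 107 nuclear data)."""
    ref = resources.files("alphadose.data").joinpath("ac225_decay_chain.json")
    with ref.open(encoding="utf-8") as fh:
        return load_chain(fh)


def mean_alpha_energy_per_decay(chain: DecayChain) -> float:
    """Total alpha energy emitted per parent decay, in J (MIRD Δ for the chain).

    Sums each member's branch-averaged alpha energy weighted by the
    probability of reaching it from the parent; order-independent and linear
    in each member's alpha energy. For the packaged ²²⁵Ac chain this is
    ≈4.4e-12 J per Bq·s.
    """
    mev = sum(chain.path_weight[n.name] * n.mean_alpha_energy for n in chain.members)
    return mev * MEV_TO_J


def physical_decay_factor(nuclide: Nuclide, elapsed: float) -> float:
    """Fraction of activity remaining after ``elapsed`` seconds: e^(−λt)."""
    if elapsed < 0:
        raise InputError(f"elapsed time must be >= 0, got {elapsed}")
    return math.exp(-nuclide.decay_constant * elapsed)


def _bateman_path(lams: np.ndarray, fracs: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Activity of the last nuclide of one decay path per unit parent activity.

    Standard Bateman solution for a serial path with decay constants ``lams``
    and branch fractions ``fracs`` (fracs[i] is the probability that member i
    feeds member i+1). Degenerate (equal) decay constants are perturbed by
    1e-9 relative, the usual guard for the analytic form.
    """
    lams = lams.astype(float).copy()
    # perturb duplicates so all pairwise differences are nonzero
    for i in range(1, len(lams)):
        while any(abs(lams[i] - lams[j]) <= 1e-12 * max(lams[i], lams[j]) for j in range(i)):
            lams[i] *= 1.0 + 1e-9
    n = len(lams)
    if n == 1:
        return np.exp(-lams[0] * times)
    lam_n = lams[-1]
    if lam_n == 0.0:  # stable end nuclide: activity identically zero
        return np.zeros_like(times)
    # A_n(t) = A_1(0) * (lam_n/lam_1) * prod(f_i lam_i, i<n) * sum_i e^{-lam_i t}/prod_{j!=i}(lam_j-lam_i)
    coeff = lam_n / lams[0] * np.prod(fracs * lams[:-1])
    out = np.zeros_like(times, dtype=float)
    for i in range(n):
        denom = np.prod([lams[j] - lams[i] for j in range(n) if j != i])
        out += np.exp(-lams[i] * times) / denom
    out = coeff * out
    out[times == 0.0] = 0.0  # exact: no daughter has grown in yet
    np.clip(out, 0.0, None, out=out)  # cancellation can leave tiny negatives
    return out


def _paths_to(chain: DecayChain, target: str) -> Iterable[tuple[list[str], list[float]]]:
    """All branch paths parent → target, as (member names, branch fractions)."""

    def walk(name: str, path: list[str], fracs: list[float]):
        if name == target:
            yield path + [name], fracs
            return
        for b in chain[name].branches:
            yield from walk(b.daughter, path + [name], fracs + [b.fraction])

    yield from walk(chain.parent.name, [], [])


def bateman_activities(
    chain: DecayChain, parent_activity_at_t0: float, times: Sequence[float]
) -> pd.DataFrame:
    """Activity of every chain member over time, Bq, analytic Bateman solution.

    ``times`` must be ascending and nonnegative; the parent column is a pure
    exponential, daughters grow in toward their branch-weighted secular
    equilibrium with the parent. Returns a DataFrame indexed by time (s) with
    one column per member.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise InputError("times must be a 1-D sequence")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly ascending")
    if np.any(t < 0):
        raise InputError("times must be >= 0")
    if parent_activity_at_t0 < 0:
        raise InputError("parent activity must be >= 0")

    cols = {}
    for nuc in chain.members:
        total = np.zeros_like(t)
        for names, fracs in _paths_to(chain, nuc.name):
            lams = np.array([chain[nm].decay_constant for nm in names])
            total += _bateman_path(lams, np.array(fracs), t)
        cols[nuc.name] = parent_activity_at_t0 * total
    return pd.DataFrame(cols, index=pd.Index(t, name="time_s"))
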