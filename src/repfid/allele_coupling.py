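"""Stochastic models of two alleles sharing an upstream regulator.

Two copies of a gene transcribed as independent linear birth–death processes
produce a product-of-Poissons joint mRNA count distribution.  When both birth
rates are modulated by a shared, fluctuating upstream regulator ``X`` the
stationary joint law becomes a Poisson mixture over the regulator density; for
a Gamma-distributed regulator this is the bivariate negative binomial (BNB).
The inter-allele covariance is ``λ1·λ2·Var(x)`` for *any* regulator law, so
extrinsic regulatory noise couples the alleles, while intrinsic noise from
two-state (telegraph) transcriptional bursting always reduces the covariance
to ``(w·λ+ + (1−w)·λ−)²·Var(x)`` in the slow-switching regime.

This module provides closed-form PMFs, moments, exact compound samplers and a
Gillespie simulation of the bursting two-allele system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._errors import (
    DomainError,
    InconsistentKineticsError,
    UndefinedStatisticError,
    UnsupportedModelError,
)

__all__ = [
    "AlleleKinetics",
    "RegulatorDistribution",
    "BurstKinetics",
    "JointCountModel",
    "SsaResult",
    "poisson_joint_pmf",
    "bnb_joint_pmf",
    "joint_covariance",
    "allelic_correlation",
    "bursty_covariance",
    "sample_joint_counts",
    "simulate_telegraph_ssa",
]

_EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class AlleleKinetics:
    """Birth/decay rates of the two alleles.

    The stationary mean count of allele ``i`` under a unit regulator is
    ``lam_i = birth_rate_i / decay_rate_i``.
    """

    birth_rate_1: float
    birth_rate_2: float
    decay_rate_1: float
    decay_rate_2: float

    def __post_init__(self) -> None:
        for name in ("birth_rate_1", "birth_rate_2", "decay_rate_1", "decay_rate_2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be finite and > 0, got {v!r}")

    @classmethod
    def from_means(cls, lam1: float, lam2: float, decay_rate: float = 1.0) -> "AlleleKinetics":
        """Build kinetics with given stationary means and a common decay rate."""
        return cls(lam1 * decay_rate, lam2 * decay_rate, decay_rate, decay_rate)

    @property
    def lam1(self) -> float:
        return self.birth_rate_1 / self.decay_rate_1

    @property
    def lam2(self) -> float:
        return self.birth_rate_2 / self.decay_rate_2


@dataclass(frozen=True)
class RegulatorDistribution:
    """Stationary law of the shared upstream regulator concentration ``x``.

    Families
    --------
    constant : point mass at ``value``
    gamma    : shape–scale parameterization ``Gamma(shape, scale)``; mean
               ``shape·scale``, variance ``shape·scale²`` (protein
               concentrations are commonly Gamma-distributed)
    gumbel   : location–scale Gumbel; variance ``π²·scale²/6``
    empirical: resampling from a supplied sample vector
    """

    family: str
    value: float = 1.0
    shape: float = 1.0
    scale: float = 1.0
    loc: float = 0.0
    samples: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.family not in {"constant", "gamma", "gumbel", "empirical"}:
            raise DomainError(f"unknown regulator family {self.family!r}")
        if self.family == "gamma" and not (self.shape > 0 and self.scale > 0):
            raise DomainError("gamma regulator requires shape > 0 and scale > 0")
        if self.family == "gumbel" and not self.scale > 0:
            raise DomainError("gumbel regulator requires scale > 0")
        if self.family == "empirical":
            if self.samples is None or np.size(self.samples) == 0:
                raise DomainError("empirical regulator requires a nonempty sample vector")
            object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @classmethod
    def constant(cls, value: float = 1.0) -> "RegulatorDistribution":
        return cls(family="constant", value=value)

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "RegulatorDistribution":
        return cls(family="gamma", shape=shape, scale=scale)

    @classmethod
    def gumbel(cls, loc: float, scale: float) -> "RegulatorDistribution":
        return cls(family="gumbel", loc=loc, scale=scale)

    @classmethod
    def empirical(cls, samples) -> "RegulatorDistribution":
        return cls(family="empirical", samples=np.asarray(samples, dtype=float))

    def mean(self) -> float:
        if self.family == "constant":
            return self.value
        if self.family == "gamma":
            return self.shape * self.scale
        if self.family == "gumbel":
            return self.loc + _EULER_GAMMA * self.scale
        return float(np.mean(self.samples))

    def var(self) -> float:
        if self.family == "constant":
            return 0.0
        if self.family == "gamma":
            return self.shape * self.scale**2
        if self.family == "gumbel":
            return math.pi**2 * self.scale**2 / 6.0
        return float(np.var(self.samples))

    def fano(self) -> float:
        """Dispersion index Var(x)/E[x] of the regulator."""
        mu = self.mean()
        if mu <= 0:
            raise UndefinedStatisticError("Fano factor undefined for nonpositive mean")
        return self.var() / mu

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "constant":
            return np.full(n, self.value, dtype=float)
        if self.family == "gamma":
            return rng.gamma(self.shape, self.scale, size=n)
        if self.family == "gumbel":
            return rng.gumbel(self.loc, self.scale, size=n)
        return rng.choice(self.samples, size=n, replace=True)


@dataclass(frozen=True)
class BurstKinetics:
    """Two-state (telegraph) transcriptional bursting of one allele.

    ``rate_active``/``rate_inactive`` are the effective transcription levels
    λ₊ ≥ λ₋ on the same dimensionless scale as the constitutive λ;
    ``active_fraction`` w is the stationary occupancy of the active state.
    If switching rates are supplied, w = switch_on/(switch_on+switch_off).
    """

    rate_active: float
    rate_inactive: float
    active_fraction: Optional[float] = None
    switch_on: Optional[float] = None
    switch_off: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.rate_active >= self.rate_inactive >= 0):
            raise DomainError("require rate_active >= rate_inactive >= 0")
        if (self.switch_on is None) != (self.switch_off is None):
            raise DomainError("switch_on and switch_off must be given together")
        if self.switch_on is not None:
            if self.switch_on < 0 or self.switch_off < 0:
                raise DomainError("switching rates must be >= 0")
            tot = self.switch_on + self.switch_off
            if tot == 0:
                if self.active_fraction is None or 0 < self.active_fraction < 1:
                    raise InconsistentKineticsError(
                        "zero switching rates are inconsistent with 0 < w < 1"
                    )
            else:
                w = self.switch_on / tot
                if self.active_fraction is not None and abs(self.active_fraction - w) > 1e-12:
                    raise InconsistentKineticsError(
                        "active_fraction contradicts switch_on/(switch_on+switch_off)"
                    )
                object.__setattr__(self, "active_fraction", w)
        if self.active_fraction is None:
            raise DomainError("either active_fraction or switching rates are required")
        if not 0 <= self.active_fraction <= 1:
            raise DomainError("active_fraction must lie in [0, 1]")

    @property
    def w(self) -> float:
        return float(self.active_fraction)

    def mean_rate(self) -> float:
        """Time-averaged transcription level w·λ₊ + (1−w)·λ₋."""
        return self.w * self.rate_active + (1.0 - self.w) * self.rate_inactive


@dataclass(frozen=True)
class JointCountModel:
    """Joint model for the mRNA counts (m1, m2) of two coregulated alleles."""

    kinetics: AlleleKinetics
    regulator: RegulatorDistribution
    bursting: Optional[BurstKinetics] = None

    @property
    def a(self) -> float:
        """Allele asymmetry a = λ2/λ1."""
        return self.kinetics.lam2 / self.kinetics.lam1

    def _require_gamma(self) -> None:
        if self.regulator.family != "gamma":
            raise UnsupportedModelError(
                "closed-form BNB parameters require a gamma regulator, "
                f"got family={self.regulator.family!r}"
            )

    @property
    def p(self) -> float:
        """BNB success probability p = λ1·θ / [1 + θ(λ1+λ2)] (gamma regulator)."""
        self._require_gamma()
        th = self.regulator.scale
        l1, l2 = self.kinetics.lam1, self.kinetics.lam2
        return l1 * th / (1.0 + th * (l1 + l2))

    @property
    def q(self) -> float:
        """BNB success probability of allele 2: q = a·p."""
        return self.a * self.p


def _validate_counts(m1, m2) -> tuple[np.ndarray, np.ndarray]:
    m1 = np.asarray(m1)
    m2 = np.asarray(m2)
    for m in (m1, m2):
        if not np.issubdtype(m.dtype, np.integer):
            if not np.all(np.equal(np.mod(m, 1), 0)):
                raise DomainError("counts must be integers")
        if np.any(m < 0):
            raise DomainError("counts must be >= 0")
    return m1.astype(np.int64), m2.astype(np.int64)


def poisson_joint_pmf(kinetics: AlleleKinetics, m1, m2) -> np.ndarray | float:
    """Stationary joint PMF of two uncoupled constitutive alleles.

    ``p(m1, m2) = λ1^m1 e^{−λ1}/m1! · λ2^m2 e^{−λ2}/m2!`` evaluated in log
    space.  Accepts scalar or array counts (broadcast).
    """
    m1, m2 = _validate_counts(m1, m2)
    l1, l2 = kinetics.lam1, kinetics.lam2
    logp = (
        m1 * math.log(l1)
        - l1
        - gammaln(m1 + 1.0)
        + m2 * math.log(l2)
        - l2
        - gammaln(m2 + 1.0)
    )
    out = np.exp(logp)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def bnb_joint_pmf(model: JointCountModel, m1, m2) -> np.ndarray | float:
    """Bivariate negative binomial joint PMF for a Gamma-mixed pair of alleles.

    ``p(m1,m2) = Γ(m1+m2+r)/(m1! m2! Γ(r)) (1−p−q)^r p^{m1} q^{m2}`` with
    ``p = λ1θ/[1+θ(λ1+λ2)]`` and ``q = (λ2/λ1)·p``; computed via log-gamma.
    """
    m1, m2 = _validate_counts(m1, m2)
    r = model.regulator.shape
    p, q = model.p, model.q
    logpmf = (
        gammaln(m1 + m2 + r)
        - gammaln(m1 + 1.0)
        - gammaln(m2 + 1.0)
        - gammaln(r)
        + r * math.log1p(-p - q)
        + m1 * math.log(p)
        + m2 * math.log(q)
    )
    out = np.exp(logpmf)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def joint_covariance(model: JointCountModel) -> float:
    """Inter-allele count covariance ``λ1·λ2·Var(x)``.

    Holds for any regulator family (a constant regulator gives 0): the
    covariance is proportional to the variance of the upstream regulator and
    to the sensitivities of both alleles to it.
    """
    v = model.regulator.var()
    if not np.isfinite(v):
        raise DomainError("regulator variance must be finite")
    return model.kinetics.lam1 * model.kinetics.lam2 * v


def allelic_correlation(model: JointCountModel) -> float:
    """Pearson correlation of the two allele outputs.

    ``Var(m_i) = λ_i·E[x] + λ_i²·Var(x)`` (law of total variance for a mixed
    Poisson), so for kinetically identical alleles the correlation is
    ``λF/(1+λF)`` where ``F`` is the regulator Fano factor — monotone
    increasing in ``F``.
    """
    mu, v = model.regulator.mean(), model.regulator.var()
    if not (np.isfinite(mu) and np.isfinite(v)):
        raise DomainError("regulator mean and variance must be finite")
    l1, l2 = model.kinetics.lam1, model.kinetics.lam2
    var1 = l1 * mu + l1**2 * v
    var2 = l2 * mu + l2**2 * v
    if var1 <= 0 or var2 <= 0:
        raise UndefinedStatisticError("correlation undefined: an allele has zero variance")
    return l1 * l2 * v / math.sqrt(var1 * var2)


def bursty_covariance(bursting: BurstKinetics, regulator: RegulatorDistribution) -> float:
    """Slow-switching inter-allele covariance ``(wλ₊+(1−w)λ₋)²·Var(x)``.

    Valid when promoter switching is slow relative to mRNA decay (documented
    contract, not enforced).  Always ≤ the constitutive value λ₊²·Var(x):
    bursting can only decorrelate the alleles.
    """
    return bursting.mean_rate() ** 2 * regulator.var()


def sample_joint_counts(model: JointCountModel, n: int, seed: int) -> pd.DataFrame:
    """Exact stationary sample of (m1, m2) by compounding.

    Draws ``x`` from the regulator, then conditionally independent
    ``Poisson(λ_i·x)`` counts.  Returns a DataFrame with columns
    ``replicate, m1, m2, x``; reproducible for a fixed seed.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = model.regulator.sample(n, rng)
    x = np.clip(x, 0.0, None)  # Gumbel support includes negatives; rates cannot
    m1 = rng.poisson(model.kinetics.lam1 * x)
    m2 = rng.poisson(model.kinetics.lam2 * x)
    return pd.DataFrame({"replicate": np.arange(n), "m1": m1, "m2": m2, "x": x})


@dataclass
class SsaResult:
    """Output of the telegraph-allele Gillespie simulation."""

    counts: pd.DataFrame  # columns replicate, m1, m2, x (stationary endpoint samples)
    occupancy_active: tuple[float, float]  # empirical active-state fraction per allele
    trajectory: pd.DataFrame  # event-time trajectory of replicate 0
    burn_in: float


def simulate_telegraph_ssa(
    kinetics: AlleleKinetics,
    bursting: BurstKinetics,
    regulator: RegulatorDistribution,
    t_end: float,
    seed: int,
    n_reps: int = 1000,
    record_trajectory: bool = True,
) -> SsaResult:
    """Exact Gillespie simulation of two bursting alleles with a shared regulator.

    Each of ``n_reps`` independent replicates (cells) draws one regulator value
    ``x`` held fixed for the whole episode (quenched extrinsic noise, matching
    the stationary-mixture picture) and simulates two 2-state promoters with
    mRNA birth propensity ``k_d^{(i)}·λ_state·x`` and per-molecule death
    ``k_d^{(i)}``.  Promoter states start from their stationary Bernoulli(w)
    law; counts start at zero, so ``t_end`` must span several decay times.
    The first 10% of each episode is discarded when accumulating the empirical
    active-state occupancy.
    """
    if t_end <= 0:
        raise DomainError("t_end must be > 0")
    if bursting.switch_on is None:
        raise DomainError("simulation requires explicit switching rates")
    if bursting.switch_on == bursting.switch_off == 0 and 0 < bursting.w < 1:
        raise InconsistentKineticsError("zero switching rates with 0 < w < 1")

    rng = np.random.default_rng(seed)
    kon, koff = float(bursting.switch_on), float(bursting.switch_off)
    lp, lm = float(bursting.rate_active), float(bursting.rate_inactive)
    kd1, kd2 = kinetics.decay_rate_1, kinetics.decay_rate_2
    burn = 0.1 * t_end

    x = np.clip(regulator.sample(n_reps, rng), 0.0, None)
    s1 = rng.random(n_reps) < bursting.w
    s2 = rng.random(n_reps) < bursting.w
    m1 = np.zeros(n_reps, dtype=np.int64)
    m2 = np.zeros(n_reps, dtype=np.int64)
    t = np.zeros(n_reps)

    occ_time = np.zeros(2)  # active time per allele, beyond burn-in
    obs_time = 0.0

    traj_t, traj_s1, traj_s2, traj_m1, traj_m2 = [0.0], [s1[0]], [s2[0]], [0], [0]

    active = np.ones(n_reps, dtype=bool)
    while active.any():
        idx = np.nonzero(active)[0]
        xs = x[idx]
        r_sw1 = np.where(s1[idx], koff, kon)
        r_sw2 = np.where(s2[idx], koff, kon)
        r_b1 = kd1 * np.where(s1[idx], lp, lm) * xs
        r_b2 = kd2 * np.where(s2[idx], lp, lm) * xs
        r_d1 = kd1 * m1[idx]
        r_d2 = kd2 * m2[idx]
        a = np.stack([r_sw1, r_sw2, r_b1, r_b2, r_d1, r_d2])
        total = a.sum(axis=0)

        stuck = total <= 0  # absorbing (w=0, λ₋=0, empty): jump straight to t_end
        dt = np.empty(idx.size)
        dt[stuck] = t_end - t[idx[stuck]]
        dt[~stuck] = rng.exponential(1.0 / total[~stuck])
        t_new = t[idx] + dt

        # occupancy accumulation on [max(t, burn), min(t_new, t_end)]
        seg = np.clip(np.minimum(t_new, t_end) - np.maximum(t[idx], burn), 0.0, None)
        occ_time[0] += float(np.sum(seg * s1[idx]))
        occ_time[1] += float(np.sum(seg * s2[idx]))
        obs_time += float(np.sum(seg))

        fire = (~stuck) & (t_new <= t_end)
        if fire.any():
            fidx = idx[fire]
            u = rng.random(fire.sum()) * total[fire]
            cum = np.cumsum(a[:, fire], axis=0)
            choice = (cum < u[None, :]).sum(axis=0)
            for react, sel in enumerate(choice == np.arange(6)[:, None]):
                tgt = fidx[sel]
                if tgt.size == 0:
                    continue
                if react == 0:
                    s1[tgt] = ~s1[tgt]
                elif react == 1:
                    s2[tgt] = ~s2[tgt]
                elif react == 2:
                    m1[tgt] += 1
                elif react == 3:
                    m2[tgt] += 1
                elif react == 4:
                    m1[tgt] -= 1
                else:
                    m2[tgt] -= 1
        t[idx] = np.minimum(t_new, t_end)
        active[idx] = t[idx] < t_end

        if record_trajectory and idx.size and idx[0] == 0 and t[0] <= t_end:
            traj_t.append(float(t[0]))
            traj_s1.append(bool(s1[0]))
            traj_s2.append(bool(s2[0]))
            traj_m1.append(int(m1[0]))
            traj_m2.append(int(m2[0]))

    counts = pd.DataFrame({"replicate": np.arange(n_reps), "m1": m1, "m2": m2, "x": x})
    occ = (occ_time[0] / obs_time, occ_time[1] / obs_time) if obs_time > 0 else (np.nan, np.nan)
    traj = pd.DataFrame(
        {"t": traj_t, "state1": traj_s1, "state2": traj_s2, "m1": traj_m1, "m2": traj_m2}
    )
    return SsaResult(counts=counts, occupancy_active=occ, trajectory=traj, burn_in=burn)
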