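"""Positive-feedback dynamics of a diploid master regulator and its reporters.

Total protein concentration ``n`` of a gene transcribed from two alleles with
basal rate ``c_b``, Hill-feedback production up to ``c_f`` (half-max ``K``,
coefficient ``H``) and first-order decay ``c_d`` obeys, after rescaling
``n = (2 c_f / c_d) n̄`` and ``t = τ / c_d``,

    dn̄/dτ = α + n̄^H / (γ^H + n̄^H) − n̄,

with ``α = c_b/c_f`` and ``γ = γ_wt = c_d K / (2 c_f)``.  For ``H > 1`` the
equation is bistable inside a wedge of the (α, γ) plane bounded by two
saddle-node (fold) curves meeting at a cusp.  A reporter construct that
removes or weakens production from one allele multiplies γ by a
design-specific factor in [1, 2] — 2 for a heterozygous knock-in,
``2/(1+ε)`` for a pre-/post (2A or IRES) insertion that scales the reporter
allele's transcription by ε, ``2/(1+εδ)`` for a fusion that additionally
degrades feedback efficacy by δ, and 1 for a BAC transgene that leaves both
endogenous alleles untouched.  Rescaling γ can carry the system across a fold
curve, qualitatively changing the expression pattern the reporter is meant to
observe; :func:`risk_map` charts where.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from ._errors import DomainError, NumericalError

__all__ = [
    "FeedbackParams",
    "ReporterDesign",
    "DimensionlessParams",
    "Equilibrium",
    "EquilibriumSet",
    "BifurcationCurves",
    "OdeResult",
    "gamma_factor",
    "nondimensionalize",
    "equilibria",
    "classify",
    "bifurcation_curves",
    "risk_map",
    "simulate_ode",
]

_STABILITY_TOL = 1e-9
_BRACKET_STEP = 1e-3
_POLISH_XTOL = 1e-12


@dataclass(frozen=True)
class FeedbackParams:
    """Kinetic constants of the positive-feedback circuit (per allele)."""

    basal_rate: float  # c_b, concentration/time
    feedback_max_rate: float  # c_f, concentration/time
    decay_rate: float  # c_d, 1/time
    half_max: float  # K, concentration
    hill_coeff: float = 2.0  # H, dimensionless

    def __post_init__(self) -> None:
        for name in ("basal_rate", "feedback_max_rate", "decay_rate", "half_max"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.hill_coeff < 1:
            raise DomainError("hill_coeff must be >= 1")


@dataclass(frozen=True)
class ReporterDesign:
    """A reporter architecture and its perturbation parameters.

    ``epsilon`` scales transcription from the reporter-bearing allele
    (pre_post, fusion); ``delta`` scales the feedback efficacy of the fusion
    protein; ``insert_count`` m is the number of tandem reporter inserts for
    pre_post designs (``epsilon`` is then interpreted as ε_m for that m).
    """

    kind: Literal["wildtype", "knock_in", "pre_post", "fusion", "bac"]
    epsilon: Optional[float] = None
    delta: Optional[float] = None
    insert_count: int = 1

    def __post_init__(self) -> None:
        if self.kind not in {"wildtype", "knock_in", "pre_post", "fusion", "bac"}:
            raise DomainError(f"unknown reporter kind {self.kind!r}")
        if self.insert_count < 1:
            raise DomainError("insert_count must be >= 1")
        for name in ("epsilon", "delta"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise DomainError(f"{name} must lie in [0, 1]")
        if self.kind == "pre_post" and self.epsilon is None:
            raise DomainError("pre_post design requires epsilon")
        if self.kind == "fusion" and (self.epsilon is None or self.delta is None):
            raise DomainError("fusion design requires epsilon and delta")

    @classmethod
    def wildtype(cls) -> "ReporterDesign":
        return cls(kind="wildtype")

    @classmethod
    def knock_in(cls) -> "ReporterDesign":
        return cls(kind="knock_in")

    @classmethod
    def pre_post(cls, epsilon: float, insert_count: int = 1) -> "ReporterDesign":
        return cls(kind="pre_post", epsilon=epsilon, insert_count=insert_count)

    @classmethod
    def fusion(cls, epsilon: float, delta: float) -> "ReporterDesign":
        return cls(kind="fusion", epsilon=epsilon, delta=delta)

    @classmethod
    def bac(cls) -> "ReporterDesign":
        return cls(kind="bac")


def gamma_factor(design: ReporterDesign) -> float:
    """Multiplier applied to the wild-type γ by a reporter design.

    wildtype → 1, knock_in → 2, pre_post → 2/(1+ε_m), fusion → 2/(1+εδ),
    bac → 1.  Always in [1, 2]: any single-allele intervention can only weaken
    the aggregate feedback.
    """
    if design.kind in ("wildtype", "bac"):
        return 1.0
    if design.kind == "knock_in":
        return 2.0
    if design.kind == "pre_post":
        return 2.0 / (1.0 + design.epsilon)
    # fusion
    return 2.0 / (1.0 + design.epsilon * design.delta)


@dataclass(frozen=True)
class DimensionlessParams:
    """Reduced parameters (α, γ, H) of the rescaled feedback equation."""

    alpha: float
    gamma: float
    hill_coeff: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise DomainError("alpha must be >= 0")
        if self.gamma <= 0:
            raise DomainError("gamma must be > 0")

    def rhs(self, n: np.ndarray | float) -> np.ndarray | float:
        """f(n̄) = α + n̄^H/(γ^H + n̄^H) − n̄."""
        nH = np.power(n, self.hill_coeff)
        return self.alpha + nH / (self.gamma**self.hill_coeff + nH) - n

    def drhs(self, n: np.ndarray | float) -> np.ndarray | float:
        """f'(n̄)."""
        H, gH = self.hill_coeff, self.gamma**self.hill_coeff
        nH = np.power(n, H)
        return H * gH * np.power(n, H - 1.0) / (gH + nH) ** 2 - 1.0


def nondimensionalize(params: FeedbackParams, design: ReporterDesign) -> DimensionlessParams:
    """Reduce kinetic constants to (α, γ) for a given reporter design.

    α = c_b/c_f; γ = gamma_factor(design) · c_d·K/(2·c_f).
    """
    alpha = params.basal_rate / params.feedback_max_rate
    gamma_wt = params.decay_rate * params.half_max / (2.0 * params.feedback_max_rate)
    return DimensionlessParams(
        alpha=alpha, gamma=gamma_factor(design) * gamma_wt, hill_coeff=params.hill_coeff
    )


@dataclass(frozen=True)
class Equilibrium:
    level: float
    stable: bool
    derivative: float
    degenerate: bool = False  # |f'| within tolerance of a fold


@dataclass(frozen=True)
class EquilibriumSet:
    equilibria: tuple[Equilibrium, ...]
    classification: Literal["monostable", "bistable"]

    @property
    def stable_levels(self) -> tuple[float, ...]:
        return tuple(e.level for e in self.equilibria if e.stable)


def equilibria(dp: DimensionlessParams) -> EquilibriumSet:
    """All nonnegative equilibria of the rescaled equation, with stability.

    f(0) = α ≥ 0 and f(n̄) < 0 for n̄ > α+1, so every root lies in
    [0, α+1]; roots are located by sign-change bracketing on a fine grid and
    polished with Brent's method.  A root is stable iff f'(root) < −1e−9;
    |f'| ≤ 1e−9 marks a degenerate (fold) root.
    """
    hi = dp.alpha + 1.0
    grid = np.arange(0.0, hi + _BRACKET_STEP, _BRACKET_STEP)
    fv = np.asarray(dp.rhs(grid), dtype=float)

    roots: list[float] = []
    if abs(fv[0]) < 1e-14:  # exact root at the origin when α = 0
        roots.append(0.0)
    sign = np.sign(fv)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        try:
            r = brentq(dp.rhs, grid[i], grid[i + 1], xtol=_POLISH_XTOL)
        except ValueError as exc:  # pragma: no cover - bracketing guaranteed
            raise NumericalError(f"failed to polish root in [{grid[i]}, {grid[i+1]}]") from exc
        roots.append(float(r))
    # grid points that are (numerically) exact roots without a sign change
    for i in np.nonzero(sign[1:-1] == 0)[0]:
        roots.append(float(grid[i + 1]))
    roots = sorted(set(round(r, 12) for r in roots))

    eqs = []
    for r in roots:
        d = float(dp.drhs(r)) if r > 0 else float(dp.drhs(1e-300)) if dp.hill_coeff > 1 else float(dp.drhs(0.0))
        if r == 0.0 and dp.hill_coeff > 1:
            d = -1.0  # Hill term has zero slope at the origin for H > 1
        eqs.append(
            Equilibrium(
                level=r,
                stable=d < -_STABILITY_TOL,
                derivative=d,
                degenerate=abs(d) <= _STABILITY_TOL,
            )
        )
    n_stable = sum(e.stable for e in eqs)
    return EquilibriumSet(
        equilibria=tuple(eqs),
        classification="bistable" if n_stable == 2 else "monostable",
    )


def classify(dp: DimensionlessParams) -> str:
    """'bistable' iff the rescaled equation has exactly two stable equilibria."""
    return equilibria(dp).classification


@dataclass(frozen=True)
class BifurcationCurves:
    """Parametric saddle-node locus in the (α, γ) plane for fixed H.

    ``alpha_lower/gamma_lower`` trace the fold branch below the cusp level
    (small equilibrium), ``alpha_upper/gamma_upper`` the branch joining the
    cusp to (0, γ) on the α = 0 axis.  The bistable region is the set of
    points with γ between the two interpolated branches at their α.
    """

    hill_coeff: float
    alpha_lower: np.ndarray = field(repr=False)
    gamma_lower: np.ndarray = field(repr=False)
    alpha_upper: np.ndarray = field(repr=False)
    gamma_upper: np.ndarray = field(repr=False)
    cusp_alpha: float = np.nan
    cusp_gamma: float = np.nan
    bistability_possible: bool = True

    def contains(self, alpha: float, gamma: float) -> bool:
        """Side-of-curve test: is (α, γ) inside the bistable wedge?"""
        if not self.bistability_possible:
            return False
        if alpha < 0 or alpha > self.cusp_alpha:
            return False
        glo = float(np.interp(alpha, self.alpha_lower, self.gamma_lower))
        ghi = float(np.interp(alpha, self.alpha_upper[::-1], self.gamma_upper[::-1]))
        return glo < gamma < ghi


def _fold_point(n: float, H: float) -> tuple[float, float]:
    """(α, γ) of the fold through equilibrium level n, from f = f' = 0.

    Eliminating γ^H = u from f'(n) = 0 gives
    u² + u(2n^H − H·n^{H−1}) + n^{2H} = 0; the physically relevant root is
    the larger one (the smaller yields α < 0).
    """
    b = 2.0 * n**H - H * n ** (H - 1.0)
    disc = b * b - 4.0 * n ** (2.0 * H)
    if disc < 0:
        return np.nan, np.nan
    u = 0.5 * (-b + np.sqrt(disc))
    if u <= 0:
        return np.nan, np.nan
    gamma = u ** (1.0 / H)
    alpha = n - n**H / (u + n**H)
    return alpha, gamma


def bifurcation_curves(H: float, n_points: int = 4000) -> BifurcationCurves:
    """Saddle-node locus at Hill coefficient H, computed parametrically.

    The locus {f = f' = 0} is swept in the equilibrium level n̄ ∈ (0, H/4]
    (the discriminant of the fold condition is nonnegative exactly there).
    The cusp (where additionally f'' = 0) is the point of maximal α along the
    locus, polished with a bounded scalar optimizer.  For H ≤ 1 the equation
    has at most one stable equilibrium anywhere, and an empty locus with
    ``bistability_possible=False`` is returned.
    """
    if H <= 1:
        empty = np.empty(0)
        return BifurcationCurves(
            hill_coeff=H,
            alpha_lower=empty,
            gamma_lower=empty,
            alpha_upper=empty,
            gamma_upper=empty,
            bistability_possible=False,
        )
    n_max = H / 4.0
    # cusp: maximize α(n) along the locus
    res = minimize_scalar(
        lambda n: -_fold_point(n, H)[0],
        bounds=(1e-9, n_max),
        method="bounded",
        options={"xatol": 1e-12},
    )
    n_cusp = float(res.x)
    cusp_alpha, cusp_gamma = _fold_point(n_cusp, H)

    n_lo = np.linspace(1e-9, n_cusp, n_points)
    n_hi = np.linspace(n_cusp, n_max, n_points)
    lo = np.array([_fold_point(n, H) for n in n_lo])
    hi = np.array([_fold_point(n, H) for n in n_hi])
    ok_lo = np.isfinite(lo[:, 0]) & (lo[:, 0] >= 0)
    ok_hi = np.isfinite(hi[:, 0]) & (hi[:, 0] >= 0)
    return BifurcationCurves(
        hill_coeff=H,
        alpha_lower=lo[ok_lo, 0],
        gamma_lower=lo[ok_lo, 1],
        alpha_upper=hi[ok_hi, 0],
        gamma_upper=hi[ok_hi, 1],
        cusp_alpha=float(cusp_alpha),
        cusp_gamma=float(cusp_gamma),
        bistability_possible=True,
    )


def risk_map(
    design: ReporterDesign,
    alphas: np.ndarray,
    gammas: np.ndarray,
    hill_coeff: float = 2.0,
) -> pd.DataFrame:
    """Chart where a reporter design changes the qualitative dynamics.

    For each grid cell, compares the wild-type classification at (α, γ) with
    the design classification at (α, gamma_factor(design)·γ).  Returns a
    DataFrame with columns ``alpha, gamma, class_wt, class_design, at_risk,
    direction`` where direction is ``bistable->monostable``,
    ``monostable->bistable`` or ``none``.
    """
    factor = gamma_factor(design)
    rows = []
    for a in np.asarray(alphas, dtype=float):
        for g in np.asarray(gammas, dtype=float):
            cw = classify(DimensionlessParams(a, g, hill_coeff))
            cd = classify(DimensionlessParams(a, factor * g, hill_coeff))
            at_risk = cw != cd
            direction = "none" if not at_risk else f"{cw}->{cd}"
            rows.append((a, g, cw, cd, at_risk, direction))
    return pd.DataFrame(
        rows, columns=["alpha", "gamma", "class_wt", "class_design", "at_risk", "direction"]
    )


@dataclass
class OdeResult:
    """Trajectory and steady state of the deterministic reporter system."""

    t: np.ndarray
    nanog: np.ndarray  # total endogenous protein concentration n(t)
    reporter: np.ndarray  # reporter protein concentration r(t)
    steady_nanog: float
    steady_reporter: float
    steady_stable: bool


def _production_multiplier(design: ReporterDesign) -> float:
    """Total endogenous production relative to one allele: 2/gamma_factor."""
    return 2.0 / gamma_factor(design)


def _reporter_transcription(design: ReporterDesign) -> float:
    """Reporter-allele production relative to a wild-type allele."""
    if design.kind == "wildtype":
        return 0.0
    if design.kind in ("knock_in", "bac"):
        return 1.0
    return float(design.epsilon)  # pre_post / fusion insertions scale transcription by ε

def simulate_ode(
    params: FeedbackParams,
    design: ReporterDesign,
    reporter_decay: Optional[float] = None,
    n0: float = 0.0,
    r0: float = 0.0,
    t_end: float = 50.0,
    rtol: float = 1e-8,
) -> OdeResult:
    """Integrate the coupled endogenous/reporter ODEs to steady state.

    The endogenous equation aggregates production over the intact allele
    complement (multiplier 2/gamma_factor); the reporter protein is slaved to
    the same Hill drive with its own decay rate (default: matched to c_d, the
    regime in which reporter and target steady states coincide for a
    knock-in).  Integration proceeds in chunks of ``t_end`` until the
    right-hand-side norm drops below 1e−10 (stiff-capable LSODA).
    """
    if n0 < 0 or r0 < 0:
        raise DomainError("initial conditions must be nonnegative")
    rho = params.decay_rate if reporter_decay is None else float(reporter_decay)
    if rho <= 0:
        raise DomainError("reporter_decay must be > 0")
    mult = _production_multiplier(design)
    tr = _reporter_transcription(design)
    cb, cf, cd, K, H = (
        params.basal_rate,
        params.feedback_max_rate,
        params.decay_rate,
        params.half_max,
        params.hill_coeff,
    )

    def rhs(_t, y):
        n, r = y
        hill = n**H / (K**H + n**H) if n > 0 else 0.0
        drive = cb + cf * hill
        return [mult * drive - cd * n, tr * drive - rho * r]

    ts, ns, rs = [np.array([0.0])], [np.array([n0])], [np.array([r0])]
    y0 = [float(n0), float(r0)]
    t_offset = 0.0
    for _ in range(60):
        sol = solve_ivp(
            rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=1e-12, dense_output=False
        )
        if not sol.success:
            raise NumericalError(f"ODE integration failed: {sol.message}")
        ts.append(sol.t[1:] + t_offset)
        ns.append(sol.y[0][1:])
        rs.append(sol.y[1][1:])
        y0 = [sol.y[0][-1], sol.y[1][-1]]
        t_offset += t_end
        if np.linalg.norm(rhs(0.0, y0)) < 1e-10:
            break
    else:
        raise NumericalError("steady state not reached within the chunk budget")

    dp = nondimensionalize(params, design)
    scale = mult * cf / cd  # n = scale · n̄
    stable = any(
        abs(lvl * scale - y0[0]) <= 1e-6 * max(1.0, scale)
        for lvl in equilibria(dp).stable_levels
    )
    return OdeResult(
        t=np.concatenate(ts),
        nanog=np.concatenate(ns),
        reporter=np.concatenate(rs),
        steady_nanog=float(y0[0]),
        steady_reporter=float(y0[1]),
        steady_stable=stable,
    )
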