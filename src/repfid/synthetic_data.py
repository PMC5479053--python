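"""Seeded generators for every input the analysis pipeline consumes.

Real flow-cytometry event data for the wild-type/reporter comparison are not
publicly deposited, so the package ships generators that emulate the study
conditions with known ground truth:

* :func:`generate_population` — per-cell endpoints of the stochastic
  (Euler–Maruyama) positive-feedback dynamics, mapped to flow-cytometry-like
  intensities through multiplicative lognormal measurement noise and an
  additive autofluorescence floor.  Bistable parameter sets yield bimodal
  populations, monostable sets unimodal ones.
* :func:`generate_mixture_sample` — direct two-channel log-scale Gaussian
  mixtures for estimator-recovery tests.
* :func:`generate_timecourse` — day-indexed populations with a decaying
  high-expression subpopulation over the default schedule 0,1,2,3,5,7.
* :func:`generate_beads` — MESF calibration-bead fixtures.

Every generator is a pure function of its spec, including the seed, and
attaches ground-truth metadata the pipeline never reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import DomainError
from .expression_stats import BeadSet, ExpressionSample
from .feedback_model import (
    FeedbackParams,
    ReporterDesign,
    classify,
    gamma_factor,
    nondimensionalize,
)

__all__ = [
    "PopulationSpec",
    "TimecourseSpec",
    "generate_population",
    "generate_mixture_sample",
    "generate_timecourse",
    "generate_beads",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of one simulated cell population.

    ``sigma`` is the dynamical noise amplitude in units of the dimensionless
    (rescaled) concentration per square-root dimensionless time — the same
    value describes wild-type and reporter variants of a circuit, so their
    basin-escape behaviour is directly comparable.  ``measurement_sd`` is the
    standard deviation of multiplicative lognormal measurement noise in
    natural-log units; ``autofluorescence`` is the additive intensity floor;
    ``gain`` converts concentration to intensity.  ``high_fraction_init`` is
    the fraction of cells initialized near the high-expression state (the
    remainder start near zero), emulating a heterogeneous starting culture.
    """

    feedback: FeedbackParams
    design: ReporterDesign = field(default_factory=ReporterDesign.wildtype)
    sigma: float = 0.01
    measurement_sd: float = 0.25
    autofluorescence: float = 10.0
    gain: float = 1000.0
    n_cells: int = 10000
    seed: int = 0
    high_fraction_init: float = 0.5
    condition: str = "synthetic"
    day: int = 0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DomainError("sigma must be >= 0")
        if self.n_cells < 1:
            raise DomainError("n_cells must be >= 1")
        if not 0 <= self.high_fraction_init <= 1:
            raise DomainError("high_fraction_init must lie in [0, 1]")


_DT = 1e-2  # Euler–Maruyama step, units of the decay time
_BURN_IN = 20.0  # decay times before the endpoint is read


def generate_population(spec: PopulationSpec) -> ExpressionSample:
    """Simulate a population of cells to stationarity and 'measure' it.

    Integrates the dimensionless total-protein equation (with the design's γ)
    and the slaved reporter equation by Euler–Maruyama with additive noise
    ``sigma·dW`` and a reflecting boundary at 0, step 0.01 and burn-in 20
    decay times.  Endpoints are scaled back to concentrations and mapped to
    intensities via ``floor + gain·conc·exp(N(0, measurement_sd))``.  A
    warning is issued if more than 1% of integration steps hit the boundary.
    """
    rng = np.random.default_rng(spec.seed)
    dp = nondimensionalize(spec.feedback, spec.design)
    n_cells = spec.n_cells

    n_high = int(round(spec.high_fraction_init * n_cells))
    n = np.concatenate(
        [
            np.full(n_high, dp.alpha + 1.0),
            np.zeros(n_cells - n_high),
        ]
    )
    rng.shuffle(n)
    r = n.copy()

    steps = int(round(_BURN_IN / _DT))
    sq = spec.sigma * np.sqrt(_DT)
    clamped = 0
    gH = dp.gamma**dp.hill_coeff
    H = dp.hill_coeff
    for _ in range(steps):
        nH = n**H
        hill = nH / (gH + nH)
        n = n + (dp.alpha + hill - n) * _DT + sq * rng.standard_normal(n_cells)
        r = r + (dp.alpha + hill - r) * _DT + sq * rng.standard_normal(n_cells)
        clamped += int(np.sum(n < 0) + np.sum(r < 0))
        n = np.abs(n)
        r = np.abs(r)
    if clamped > 0.01 * 2 * steps * n_cells:
        warnings.warn(
            "more than 1% of integration steps were boundary-clamped; "
            "sigma may be large for this parameter set",
            stacklevel=2,
        )

    # back to concentration units, then to measured intensity
    mult = 2.0 / gamma_factor(spec.design)
    scale = mult * spec.feedback.feedback_max_rate / spec.feedback.decay_rate
    nanog_conc = scale * n
    rep_conc = scale * r
    meas = lambda c: spec.autofluorescence + spec.gain * c * np.exp(
        spec.measurement_sd * rng.standard_normal(n_cells)
    )
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "nanog": meas(nanog_conc),
            "reporter": meas(rep_conc),
            "condition": spec.condition,
            "day": spec.day,
            "replicate": spec.replicate,
        }
    )
    truth = {
        "generator": "sde_population",
        "alpha": dp.alpha,
        "gamma": dp.gamma,
        "hill_coeff": dp.hill_coeff,
        "design": spec.design.kind,
        "classification": classify(dp),
        "classification_wildtype": classify(
            nondimensionalize(spec.feedback, ReporterDesign.wildtype())
        ),
        "sigma": spec.sigma,
        "seed": spec.seed,
    }
    return ExpressionSample(data=df, units="arbitrary", ground_truth=truth)


def generate_mixture_sample(
    weights: Sequence[float],
    means: Sequence[Sequence[float]],
    sds: Sequence[Sequence[float]],
    correlation: float = 0.0,
    n: int = 1000,
    seed: int = 0,
    condition: str = "synthetic",
    day: int = 0,
    replicate: int = 0,
) -> ExpressionSample:
    """Two-channel Gaussian mixture on log scale with known ground truth.

    ``means``/``sds`` give per-component (nanog, reporter) log-intensity
    parameters; ``correlation`` is the within-component channel correlation.
    Linear intensities are ``exp`` of the sampled log values, so the
    pipeline's log-transform recovers exactly the specified mixture.
    """
    weights = np.asarray(weights, dtype=float)
    means = np.atleast_2d(np.asarray(means, dtype=float))
    sds = np.atleast_2d(np.asarray(sds, dtype=float))
    if not np.isclose(weights.sum(), 1.0):
        raise DomainError("weights must sum to 1")
    if not -1 < correlation < 1:
        raise DomainError("correlation must lie in (-1, 1)")
    if means.shape != (weights.size, 2) or sds.shape != (weights.size, 2):
        raise DomainError("means and sds must have shape (n_components, 2)")
    rng = np.random.default_rng(seed)
    comp = rng.choice(weights.size, size=n, p=weights)
    z1 = rng.standard_normal(n)
    z2 = correlation * z1 + np.sqrt(1 - correlation**2) * rng.standard_normal(n)
    log_nanog = means[comp, 0] + sds[comp, 0] * z1
    log_rep = means[comp, 1] + sds[comp, 1] * z2
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "nanog": np.exp(log_nanog),
            "reporter": np.exp(log_rep),
            "condition": condition,
            "day": day,
            "replicate": replicate,
        }
    )
    truth = {
        "generator": "gaussian_mixture",
        "weights": weights.tolist(),
        "means": means.tolist(),
        "sds": sds.tolist(),
        "correlation": correlation,
        "component": comp,
        "seed": seed,
    }
    return ExpressionSample(data=df, units="arbitrary", ground_truth=truth)


@dataclass(frozen=True)
class TimecourseSpec:
    """A differentiation-style time course with a decaying high subpopulation.

    The high-state weight decays exponentially in time from
    ``high_weight_start`` at rate ``weight_decay_rate`` per day, and both
    channel means of the high component drift downward by ``mean_drift`` log
    units per day — emulating gradual loss of expression after the
    self-renewal stimulus is withdrawn.
    """

    days: tuple[int, ...] = (0, 1, 2, 3, 5, 7)
    n_cells: int = 2000
    seed: int = 0
    high_weight_start: float = 0.7
    weight_decay_rate: float = 0.4  # per day
    low_mean: tuple[float, float] = (3.5, 3.5)  # log-intensity (nanog, reporter)
    high_mean: tuple[float, float] = (7.0, 7.0)
    mean_drift: float = 0.08  # log units per day, high component
    sds: tuple[float, float] = (0.45, 0.45)
    correlation: float = 0.6
    condition: str = "synthetic-timecourse"

    def __post_init__(self) -> None:
        if list(self.days) != sorted(set(self.days)):
            raise DomainError("days must be strictly increasing")
        if not 0 <= self.high_weight_start <= 1:
            raise DomainError("high_weight_start must lie in [0, 1]")

    def high_weight(self, day: int) -> float:
        return self.high_weight_start * float(np.exp(-self.weight_decay_rate * day))


def generate_timecourse(spec: TimecourseSpec) -> ExpressionSample:
    """Per-day populations with monotonically decreasing high-state weight."""
    frames = []
    truths = {}
    for i, day in enumerate(spec.days):
        w_high = spec.high_weight(day)
        hm = (spec.high_mean[0] - spec.mean_drift * day, spec.high_mean[1] - spec.mean_drift * day)
        sub = generate_mixture_sample(
            weights=[1.0 - w_high, w_high],
            means=[list(spec.low_mean), list(hm)],
            sds=[list(spec.sds), list(spec.sds)],
            correlation=spec.correlation,
            n=spec.n_cells,
            seed=spec.seed + 1000 * i,
            condition=spec.condition,
            day=day,
        )
        frames.append(sub.data)
        truths[int(day)] = {"high_weight": w_high, "high_mean": hm}
    df = pd.concat(frames, ignore_index=True)
    df["cell_id"] = np.arange(len(df))
    truth = {"generator": "timecourse", "per_day": truths, "seed": spec.seed}
    return ExpressionSample(data=df, units="arbitrary", ground_truth=truth)


def generate_beads(
    levels: Sequence[float],
    gain: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    slope: float = 1.0,
) -> BeadSet:
    """MESF calibration-bead fixture: intensity = gain·MESF^slope·e^noise."""
    levels = np.asarray(levels, dtype=float)
    if levels.size < 2:
        raise DomainError("need >= 2 bead levels")
    rng = np.random.default_rng(seed)
    intensity = gain * levels**slope * np.exp(noise_sd * rng.standard_normal(levels.size))
    return BeadSet(intensity=intensity, mesf=levels)
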